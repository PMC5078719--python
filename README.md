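# ltagmm

Latent transition analysis with growth-mixture measurement (LTA-GMM) for
longitudinal ability panels, plus a synthetic-panel generator that makes the
whole pipeline testable without access to restricted survey data.

## The problem

Children's reading ability (and many other developmental outcomes) grows in
stages: constrained skills (letter knowledge, decoding) are mastered quickly
in the early grades, unconstrained skills (vocabulary, comprehension) keep
developing for years. A single linear growth curve cannot describe both
phases, and children do not all follow the same trajectory — a small group
grows more slowly and may or may not catch up. The questions practitioners
ask are: *how many latent trajectory classes are there per stage, who moves
between classes across stages, and which covariates (parent and teacher
ratings, socioeconomic status, poverty) predict membership and transition?*

`ltagmm` answers these with a two-part model:

1. **Measurement (per stage):** a finite mixture of linear latent growth
   curves. Within class *c*, indicator *t* of a unit is
   `y_t = INT + t_s · SLP + ε_t`, with growth factors
   `(INT, SLP) ~ N(μ_c, Ψ_c)` and residuals `ε_t ~ N(0, θ_t)`. The mixture is
   fitted by multi-start EM with full-information handling of missing
   indicator cells (each unit contributes the Gaussian density of its
   observed sub-vector).
2. **Structure (3-step):** units are modally assigned to their highest
   posterior class `W`; the classification-error matrix
   `q[k, s] = P(W = s | C = k)` is computed from the posteriors; and the
   transition model is then estimated by maximum likelihood with `q` held
   fixed, so the error in treating assignments as known does not attenuate
   the estimates. Stage-1 membership and the stage-2 transition are binary
   logits; covariates enter the membership logit (`β1`), the stage-2 logit
   (`β2`), and a transition-specific increment (`γ`) applied to units that
   start in the low class.

Model selection uses BIC, sample-size-adjusted BIC
(`aBIC = -2LL + p·ln((n+2)/24)`, the primary index), relative entropy
(`1 − Σ −p·ln p / (n·ln K)`), and a minimum-class-size screen. Missing
covariates can be multiply imputed under a joint normal model and results
pooled by Rubin's rules.

## Worked example

```python
import ltagmm

# a synthetic 6-wave panel shaped like a large kindergarten-to-grade-8
# reading study: two latent classes per stage, absorbing high class
cfg = ltagmm.final_model_null(n=7803, seed=20161025 % 2**31)
panel = ltagmm.generate(cfg)
s1, s2 = ltagmm.stage_specs(cfg)

res = ltagmm.three_step_pipeline(panel, s1, s2, n_starts=20, seed=1)
print("stage-1 class weights:", res.stage1_fit.params.weights.round(3))
print("stage-1 majority growth means:", res.stage1_fit.params.means[0].round(3))
print("stage-2 majority growth means:", res.stage2_fit.params.means[0].round(3))
print("low-origin transition row:", res.lta.transition_matrix[1].round(3))
```

Output from one run of this exact snippet:

```
stage-1 class weights: [0.962 0.038]
stage-1 majority growth means: [-1.122  0.941]
stage-2 majority growth means: [0.414 0.121]
low-origin transition row: [0.329 0.671]
```

The stage-2 growth means (initial status 0.41, slope 0.12 per year) and the
stage-1 majority means (−1.12, 0.94) recover their generating values
(0.41/0.12 and −1.10/0.93) closely. The stage-1 class weight and the
corrected transition probabilities carry much more sampling noise: the two
stage-1 classes differ by only about one residual standard deviation, so the
mixture is weakly separated and single-run estimates of the class split and
of `P(high at stage 2 | low at stage 1)` (generating value 0.474) scatter
widely across seeds. `docs/methods.md` quantifies this.

The same pipeline is available from the shell:

```bash
ltagmm simulate --seed 42 --out sim/
ltagmm fit --data sim/panel.csv --mode enumerate --stage 2 --classes 4 --out fits/
ltagmm fit --data sim/panel.csv --mode lta3step \
       --covariates parent_rating,teacher_rating,ses,poverty --out fits/
ltagmm report fits/lta3step.json
```

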