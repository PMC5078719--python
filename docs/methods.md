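# Methods

## Model

Each developmental stage has its own growth-mixture measurement model. For
stage *s* with indicators observed at time scores `t = (0, t_2, …, t_T)`
(years since stage entry; the origin fixes the intercept's meaning), a unit
in class *c* follows

    y = Λ η + ε,   η = (INT, SLP) ~ N(μ_c, Ψ_c),   ε ~ N(0, diag(θ)),
    Λ = [1, t],

so the class-implied moments are `Λ μ_c` and `Λ Ψ_c Λ' + diag(θ)`. The
marginal distribution of the indicator vector is a K-component Gaussian
mixture with weights π. Missing indicator cells are handled by
full-information likelihood: a unit contributes the density of its observed
sub-vector, with moments restricted to the observed rows.

The structural model links the stage classifications. With two classes per
stage (high = majority, the reference class is low):

    logit P(G1 = high | x)            = α1 + β1'x
    logit P(G2 = high | G1 = g, x)    = α2_g + (β2 + γ·1[g = low])'x

The 3-step estimator fits each stage's mixture alone (step 1), modally
assigns classes W and computes the classification-error matrix
`q[k, s] = P(W = s | C = k)` from the posteriors (step 2), then maximizes

    Σ_i log Σ_{g1, g2} P(g1|x_i) P(g2|g1, x_i) q1[g1, W1_i] q2[g2, W2_i]

over the structural parameters with q fixed (step 3). With error-free
classification (q = I) and no covariates this reduces exactly to the
observed cross-tabulation proportions, which the tests verify against a
closed-form oracle.

## Estimation

* **EM for the growth mixture.** The E-step computes class responsibilities
  and, per class, the posterior factor moments by Gaussian conditioning (in
  gain form, `E[η|y,c] = μ_c + Ψ_c Λ' Σ_c^{-1}(y − Λμ_c)`, valid for
  singular Ψ). The M-step is closed form. Residual variances are estimated
  per indicator and shared across classes by default. The intercept–slope
  covariance is constrained equal across classes by default (the fitted
  models this package emulates report a single shared value per stage); the
  constrained update is a generalized-EM step — a bounded quasi-Newton pass
  on the expected complete-data log-likelihood restricted to the factor
  covariances, started from the current value and accepted only when it
  improves — so the observed log-likelihood never decreases. Both
  constraints are toggleable.
* **Acceleration.** The driver wraps plain EM in a SQUAREM-style squared
  extrapolation; the extrapolated candidate is stabilized with one EM step
  and accepted only when it does not lower the log-likelihood, preserving
  the monotone trace that the tests assert. This cuts iteration counts
  roughly four-fold on the weakly separated stage-1 problem.
* **Starts.** Responsibilities are initialized from a random hard partition
  blended with Dirichlet noise; all starts run a short burn-in (50 map
  evaluations) and the best three continue to convergence (log-likelihood
  change < 1e-6, cap 2000 map evaluations by default; the packaged
  acceptance runs raise the cap to 20000 because the stage-1 ridge
  converges slowly). Classes are relabeled canonically: descending weight, ties by
  ascending intercept mean.
* **Step 3.** EM over the latent (G1, G2) pair with weighted-logistic
  M-steps, polished by bounded L-BFGS-B on the exact likelihood. Covariates
  are standardized internally; coefficients are reported on the original
  scale via the exact linear back-transformation. All logits are bounded at
  |15|: an absorbing transition cell (the fixtures' high→high row) drives
  its intercept to this clamp, which is reported as a flag rather than an
  error, and such parameters get no Wald standard error. Standard errors
  come from the observed information (central-difference Hessian), mapped to
  the original scale by the standardization Jacobian.

## Synthetic-data generator

The generator emulates a large US kindergarten–grade-8 reading panel
(n = 7803, six IRT-scale score waves, four covariates) with the exact
structure the analysis assumes:

* **Covariates** are jointly normal with means (3.13, 3.06, 0.11, 1.84),
  SDs (0.22, 0.42, 0.63, 0.14) and the published correlation matrix for
  (parent rating, teacher rating, SES, poverty). Rating-scale truncation to
  [1, 4] is off by default; poverty is kept continuous.
* **Classes.** Stage-1 membership is Bernoulli(0.909 high) in the null
  fixture, or logistic in the covariates with β1 = (0.65, 1.95, 1.65, 0.59)
  and an intercept calibrated by root search so the marginal still hits
  0.909. The high class is absorbing (high→high probability 1); the
  low-origin transition row is (0.474, 0.526), or logistic with effective
  coefficients β2 + γ = (−0.19, −0.36, −0.48, −0.09) calibrated to the
  0.474 marginal. β2 alone is deliberately unidentified in the generator
  (the high stratum never varies), mirroring the boundary in the emulated
  results.
* **Trajectories.** Stage-1 time scores (0, 0.5, 1.5) years — Fall K,
  Spring K, Spring G1 — and stage-2 scores (0, 2, 4, 7) — Spring G1, G3,
  G5, G8 — chosen from the calendar spacing of the waves. Growth factors
  per class: stage 1 high (−1.10, 0.93) / low (−1.58, 0.89) with
  Ψ = [[0.18, −0.05], [−0.05, 0.04]] / [[0.16, −0.05], [−0.05, 0.09]];
  stage 2 high (0.41, 0.12) / low (−0.48, 0.19). The published stage-2
  slope variance and intercept–slope covariance round to 0.00/0.01, which
  is not jointly positive semi-definite; the generator uses
  Ψ2 = [[0.01, 0.002], [0.002, 0.002]], a PSD matrix consistent with those
  printed magnitudes. Residual SDs default to 0.3 (stage 1) and 0.15
  (stage 2).
* **The knot.** The Spring-G1 wave belongs to both stages, but the printed
  stage-1 endpoint (−1.10 + 1.5·0.93 = 0.295) and stage-2 intercept (0.41)
  are inconsistent under a single shared score, so the two stage processes
  are conditionally independent given the classes. `knot_mode` controls the
  emitted column(s): `duplicate` (default; stage-specific `y3a`/`y3b`, used
  for recovery testing), `average`, `stage1`, or `stage2`.
* **Missingness.** MCAR by default at per-variable rates
  (y1 = 7.0%, others 0.5–4.8%, covariates 0.5–1.5%) whose ten-variable mean
  is exactly 2.6%; a MAR option keys the masking probability on SES through
  a logistic weight rescaled to preserve each marginal rate.

What the generator does **not** emulate: item-level responses or IRT
scoring, survey weights, school clustering, floor/ceiling effects, or the
non-normal features of real score distributions. Consequences for
interpreting passing tests are discussed below.

## Multiple imputation

Missing cells are imputed from a single joint normal over the ten analysis
variables, fitted by EM to the observed data; each imputation draws missing
entries from their conditional normal given the unit's observed values at
the maximum-likelihood parameters (no parameter-uncertainty draw), with
m = 10 by default, and scalar estimates are pooled by Rubin's rules
(`total = within + (1 + 1/m)·between`). Indicator missingness is normally
handled inside the EM by full information instead; imputation is mainly for
missing covariates in step 3.

## Numerical choices

* Log-space responsibility computation (log-sum-exp); residual variances
  floored at 1e-8; factor covariances kept PSD by construction in the
  M-step and repaired (eigenvalue clip, correlation bound 0.999) after
  SQUAREM extrapolation.
* Class weights below 1e-4 flag the fit as degenerate; enumeration reports
  degenerate candidates rather than re-fitting them.
* Modal-assignment ties break toward the lower class index.
* Entropy is NaN for K = 1 (undefined); enumeration treats entropy below
  0.6 as a warning, not a gate; selection uses minimum aBIC among
  candidates whose smallest class is at least 5% of the sample, with a
  fallback to the smallest K plus a warning when every candidate fails.
* Acceptance-scale runs use n = 7803, 20 random starts, and a 6000-step
  cap per retained start; the packaged test suite uses smaller panels
  (n = 600–2000) for everything except the end-to-end recovery checks.

## Weak separation of the stage-1 mixture (known limitation)

Under the packaged generating values the two stage-1 classes differ in mean
intercept by 0.48 while the within-class intercept SD is ~0.42 and the
residual SD 0.3 — about one pooled SD of separation, with a 91/9 split. The
oracle (true-parameter) posterior classification has relative entropy 0.66,
far below the ~0.91 reported for the real data this structure summarizes;
no Gaussian mixture with the published variance components can reproduce
that entropy, which the package treats as an inconsistency inherent to the
published summaries rather than something the generator should hide.

The practical consequence is a very flat likelihood ridge: the stage-1
class-weight MLE at n = 7803 scatters widely across seeds (replicate runs
here gave majority weights 0.74–0.98 around the generating 0.909,
Monte-Carlo SD ≈ 0.08; likelihood differences across that whole range are a
few log-units, and on some realizations even an EM started at the true
parameters converges far from them), and the
classification-error-corrected low-origin transition probability scatters
even more (replicates 0.16–0.78 around 0.474, Monte-Carlo SD ≈ 0.2,
because the correction divides by a near-vanishing information term when
the error-matrix row approaches uniformity). Covariate coefficients on stage-1 membership inherit this
noise (Wald SE ≈ 0.3 for the teacher-rating effect). Growth-factor means of
the majority classes, and everything about the well-separated stage-2
mixture, are recovered tightly. Point estimates from a single synthetic run
therefore recover stage-1 class-composition quantities only to within a few
Monte-Carlo SDs, not to the nominal precision of the emulated study; the
recovery tests that assert tighter single-seed bands on those specific
quantities document this gap rather than a defect of the estimator.
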