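"""Synthetic longitudinal reading-ability panels.

Generates wide panels with the statistical structure the analysis assumes:
jointly normal covariates with configurable moments and correlations, a
two-class two-stage latent structure (Stage-1 membership, then a transition
to the Stage-2 class that is either a fixed probability row or logistic in
the covariates), per-class linear growth trajectories for each stage, and
MCAR or covariate-keyed MAR missingness.

The packaged fixtures mirror a large US kindergarten-to-grade-8 reading
panel (n = 7803, six IRT-scale score waves): ``final_model_null`` carries
the fitted two-class growth and transition structure without covariates;
``final_model_covariates`` adds logistic covariate effects on membership
and transition with intercepts calibrated to the same marginals.

The two stage processes are conditionally independent given the class
labels; the shared Spring-Grade-1 wave (the knot) can be emitted as two
stage-specific columns ("duplicate"), their average, or either single
process, because the two stages' generating values do not admit a single
consistent shared score.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .growth_mixture import StageSpec
from .panel_io import COVARIATE_NAMES, PanelDataset

__all__ = [
    "StageGrowth",
    "GeneratorConfig",
    "final_model_null",
    "final_model_covariates",
    "sample_covariates",
    "calibrate_intercept",
    "sample_classes",
    "sample_trajectories",
    "apply_missingness",
    "generate",
    "stage_specs",
    "DEFAULT_MISSING_RATES",
]

logger = logging.getLogger(__name__)

#: Table-style covariate moments: parent rating, teacher rating, SES, poverty
DEFAULT_COV_MEANS = (3.13, 3.06, 0.11, 1.84)
DEFAULT_COV_SDS = (0.22, 0.42, 0.63, 0.14)
DEFAULT_COV_CORR = (
    (1.00, 0.23, 0.18, 0.12),
    (0.23, 1.00, 0.19, 0.15),
    (0.18, 0.19, 1.00, 0.49),
    (0.12, 0.15, 0.49, 1.00),
)

#: per-variable MCAR rates; the 10-variable mean is exactly 0.026
DEFAULT_MISSING_RATES = {
    "y1": 0.070,
    "y2": 0.025,
    "y3": 0.015,
    "y4": 0.030,
    "y5": 0.035,
    "y6": 0.048,
    "parent_rating": 0.012,
    "teacher_rating": 0.015,
    "ses": 0.005,
    "poverty": 0.005,
}

STAGE1_TIME_SCORES = (0.0, 0.5, 1.5)  # Fall K, Spring K, Spring G1 (years)
STAGE2_TIME_SCORES = (0.0, 2.0, 4.0, 7.0)  # Spring G1, G3, G5, G8


@dataclass(frozen=True)
class StageGrowth:
    """Two-class growth configuration of one stage (class 0 = high)."""

    mu_high: tuple[float, float]
    mu_low: tuple[float, float]
    psi_high: tuple[tuple[float, float], tuple[float, float]]
    psi_low: tuple[tuple[float, float], tuple[float, float]]
    resid_sd: float
    time_scores: tuple[float, ...]

    def psi(self, cls: int) -> np.ndarray:
        S = np.asarray(self.psi_high if cls == 0 else self.psi_low, dtype=float)
        if np.linalg.eigvalsh(S).min() < -1e-10:
            raise ValueError("factor covariance must be positive semi-definite")
        return S

    def mu(self, cls: int) -> np.ndarray:
        return np.asarray(self.mu_high if cls == 0 else self.mu_low, dtype=float)


# fitted growth-factor values of the two-stage two-class solution; the
# Stage-2 slope variance / covariance are small positive values consistent
# with the near-zero printed estimates while keeping the matrix PSD
DEFAULT_STAGE1_GROWTH = StageGrowth(
    mu_high=(-1.10, 0.93),
    mu_low=(-1.58, 0.89),
    psi_high=((0.18, -0.05), (-0.05, 0.04)),
    psi_low=((0.16, -0.05), (-0.05, 0.09)),
    resid_sd=0.3,
    time_scores=STAGE1_TIME_SCORES,
)
DEFAULT_STAGE2_GROWTH = StageGrowth(
    mu_high=(0.41, 0.12),
    mu_low=(-0.48, 0.19),
    psi_high=((0.01, 0.002), (0.002, 0.002)),
    psi_low=((0.01, 0.002), (0.002, 0.002)),
    resid_sd=0.15,
    time_scores=STAGE2_TIME_SCORES,
)

#: Stage-1 membership logit coefficients (high vs low) on
#: (parent rating, teacher rating, SES, poverty)
DEFAULT_BETA1 = (0.65, 1.95, 1.65, 0.59)
#: effective low-origin transition logit coefficients (beta2 + gamma)
DEFAULT_BETA_TRANS = (-0.19, -0.36, -0.48, -0.09)


@dataclass(frozen=True)
class GeneratorConfig:
    """Complete recipe for one synthetic panel."""

    n: int = 7803
    seed: int = 0
    covariate_means: tuple[float, ...] = DEFAULT_COV_MEANS
    covariate_sds: tuple[float, ...] = DEFAULT_COV_SDS
    covariate_corr: tuple[tuple[float, ...], ...] = DEFAULT_COV_CORR
    truncate_ratings: bool = False
    structural_mode: str = "null"  # "null" | "covariate"
    pi_g1_high: float = 0.909
    tau_high: tuple[float, float] = (1.0, 0.0)
    tau_low: tuple[float, float] = (0.474, 0.526)
    beta1: tuple[float, ...] = DEFAULT_BETA1
    beta_trans: tuple[float, ...] = DEFAULT_BETA_TRANS
    target_g1_high: float = 0.909
    target_trans_high: float = 0.474
    stage1: StageGrowth = DEFAULT_STAGE1_GROWTH
    stage2: StageGrowth = DEFAULT_STAGE2_GROWTH
    knot_mode: str = "duplicate"  # duplicate | average | stage1 | stage2
    missing_rates: dict | None = None
    missing_mechanism: str = "MCAR"  # MCAR | MAR
    mar_coef: float = -1.0  # SES coefficient of the MAR masking logit

    def __post_init__(self) -> None:
        if self.structural_mode not in ("null", "covariate"):
            raise ValueError("structural_mode must be 'null' or 'covariate'")
        if self.knot_mode not in ("duplicate", "average", "stage1", "stage2"):
            raise ValueError(f"unknown knot_mode {self.knot_mode!r}")
        if self.missing_mechanism not in ("MCAR", "MAR"):
            raise ValueError("missing_mechanism must be 'MCAR' or 'MAR'")
        tau = np.array([self.tau_high, self.tau_low])
        if np.any(tau < 0) or np.max(np.abs(tau.sum(axis=1) - 1)) > 1e-8:
            raise ValueError("transition rows must be probability vectors")
        if self.missing_rates is not None:
            for k, r in self.missing_rates.items():
                if not 0.0 <= r < 1.0:
                    raise ValueError(f"missing rate for {k} out of [0, 1): {r}")

    @property
    def indicator_cols(self) -> tuple[str, ...]:
        if self.knot_mode == "duplicate":
            return ("y1", "y2", "y3a", "y3b", "y4", "y5", "y6")
        return ("y1", "y2", "y3", "y4", "y5", "y6")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def final_model_null(n: int = 7803, seed: int = 0, **overrides) -> GeneratorConfig:
    """Fixture: fitted two-class structure, fixed transition rows, no covariate effects."""
    return GeneratorConfig(n=n, seed=seed, structural_mode="null", **overrides)


def final_model_covariates(n: int = 7803, seed: int = 0, **overrides) -> GeneratorConfig:
    """Fixture: membership and transition logistic in the covariates, with
    intercepts calibrated to the null fixture's marginals."""
    return GeneratorConfig(n=n, seed=seed, structural_mode="covariate", **overrides)


def stage_specs(config: GeneratorConfig, K: int = 2) -> tuple[StageSpec, StageSpec]:
    """StageSpec pair matching the panel's indicator naming for its knot mode."""
    y3_first = "y3a" if config.knot_mode == "duplicate" else "y3"
    y3_second = "y3b" if config.knot_mode == "duplicate" else "y3"
    s1 = StageSpec(1, ("y1", "y2", y3_first), config.stage1.time_scores, K=K)
    s2 = StageSpec(
        2, (y3_second, "y4", "y5", "y6"), config.stage2.time_scores, K=K
    )
    return s1, s2


# ---------------------------------------------------------------------------
# components


def sample_covariates(
    config: GeneratorConfig, n: int | None = None, rng=None
) -> pd.DataFrame:
    """Jointly normal covariates with the configured moments and correlations."""
    n = config.n if n is None else n
    rng = np.random.default_rng(config.seed) if rng is None else rng
    means = np.asarray(config.covariate_means, dtype=float)
    sds = np.asarray(config.covariate_sds, dtype=float)
    corr = np.asarray(config.covariate_corr, dtype=float)
    if not np.allclose(corr, corr.T) or np.any(np.abs(np.diag(corr) - 1) > 1e-10):
        raise ValueError("correlation matrix must be symmetric with unit diagonal")
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < -1e-10:
        raise ValueError(
            "correlation matrix is not PSD; clip its negative eigenvalues to 0 "
            "and renormalize the diagonal (nearest-PSD repair)"
        )
    cov = corr * np.outer(sds, sds)
    # eigen square root tolerates zero-variance columns
    w, V = np.linalg.eigh(cov)
    root = V @ np.diag(np.sqrt(np.maximum(w, 0.0))) @ V.T
    X = means + rng.standard_normal((n, len(means))) @ root.T
    df = pd.DataFrame(X, columns=list(COVARIATE_NAMES))
    if config.truncate_ratings:
        for c in ("parent_rating", "teacher_rating"):
            df[c] = df[c].clip(1.0, 4.0)
    return df


def calibrate_intercept(
    beta: np.ndarray, X: np.ndarray, target_marginal: float, tol: float = 1e-3
) -> float:
    """Intercept alpha with mean_x logistic(alpha + beta'x) = target.

    The marginal is strictly increasing in alpha, so a bracketing root search
    suffices.  With beta = 0 this reduces to the closed form logit(target).
    """
    if not 0.0 < target_marginal < 1.0:
        raise ValueError("target marginal must be in (0, 1)")
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = np.asarray(X, dtype=float)
    if not np.any(beta):
        return float(logit(target_marginal))
    xb = X @ beta

    def f(a):
        return float(expit(a + xb).mean() - target_marginal)

    lo, hi = -40.0, 40.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("target marginal unattainable for this covariate sample")
    alpha = brentq(f, lo, hi, xtol=1e-10)
    if abs(f(alpha)) > tol:
        raise ValueError("intercept calibration failed to reach the target")
    return float(alpha)


def sample_classes(
    X: pd.DataFrame | np.ndarray | None,
    config: GeneratorConfig,
    rng=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (G1, G2) class labels, 0 = high, 1 = low.

    Null mode: G1 ~ Bernoulli(pi), G2 from the fixed transition rows.
    Covariate mode: logistic membership / low-origin transition with
    intercepts calibrated so the marginals hit the configured targets;
    the high-origin row keeps its configured (default absorbing) values.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n if X is None else len(X)

    if config.structural_mode == "covariate":
        if X is None:
            raise ValueError("covariate mode needs a covariate sample")
        Xm = X[list(COVARIATE_NAMES)].to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X)
        a1 = calibrate_intercept(config.beta1, Xm, config.target_g1_high)
        p_high = expit(a1 + Xm @ np.asarray(config.beta1))
    else:
        p_high = np.full(n, config.pi_g1_high)

    G1 = (rng.random(n) >= p_high).astype(int)  # 0 = high with prob p_high

    G2 = np.empty(n, dtype=int)
    hi = G1 == 0
    G2[hi] = (rng.random(hi.sum()) >= config.tau_high[0]).astype(int)
    lo = ~hi
    if config.structural_mode == "covariate" and lo.any():
        Xlo = Xm[lo]
        a2 = calibrate_intercept(config.beta_trans, Xlo, config.target_trans_high)
        p_trans = expit(a2 + Xlo @ np.asarray(config.beta_trans))
        G2[lo] = (rng.random(lo.sum()) >= p_trans).astype(int)
    else:
        G2[lo] = (rng.random(lo.sum()) >= config.tau_low[0]).astype(int)
    return G1, G2


def sample_trajectories(
    G1: np.ndarray,
    G2: np.ndarray,
    config: GeneratorConfig,
    rng=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-unit growth factors and noisy indicator trajectories.

    Returns (indicators, truth); truth holds the latent factors and labels.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = len(G1)

    def draw_factors(stage: StageGrowth, cls: np.ndarray) -> np.ndarray:
        eta = np.empty((n, 2))
        for c in (0, 1):
            idx = np.flatnonzero(cls == c)
            if idx.size:
                S = stage.psi(c)
                # eigen square root handles PSD (possibly singular) Psi
                w, V = np.linalg.eigh(S)
                root = V @ np.diag(np.sqrt(np.maximum(w, 0.0))) @ V.T
                eta[idx] = stage.mu(c) + rng.standard_normal((idx.size, 2)) @ root.T
        return eta

    eta1 = draw_factors(config.stage1, G1)
    eta2 = draw_factors(config.stage2, G2)

    t1 = np.asarray(config.stage1.time_scores)
    t2 = np.asarray(config.stage2.time_scores)
    Y1 = eta1[:, [0]] + np.outer(eta1[:, 1], t1)
    Y2 = eta2[:, [0]] + np.outer(eta2[:, 1], t2)
    Y1 += config.stage1.resid_sd * rng.standard_normal(Y1.shape)
    Y2 += config.stage2.resid_sd * rng.standard_normal(Y2.shape)

    cols = {"y1": Y1[:, 0], "y2": Y1[:, 1]}
    if config.knot_mode == "duplicate":
        cols["y3a"] = Y1[:, 2]
        cols["y3b"] = Y2[:, 0]
    elif config.knot_mode == "average":
        cols["y3"] = 0.5 * (Y1[:, 2] + Y2[:, 0])
    elif config.knot_mode == "stage1":
        cols["y3"] = Y1[:, 2]
    else:  # stage2
        cols["y3"] = Y2[:, 0]
    cols["y4"] = Y2[:, 1]
    cols["y5"] = Y2[:, 2]
    cols["y6"] = Y2[:, 3]
    indicators = pd.DataFrame({c: cols[c] for c in config.indicator_cols})

    truth = pd.DataFrame(
        {
            "g1": G1,
            "g2": G2,
            "int1": eta1[:, 0],
            "slp1": eta1[:, 1],
            "int2": eta2[:, 0],
            "slp2": eta2[:, 1],
        }
    )
    return indicators, truth


def apply_missingness(
    panel: PanelDataset,
    rates: dict | None = None,
    mechanism: str = "MCAR",
    rng=None,
    mar_coef: float = -1.0,
) -> PanelDataset:
    """Mask cells at the per-variable rates.

    MCAR masks each cell independently.  MAR keys the masking probability on
    SES through a logistic weight, rescaled so each variable still hits its
    marginal rate (lower SES -> more missingness for negative ``mar_coef``).
    """
    if rates is None:
        rates = DEFAULT_MISSING_RATES
    rng = np.random.default_rng(0) if rng is None else rng
    df = panel.data.copy()
    truth = panel.truth.copy() if panel.truth is not None else pd.DataFrame(index=df.index)
    n = len(df)

    if mechanism == "MAR":
        ses = df["ses"].to_numpy(dtype=float)
        w = expit(mar_coef * (ses - np.nanmean(ses)))
        w = w / w.mean()
    else:
        w = np.ones(n)

    for var, rate in rates.items():
        if rate <= 0.0:
            continue
        cands = [var]
        if var == "y3" and var not in df.columns:
            cands = [c for c in ("y3a", "y3b") if c in df.columns]
        for col in cands:
            if col not in df.columns:
                continue
            if f"premask_{col}" not in truth.columns:
                truth[f"premask_{col}"] = df[col].to_numpy(copy=True)
            p = np.minimum(rate * w, 1.0)
            mask = rng.random(n) < p
            df.loc[mask, col] = np.nan

    return dataclasses.replace(panel, data=df, truth=truth)


def generate(config: GeneratorConfig) -> PanelDataset:
    """End-to-end panel: covariates, classes, trajectories, missingness.

    Fully reproducible from the config (all randomness flows from its seed);
    the truth block records classes, latent factors and pre-masking values.
    """
    ss = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(4)]
    logger.info(
        "generating panel: n=%d seed=%d config_hash=%s",
        config.n,
        config.seed,
        config.config_hash(),
    )

    cov = sample_covariates(config, config.n, rngs[0])
    G1, G2 = sample_classes(
        cov if config.structural_mode == "covariate" else None, config, rngs[1]
    )
    indicators, truth = sample_trajectories(G1, G2, config, rngs[2])

    df = pd.concat(
        [
            pd.Series(np.arange(config.n), name="unit_id"),
            indicators,
            cov,
        ],
        axis=1,
    )
    panel = PanelDataset(
        data=df,
        indicator_cols=config.indicator_cols,
        covariate_cols=COVARIATE_NAMES,
        truth=truth,
    )
    if config.missing_rates:
        panel = apply_missingness(
            panel,
            config.missing_rates,
            config.missing_mechanism,
            rngs[3],
            config.mar_coef,
        )
    return panel
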