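"""Steps 2-3 of the 3-step latent transition analysis.

Step 1 (per-stage growth mixtures) yields posterior class probabilities.
Step 2 assigns each unit its modal class W and computes the classification
error matrix q[k, s] = P(W = s | C = k) from the posteriors.  Step 3 then
estimates the structural model by maximum likelihood with q held fixed as
the measurement part: Stage-1 membership and the Stage-2 transition are
binary logits (high vs low), with covariates entering the Stage-1 logit
(beta1), the Stage-2 logit (beta2), and a transition-specific increment
(gamma) that applies when the unit starts in the low class.  Treating the
modal classes as error-free would attenuate transition estimates; fixing q
removes that bias.

Class index 0 is the high (majority) class, inherited from the canonical
step-1 ordering; the low class is the logit reference.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

from . import model_selection
from .panel_io import PooledEstimate, pool_rubin

__all__ = [
    "ModalAssignment",
    "ErrorMatrix",
    "StructuralParams",
    "LTAFit",
    "modal_assign",
    "classification_error",
    "step3_loglik",
    "fit_step3",
    "odds_ratios",
    "pool_step3_fits",
]

LOGIT_CLAMP = 15.0


@dataclass(frozen=True)
class ModalAssignment:
    classes: np.ndarray  # (n,) int, 0-based
    proportions: np.ndarray  # (K,)


@dataclass(frozen=True)
class ErrorMatrix:
    """Classification-error probabilities q[k, s] = P(modal = s | true = k)."""

    q: np.ndarray  # (K, K), rows sum to 1
    logits: np.ndarray  # log(q[k, s] / q[k, K-1]), clamped at +-LOGIT_CLAMP

    @property
    def K(self) -> int:
        return self.q.shape[0]

    @classmethod
    def identity(cls, K: int) -> "ErrorMatrix":
        q = np.eye(K)
        return cls(q=q, logits=_error_logits(q))

    @classmethod
    def from_q(cls, q: np.ndarray) -> "ErrorMatrix":
        q = np.asarray(q, dtype=float)
        if q.ndim != 2 or q.shape[0] != q.shape[1]:
            raise ValueError("q must be square")
        if np.any(q < 0) or np.max(np.abs(q.sum(axis=1) - 1.0)) > 1e-8:
            raise ValueError("rows of q must be probability vectors")
        return cls(q=q, logits=_error_logits(q))


def _error_logits(q: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lg = np.log(np.maximum(q, 1e-300)) - np.log(
            np.maximum(q[:, -1:], 1e-300)
        )
    return np.clip(lg, -LOGIT_CLAMP, LOGIT_CLAMP)


@dataclass
class StructuralParams:
    """Structural coefficients of the transition model (original covariate scale).

    alpha1 : Stage-1 membership intercept (logit high vs low).
    beta1 : covariate effects on Stage-1 membership.
    alpha2_high / alpha2_low : Stage-2 intercepts by origin class.
    beta2 : covariate effects on Stage-2 membership (baseline, high origin).
    gamma : transition-specific increment, applied when the origin is low
        (effective low-origin slope is beta2 + gamma).
    """

    alpha1: float
    beta1: np.ndarray
    alpha2_high: float
    alpha2_low: float
    beta2: np.ndarray
    gamma: np.ndarray
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.beta1 = np.atleast_1d(np.asarray(self.beta1, dtype=float))
        self.beta2 = np.atleast_1d(np.asarray(self.beta2, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if not (len(self.beta1) == len(self.beta2) == len(self.gamma)):
            raise ValueError("covariate blocks must have equal length")

    @property
    def p(self) -> int:
        return len(self.beta1)


@dataclass
class LTAFit:
    structural: StructuralParams
    loglik: float
    bic: float
    abic: float
    entropy: float
    n_params: int
    transition_matrix: np.ndarray  # (2, 2): rows origin (high, low)
    stage1_proportions: np.ndarray  # (2,)
    combination_table: list[dict]
    joint_posterior: np.ndarray  # (n, 4) over (g1, g2) combos
    ses: StructuralParams | None = None
    clamped: list[str] = field(default_factory=list)
    converged: bool = True
    per_imputation: list["LTAFit"] | None = None
    pooled: dict[str, PooledEstimate] | None = None

    def to_dict(self) -> dict:
        s = self.structural
        d = {
            "alpha1": s.alpha1,
            "beta1": s.beta1.tolist(),
            "alpha2_high": s.alpha2_high,
            "alpha2_low": s.alpha2_low,
            "beta2": s.beta2.tolist(),
            "gamma": s.gamma.tolist(),
            "covariate_names": list(s.covariate_names),
            "loglik": self.loglik,
            "bic": self.bic,
            "abic": self.abic,
            "entropy": self.entropy,
            "n_params": self.n_params,
            "transition_matrix": self.transition_matrix.tolist(),
            "stage1_proportions": self.stage1_proportions.tolist(),
            "combination_table": self.combination_table,
            "clamped": self.clamped,
            "converged": self.converged,
        }
        if self.ses is not None:
            d["ses"] = {
                "alpha1": self.ses.alpha1,
                "beta1": self.ses.beta1.tolist(),
                "alpha2_high": self.ses.alpha2_high,
                "alpha2_low": self.ses.alpha2_low,
                "beta2": self.ses.beta2.tolist(),
                "gamma": self.ses.gamma.tolist(),
            }
        return d


# ---------------------------------------------------------------------------
# step 2


def modal_assign(responsibilities: np.ndarray) -> ModalAssignment:
    """Highest-posterior class per unit; ties go to the lower class index."""
    p = np.asarray(responsibilities, dtype=float)
    classes = p.argmax(axis=1)
    K = p.shape[1]
    props = np.bincount(classes, minlength=K) / len(classes)
    return ModalAssignment(classes=classes, proportions=props)


def classification_error(
    responsibilities: np.ndarray, modal: ModalAssignment | None = None
) -> ErrorMatrix:
    """Posterior-weighted cross-tabulation of true class against modal class.

    q[k, s] = sum_i p_ik 1(W_i = s) / sum_i p_ik.
    """
    p = np.asarray(responsibilities, dtype=float)
    if modal is None:
        modal = modal_assign(p)
    n, K = p.shape
    if len(modal.classes) != n:
        raise ValueError("responsibilities and modal assignment sizes disagree")
    col = np.sum(p, axis=0)
    if np.any(col <= 0):
        raise ValueError("a latent class carries zero posterior mass")
    onehot = np.zeros((n, K))
    onehot[np.arange(n), modal.classes] = 1.0
    q = p.T @ onehot / col[:, None]
    return ErrorMatrix(q=q, logits=_error_logits(q))


# ---------------------------------------------------------------------------
# step 3 likelihood


def _unit_likelihood(
    theta: np.ndarray, W1, W2, X, q1: np.ndarray, q2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-unit likelihood and the four joint (g1, g2) component terms.

    theta = [alpha1, beta1(p), alpha2_high, alpha2_low, beta2(p), gamma(p)].
    """
    p = 0 if X is None else X.shape[1]
    a1 = theta[0]
    b1 = theta[1 : 1 + p]
    a2h = theta[1 + p]
    a2l = theta[2 + p]
    b2 = theta[3 + p : 3 + 2 * p]
    g = theta[3 + 2 * p : 3 + 3 * p]

    if p:
        eta1 = a1 + X @ b1
        etaH = a2h + X @ b2
        etaL = a2l + X @ (b2 + g)
    else:
        n = len(W1)
        eta1 = np.full(n, a1)
        etaH = np.full(n, a2h)
        etaL = np.full(n, a2l)
    p1h = expit(eta1)
    p2h_h = expit(etaH)
    p2h_l = expit(etaL)

    m1h = q1[0, W1]
    m1l = q1[1, W1]
    m2h = q2[0, W2]
    m2l = q2[1, W2]

    terms = np.empty((len(W1), 4))
    terms[:, 0] = p1h * m1h * p2h_h * m2h  # (H, H)
    terms[:, 1] = p1h * m1h * (1 - p2h_h) * m2l  # (H, L)
    terms[:, 2] = (1 - p1h) * m1l * p2h_l * m2h  # (L, H)
    terms[:, 3] = (1 - p1h) * m1l * (1 - p2h_l) * m2l  # (L, L)
    lik = terms.sum(axis=1)
    return lik, terms


def _pack(s: StructuralParams) -> np.ndarray:
    return np.concatenate(
        [[s.alpha1], s.beta1, [s.alpha2_high, s.alpha2_low], s.beta2, s.gamma]
    )


def _unpack(theta: np.ndarray, p: int, names=()) -> StructuralParams:
    return StructuralParams(
        alpha1=float(theta[0]),
        beta1=theta[1 : 1 + p].copy(),
        alpha2_high=float(theta[1 + p]),
        alpha2_low=float(theta[2 + p]),
        beta2=theta[3 + p : 3 + 2 * p].copy(),
        gamma=theta[3 + 2 * p : 3 + 3 * p].copy(),
        covariate_names=tuple(names),
    )


def step3_loglik(
    structural: StructuralParams,
    W1: np.ndarray,
    W2: np.ndarray,
    X: np.ndarray | None,
    q1: ErrorMatrix,
    q2: ErrorMatrix,
) -> float:
    """Observed-data log-likelihood of the modal classes given fixed q."""
    W1 = np.asarray(W1, dtype=int)
    W2 = np.asarray(W2, dtype=int)
    if W1.shape != W2.shape:
        raise ValueError("W1 and W2 must be aligned")
    if X is not None:
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("covariates must be finite (impute first)")
        if X.shape[1] != structural.p:
            raise ValueError("covariate dimension mismatch")
    lik, _ = _unit_likelihood(_pack(structural), W1, W2, X, q1.q, q2.q)
    return float(np.log(np.maximum(lik, 1e-300)).sum())


# ---------------------------------------------------------------------------
# step 3 estimation


def _irls(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, coef: np.ndarray, n_iter: int = 30
) -> np.ndarray:
    """Weighted binary logistic Newton steps with fractional responses."""
    ridge = 1e-8
    for _ in range(n_iter):
        eta = np.clip(X @ coef, -30, 30)
        mu = expit(eta)
        grad = X.T @ (w * (y - mu))
        Wd = w * mu * (1 - mu) + 1e-12
        H = (X * Wd[:, None]).T @ X + ridge * np.eye(X.shape[1])
        step = np.linalg.solve(H, grad)
        coef = np.clip(coef + step, -LOGIT_CLAMP, LOGIT_CLAMP)
        if np.max(np.abs(step)) < 1e-10:
            break
    return coef


def fit_step3(
    W1: np.ndarray,
    W2: np.ndarray,
    X: np.ndarray | None,
    q1: ErrorMatrix,
    q2: ErrorMatrix,
    covariate_names: tuple[str, ...] = (),
    max_em_iter: int = 300,
    tol: float = 1e-9,
    compute_se: bool = True,
) -> LTAFit:
    """Maximize the step-3 likelihood over the structural parameters.

    EM over the latent (G1, G2) pair with weighted-logistic M-steps, polished
    by bounded quasi-Newton; covariates are standardized internally and the
    coefficients reported on the original scale.  Coefficients that reach the
    |15| logit clamp (separation, e.g. an empty transition cell) are flagged
    rather than treated as failures.
    """
    W1 = np.asarray(W1, dtype=int)
    W2 = np.asarray(W2, dtype=int)
    n = len(W1)
    if q1.K != 2 or q2.K != 2:
        raise ValueError("the structural model is defined for 2 classes per stage")
    for W, name in ((W1, "W1"), (W2, "W2")):
        if len(np.unique(W)) < 2:
            raise ValueError(f"{name} must contain both modal classes")

    if X is not None:
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("covariates must be finite (impute first)")
        x_mean = X.mean(axis=0)
        x_sd = X.std(axis=0)
        x_sd[x_sd == 0] = 1.0
        Z = (X - x_mean) / x_sd
        p = X.shape[1]
    else:
        Z = None
        x_mean = x_sd = np.zeros(0)
        p = 0

    # starting values: naive cross-tab of the modal classes
    eps = 0.5
    p1 = (np.sum(W1 == 0) + eps) / (n + 2 * eps)
    tab = np.array(
        [[np.sum((W1 == k) & (W2 == s)) for s in (0, 1)] for k in (0, 1)], float
    )
    trans = (tab + eps) / (tab + eps).sum(axis=1, keepdims=True)
    theta = np.zeros(3 + 3 * p)
    theta[0] = np.clip(np.log(p1 / (1 - p1)), -LOGIT_CLAMP, LOGIT_CLAMP)
    theta[1 + p] = np.clip(
        np.log(trans[0, 0] / trans[0, 1]), -LOGIT_CLAMP, LOGIT_CLAMP
    )
    theta[2 + p] = np.clip(
        np.log(trans[1, 0] / trans[1, 1]), -LOGIT_CLAMP, LOGIT_CLAMP
    )

    ones = np.ones(n)
    prev_ll = -np.inf
    for _ in range(max_em_iter):
        lik, terms = _unit_likelihood(theta, W1, W2, Z, q1.q, q2.q)
        ll = float(np.log(np.maximum(lik, 1e-300)).sum())
        post = terms / np.maximum(lik, 1e-300)[:, None]
        if abs(ll - prev_ll) < tol * (1 + abs(ll)):
            break
        prev_ll = ll

        # stage-1 block: fractional response P(G1 = high | data)
        u1 = post[:, 0] + post[:, 1]
        D1 = np.column_stack([ones, Z]) if p else ones[:, None]
        c1 = _irls(D1, u1, ones, theta[: 1 + p].copy())
        theta[: 1 + p] = c1

        # transition block: per origin stratum
        uH = post[:, 0] + post[:, 1]
        uL = post[:, 2] + post[:, 3]
        yH = post[:, 0] / np.maximum(uH, 1e-300)
        yL = post[:, 2] / np.maximum(uL, 1e-300)
        if p:
            DH = np.column_stack([ones, np.zeros(n), Z, np.zeros_like(Z)])
            DL = np.column_stack([np.zeros(n), ones, Z, Z])
            D2 = np.vstack([DH, DL])
        else:
            D2 = np.vstack(
                [np.column_stack([ones, np.zeros(n)]),
                 np.column_stack([np.zeros(n), ones])]
            )
        y2 = np.concatenate([yH, yL])
        w2 = np.concatenate([uH, uL])
        c2 = _irls(D2, y2, w2, theta[1 + p :].copy())
        theta[1 + p :] = c2

    def negll(th):
        lik, _ = _unit_likelihood(th, W1, W2, Z, q1.q, q2.q)
        return -float(np.log(np.maximum(lik, 1e-300)).sum())

    bounds = [(-LOGIT_CLAMP, LOGIT_CLAMP)] * len(theta)
    res = minimize(negll, theta, method="L-BFGS-B", bounds=bounds)
    if res.fun <= negll(theta):
        theta = res.x
    loglik = -negll(theta)
    converged = bool(res.success) or abs(prev_ll - loglik) < 1e-6 * (1 + abs(loglik))

    at_bound = np.abs(np.abs(theta) - LOGIT_CLAMP) < 1e-6
    labels = (
        ["alpha1"]
        + [f"beta1[{j}]" for j in range(p)]
        + ["alpha2_high", "alpha2_low"]
        + [f"beta2[{j}]" for j in range(p)]
        + [f"gamma[{j}]" for j in range(p)]
    )
    clamped = [labels[j] for j in np.flatnonzero(at_bound)]

    # covariance on the internal scale from the observed information
    se_internal = np.full(len(theta), np.nan)
    cov_internal = None
    if compute_se:
        free = ~at_bound
        H = _numerical_hessian(negll, theta)
        Hf = H[np.ix_(free, free)]
        try:
            covf = np.linalg.pinv(0.5 * (Hf + Hf.T))
            se_f = np.sqrt(np.maximum(np.diag(covf), 0.0))
            se_internal[free] = se_f
            cov_internal = np.full((len(theta), len(theta)), np.nan)
            cov_internal[np.ix_(free, free)] = covf
        except np.linalg.LinAlgError:
            pass

    # back-transform to the original covariate scale
    J = _standardization_jacobian(p, x_mean, x_sd)
    theta_orig = J @ theta
    structural = _unpack(theta_orig, p, covariate_names)
    ses = None
    if compute_se and cov_internal is not None:
        with np.errstate(invalid="ignore"):
            cov_orig = J @ np.nan_to_num(cov_internal, nan=0.0) @ J.T
            se_orig = np.sqrt(np.maximum(np.diag(cov_orig), 0.0))
        # clamped parameters have no meaningful SE
        bad = np.flatnonzero(np.isnan(se_internal))
        se_orig = se_orig.astype(float)
        se_orig[bad] = np.nan
        ses = _unpack(se_orig, p, covariate_names)

    # fitted summaries
    lik, terms = _unit_likelihood(theta, W1, W2, Z, q1.q, q2.q)
    post = terms / np.maximum(lik, 1e-300)[:, None]
    ent = model_selection.entropy(post)
    n_params = 3 + 3 * p
    minus2 = -2.0 * loglik

    # model-implied transition matrix at covariate means (Z = 0)
    tm = np.array(
        [
            [expit(theta[1 + p]), 1 - expit(theta[1 + p])],
            [expit(theta[2 + p]), 1 - expit(theta[2 + p])],
        ]
    )
    if p:
        s1h = float(expit(theta[0] + Z @ theta[1 : 1 + p]).mean())
    else:
        s1h = float(expit(theta[0]))
    stage1_props = np.array([s1h, 1 - s1h])

    combo_modal = post.argmax(axis=1)
    counts = np.bincount(combo_modal, minlength=4)
    combo_labels = [("High", "High"), ("High", "Low"), ("Low", "High"), ("Low", "Low")]
    table = []
    for j, (g1, g2) in enumerate(combo_labels):
        table.append(
            {
                "combination": j + 1,
                "stage1": g1,
                "stage2": g2,
                "count": int(counts[j]),
                "proportion": float(counts[j] / n),
                "transition_probability": float(tm[0 if g1 == "High" else 1, 0 if g2 == "High" else 1]),
            }
        )

    return LTAFit(
        structural=structural,
        loglik=loglik,
        bic=model_selection.bic(minus2, n_params, n),
        abic=model_selection.abic(minus2, n_params, n),
        entropy=ent,
        n_params=n_params,
        transition_matrix=tm,
        stage1_proportions=stage1_props,
        combination_table=table,
        joint_posterior=post,
        ses=ses,
        clamped=clamped,
        converged=converged,
    )


def _numerical_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian."""
    k = len(x)
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            xi = x.copy()
            if i == j:
                xi[i] = x[i] + h
                fp = f(xi)
                xi[i] = x[i] - h
                fm = f(xi)
                H[i, i] = (fp - 2 * f0 + fm) / h**2
            else:
                xi[i], xi[j] = x[i] + h, x[j] + h
                fpp = f(xi)
                xi[j] = x[j] - h
                fpm = f(xi)
                xi[i], xi[j] = x[i] - h, x[j] + h
                fmp = f(xi)
                xi[j] = x[j] - h
                fmm = f(xi)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h**2)
    return H


def _standardization_jacobian(p: int, x_mean: np.ndarray, x_sd: np.ndarray) -> np.ndarray:
    """Linear map from standardized-scale to original-scale parameters."""
    k = 3 + 3 * p
    J = np.eye(k)
    if p == 0:
        return J
    ms = x_mean / x_sd
    # alpha1 row
    J[0, 1 : 1 + p] = -ms
    for j in range(p):
        J[1 + j, 1 + j] = 1.0 / x_sd[j]
    # alpha2_high depends on beta2
    J[1 + p, 3 + p : 3 + 2 * p] = -ms
    # alpha2_low depends on beta2 + gamma
    J[2 + p, 3 + p : 3 + 2 * p] = -ms
    J[2 + p, 3 + 2 * p : 3 + 3 * p] = -ms
    for j in range(p):
        J[3 + p + j, 3 + p + j] = 1.0 / x_sd[j]
        J[3 + 2 * p + j, 3 + 2 * p + j] = 1.0 / x_sd[j]
    return J


def odds_ratios(structural: StructuralParams) -> dict[str, dict[str, float]]:
    """exp(coefficient) per block, keyed by covariate name."""
    names = structural.covariate_names or tuple(
        f"x{j + 1}" for j in range(structural.p)
    )
    out = {
        "stage1": {nm: math.exp(b) for nm, b in zip(names, structural.beta1)},
        "stage2": {nm: math.exp(b) for nm, b in zip(names, structural.beta2)},
        "transition": {nm: math.exp(b) for nm, b in zip(names, structural.gamma)},
    }
    return out


def wald_table(fit: LTAFit) -> list[dict]:
    """Per-coefficient estimate / SE / t / p / odds-ratio rows (three blocks)."""
    s, se = fit.structural, fit.ses
    names = s.covariate_names or tuple(f"x{j + 1}" for j in range(s.p))
    rows = []

    def add(block, name, est, sev, is_or=True):
        t = est / sev if (sev is not None and np.isfinite(sev) and sev > 0) else np.nan
        pval = 2 * (1 - norm.cdf(abs(t))) if np.isfinite(t) else np.nan
        rows.append(
            {
                "block": block,
                "term": name,
                "beta": float(est),
                "se": float(sev) if sev is not None else np.nan,
                "t": float(t),
                "p": float(pval),
                "odds_ratio": float(np.exp(est)) if is_or else np.nan,
                "significant_p001": bool(np.isfinite(pval) and pval < 0.001),
            }
        )

    add("stage1", "intercept", s.alpha1, se.alpha1 if se else np.nan, is_or=False)
    for j, nm in enumerate(names):
        add("stage1", nm, s.beta1[j], se.beta1[j] if se else np.nan)
    add("stage2", "intercept_high_origin", s.alpha2_high, se.alpha2_high if se else np.nan, is_or=False)
    add("stage2", "intercept_low_origin", s.alpha2_low, se.alpha2_low if se else np.nan, is_or=False)
    for j, nm in enumerate(names):
        add("stage2", nm, s.beta2[j], se.beta2[j] if se else np.nan)
    for j, nm in enumerate(names):
        add("transition", nm, s.gamma[j], se.gamma[j] if se else np.nan)
    return rows


def pool_step3_fits(fits: list[LTAFit]) -> dict[str, PooledEstimate]:
    """Rubin-rules pooling of structural coefficients across imputations."""
    if len(fits) < 2:
        raise ValueError("pooling needs at least 2 fits")
    out: dict[str, PooledEstimate] = {}
    names = fits[0].structural.covariate_names or tuple(
        f"x{j + 1}" for j in range(fits[0].structural.p)
    )

    def collect(label, getter):
        est = [getter(f.structural) for f in fits]
        ses_ = [getter(f.ses) if f.ses is not None else np.nan for f in fits]
        if np.all(np.isfinite(ses_)):
            out[label] = pool_rubin(est, ses_)

    collect("alpha1", lambda s: s.alpha1)
    collect("alpha2_high", lambda s: s.alpha2_high)
    collect("alpha2_low", lambda s: s.alpha2_low)
    for j, nm in enumerate(names):
        collect(f"beta1.{nm}", lambda s, j=j: s.beta1[j])
        collect(f"beta2.{nm}", lambda s, j=j: s.beta2[j])
        collect(f"gamma.{nm}", lambda s, j=j: s.gamma[j])
    return out
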