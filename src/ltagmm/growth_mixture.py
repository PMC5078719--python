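"""Finite mixture of linear latent growth curves, fitted by EM.

This is the measurement model of each stage: within class c the indicator
vector follows y = L eta + e with growth factors eta = (INT, SLP) ~
N(mu_c, Psi_c), loadings L = [1, t] built from the stage time scores, and
independent residuals e_t ~ N(0, theta_t).  Marginally y is a K-component
Gaussian mixture; missing indicator entries are handled by full-information
likelihood (each unit contributes the density of its observed sub-vector).

The EM treats both the class label and the growth factors as missing data:
the E-step computes class responsibilities and within-class posterior factor
moments by Gaussian conditioning, the M-step updates weights, factor means /
covariances and residual variances in closed form (the optional shared
intercept-slope covariance across classes uses a bounded quasi-Newton update
of the expected complete-data log-likelihood, accepted only on improvement,
so the EM ascent property is preserved).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import minimize

from .panel_io import PanelDataset

__all__ = [
    "StageSpec",
    "GMMParams",
    "GMMFit",
    "EStepResult",
    "EmptyClassError",
    "EstimationError",
    "implied_moments",
    "marginal_loglik",
    "e_step",
    "m_step",
    "fit_gmm",
    "count_params",
    "canonicalize",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_THETA_FLOOR = 1e-8
_DEGENERATE_WEIGHT = 1e-4


class EmptyClassError(RuntimeError):
    """A class lost essentially all posterior mass during the M-step."""


class EstimationError(RuntimeError):
    """No random start produced a usable solution."""


@dataclass(frozen=True)
class StageSpec:
    """Indicator set and time scores of one developmental stage.

    ``time_scores`` are years from the stage origin; the first must be 0 so
    the intercept is the status at stage entry.
    """

    stage_id: int
    indicators: tuple[str, ...]
    time_scores: tuple[float, ...]
    K: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "indicators", tuple(self.indicators))
        object.__setattr__(self, "time_scores", tuple(float(t) for t in self.time_scores))
        if len(self.indicators) != len(self.time_scores):
            raise ValueError("indicators and time_scores must have equal length")
        if len(self.time_scores) < 2:
            raise ValueError("a stage needs at least 2 indicators")
        if self.time_scores[0] != 0.0:
            raise ValueError("first time score must be 0 (stage origin)")
        if any(b <= a for a, b in zip(self.time_scores, self.time_scores[1:])):
            raise ValueError("time scores must be strictly increasing")
        if self.K < 1:
            raise ValueError("K must be >= 1")

    @property
    def T(self) -> int:
        return len(self.indicators)

    @property
    def loadings(self) -> np.ndarray:
        """Design matrix Lambda = [1, t], shape (T, 2)."""
        t = np.asarray(self.time_scores)
        return np.column_stack([np.ones_like(t), t])


@dataclass
class GMMParams:
    """Mixture-of-growth-curves parameters for one stage.

    weights : (K,) class mixing proportions, positive, summing to 1.
    means : (K, 2) per-class (INT, SLP) means.
    covs : (K, 2, 2) per-class factor covariances, symmetric PSD.
    resid_var : (K, T) residual variances per class and indicator (rows are
        identical when residuals are shared across classes).
    """

    weights: np.ndarray
    means: np.ndarray
    covs: np.ndarray
    resid_var: np.ndarray
    cov_equal_across_classes: bool = True
    residuals_equal_across_classes: bool = True

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float).reshape(self.K, 2)
        self.covs = np.asarray(self.covs, dtype=float).reshape(self.K, 2, 2)
        rv = np.asarray(self.resid_var, dtype=float)
        if rv.ndim == 1:
            rv = np.tile(rv, (self.K, 1))
        self.resid_var = rv
        self.validate()

    @property
    def K(self) -> int:
        return self.weights.size

    def validate(self) -> None:
        if np.any(self.weights <= 0) or abs(self.weights.sum() - 1.0) > 1e-6:
            raise ValueError("class weights must be positive and sum to 1")
        for c in range(self.K):
            S = self.covs[c]
            if not np.allclose(S, S.T, atol=1e-8):
                raise ValueError("factor covariance must be symmetric")
            if np.linalg.eigvalsh(S).min() < -1e-8:
                raise ValueError("factor covariance must be positive semi-definite")
        if np.any(self.resid_var <= 0):
            raise ValueError("residual variances must be positive")
        if self.cov_equal_across_classes:
            off = self.covs[:, 0, 1]
            if np.max(np.abs(off - off[0])) > 1e-6:
                raise ValueError(
                    "cov_equal_across_classes set but INT-SLP covariances differ"
                )


@dataclass
class EStepResult:
    """E-step output: responsibilities plus posterior factor moments.

    The posterior factor covariance depends only on the missingness pattern
    and the class, so it is stored per pattern; ``post_cov`` materializes the
    per-unit (n, K, 2, 2) array on demand.
    """

    loglik: float
    responsibilities: np.ndarray  # (n, K)
    post_mean: np.ndarray  # (n, K, 2) E[eta | y, c]
    patterns: list  # [(obs_mask (T,), idx (m,)), ...]
    pattern_cov: np.ndarray  # (P, K, 2, 2) Cov[eta | y, c] per pattern

    @property
    def post_cov(self) -> np.ndarray:
        n, K = self.responsibilities.shape
        out = np.empty((n, K, 2, 2))
        for pi, (_, idx) in enumerate(self.patterns):
            out[idx] = self.pattern_cov[pi]
        return out


@dataclass
class GMMFit:
    params: GMMParams
    loglik: float
    responsibilities: np.ndarray
    n_params: int
    converged: bool
    n_iter: int
    best_start_seed: int
    loglik_trace: np.ndarray
    degenerate: bool = False

    def to_dict(self) -> dict:
        p = self.params
        return {
            "weights": p.weights.tolist(),
            "means": p.means.tolist(),
            "covs": p.covs.tolist(),
            "resid_var": p.resid_var.tolist(),
            "cov_equal_across_classes": p.cov_equal_across_classes,
            "residuals_equal_across_classes": p.residuals_equal_across_classes,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "best_start_seed": self.best_start_seed,
            "degenerate": self.degenerate,
            "loglik_trace": np.asarray(self.loglik_trace).tolist(),
        }


# ---------------------------------------------------------------------------
# moments and likelihood


def implied_moments(
    params: GMMParams, spec: StageSpec, class_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied indicator mean and covariance of one class.

    mean = L mu_c, covariance = L Psi_c L' + diag(theta_c).
    """
    if not 0 <= class_index < params.K:
        raise IndexError("class_index out of range")
    L = spec.loadings
    mu = L @ params.means[class_index]
    cov = L @ params.covs[class_index] @ L.T + np.diag(params.resid_var[class_index])
    return mu, cov


def _as_matrix(data: PanelDataset | np.ndarray, spec: StageSpec) -> np.ndarray:
    if isinstance(data, PanelDataset):
        return data.values(spec.indicators)
    Y = np.asarray(data, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != spec.T:
        raise ValueError(f"expected (n, {spec.T}) indicator matrix")
    return Y


def _pattern_groups(Y: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group row indices by missingness pattern; returns (obs_mask, idx) pairs."""
    obs = ~np.isnan(Y)
    if obs.all():
        return [(np.ones(Y.shape[1], dtype=bool), np.arange(len(Y)))]
    keys = {}
    for i, row in enumerate(obs):
        keys.setdefault(row.tobytes(), []).append(i)
    return [
        (np.frombuffer(k, dtype=bool).copy(), np.asarray(v)) for k, v in keys.items()
    ]


def _e_step_matrix(params: GMMParams, spec: StageSpec, Y: np.ndarray) -> EStepResult:
    n, T = Y.shape
    K = params.K
    L = spec.loadings
    log_dens = np.full((n, K), -np.inf)
    post_mean = np.zeros((n, K, 2))
    patterns = _pattern_groups(Y)
    pattern_cov = np.zeros((len(patterns), K, 2, 2))

    for pi, (o, idx) in enumerate(patterns):
        if not o.any():
            raise ValueError(
                f"{len(idx)} unit(s) have no observed indicators for stage "
                f"{spec.stage_id}; drop them before fitting"
            )
        Lo = L[o]
        Yo = Y[np.ix_(idx, np.flatnonzero(o))]
        To = int(o.sum())
        for c in range(K):
            Psi = params.covs[c]
            Sig = Lo @ Psi @ Lo.T + np.diag(params.resid_var[c][o])
            try:
                chol = np.linalg.cholesky(Sig)
            except np.linalg.LinAlgError:
                chol = np.linalg.cholesky(Sig + 1e-10 * np.eye(To))
            dev = Yo - Lo @ params.means[c]
            sol = solve_triangular(chol, dev.T, lower=True, check_finite=False)
            quad = np.einsum("ij,ij->j", sol, sol)
            logdet = 2.0 * np.log(np.diag(chol)).sum()
            log_dens[idx, c] = -0.5 * (To * _LOG2PI + logdet + quad)
            # posterior factor moments by Gaussian conditioning (gain form,
            # valid for singular Psi)
            G = Psi @ Lo.T @ np.linalg.inv(Sig)  # (2, To)
            post_mean[idx, c] = params.means[c] + dev @ G.T
            V = Psi - G @ Lo @ Psi
            pattern_cov[pi, c] = 0.5 * (V + V.T)

    logw = np.log(params.weights)
    joint = log_dens + logw
    m = joint.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(joint - m).sum(axis=1))
    resp = np.exp(joint - lse[:, None])
    resp /= resp.sum(axis=1, keepdims=True)
    return EStepResult(float(lse.sum()), resp, post_mean, patterns, pattern_cov)


def marginal_loglik(
    params: GMMParams, spec: StageSpec, data: PanelDataset | np.ndarray
) -> float:
    """Observed-data mixture log-likelihood (full information over missing cells)."""
    return _e_step_matrix(params, spec, _as_matrix(data, spec)).loglik


def e_step(
    params: GMMParams, spec: StageSpec, data: PanelDataset | np.ndarray
) -> EStepResult:
    """Responsibilities and per-class posterior factor moments."""
    return _e_step_matrix(params, spec, _as_matrix(data, spec))


# ---------------------------------------------------------------------------
# M-step


def _constrained_cov_update(
    S: np.ndarray, Nk: np.ndarray, prev: np.ndarray | None, refine: bool = True
) -> np.ndarray:
    """Shared-offdiagonal factor covariances improving the expected
    complete-data log-likelihood (GEM step).

    Candidates: the previous covariances (guaranteeing the EM ascent
    property), the unconstrained scatter projected onto the shared-covariance
    set, and — when ``refine`` is set — a bounded quasi-Newton pass with
    analytic gradient started from the better of the two.  The best candidate
    under the expected complete-data criterion wins, so the observed
    log-likelihood never decreases.

    S : (K, 2, 2) responsibility-weighted posterior scatter per class.
    """
    K = len(Nk)
    S00, S01, S11 = S[:, 0, 0], S[:, 0, 1], S[:, 1, 1]

    def pack(covs):
        return np.concatenate([covs[:, 0, 0], covs[:, 1, 1], [covs[:, 0, 1].mean()]])

    def unpack(x):
        covs = np.empty((K, 2, 2))
        covs[:, 0, 0] = x[:K]
        covs[:, 1, 1] = x[K : 2 * K]
        covs[:, 0, 1] = covs[:, 1, 0] = x[2 * K]
        return covs

    def fg(x):
        a, b, rho = x[:K], x[K : 2 * K], x[2 * K]
        det = a * b - rho**2
        if np.any(det <= 1e-14) or np.any(a <= 0) or np.any(b <= 0):
            return 1e12, np.zeros_like(x)
        tr = (b * S00 - 2 * rho * S01 + a * S11) / det
        f = 0.5 * float(np.sum(Nk * (np.log(det) + tr)))
        ga = 0.5 * Nk * (b + S11 - tr * b) / det
        gb = 0.5 * Nk * (a + S00 - tr * a) / det
        gr = float(np.sum(Nk * (-rho - S01 + tr * rho) / det))
        return f, np.concatenate([ga, gb, [gr]])

    def objective(x):
        return fg(x)[0]

    proj = S.copy()
    rho = float(np.average(S[:, 0, 1], weights=Nk))
    proj[:, 0, 1] = proj[:, 1, 0] = rho
    candidates = [pack(proj)]
    if prev is not None:
        candidates.append(pack(prev))
    best = min(candidates, key=objective)
    if refine:
        bounds = [(1e-8, None)] * (2 * K) + [(None, None)]
        res = minimize(fg, best, jac=True, method="L-BFGS-B", bounds=bounds)
        if np.isfinite(res.fun) and objective(res.x) < objective(best):
            best = res.x
    return unpack(best)


def m_step(
    data: PanelDataset | np.ndarray,
    spec: StageSpec,
    estep: EStepResult,
    cov_equal_across_classes: bool = True,
    residuals_equal_across_classes: bool = True,
    prev_covs: np.ndarray | None = None,
    refine_cov: bool = True,
) -> GMMParams:
    """Closed-form responsibility-weighted parameter updates.

    ``prev_covs`` (the previous iteration's factor covariances) is used as a
    fallback candidate by the shared-covariance GEM update so the observed
    log-likelihood can never decrease.
    """
    Y = _as_matrix(data, spec)
    n, T = Y.shape
    resp = estep.responsibilities
    K = resp.shape[1]
    L = spec.loadings

    Nk = resp.sum(axis=0)
    if np.any(Nk < 1e-8):
        raise EmptyClassError(f"class weights collapsed: {Nk / n}")
    weights = Nk / n

    means = np.einsum("ik,ikf->kf", resp, estep.post_mean) / Nk[:, None]
    scatter = np.zeros((K, 2, 2))
    for c in range(K):
        dev = estep.post_mean[:, c, :] - means[c]
        wdev = resp[:, c][:, None] * dev
        scatter[c] = wdev.T @ dev
    for pi, (_, idx) in enumerate(estep.patterns):
        w = resp[idx].sum(axis=0)  # (K,)
        scatter += w[:, None, None] * estep.pattern_cov[pi]
    scatter /= Nk[:, None, None]
    scatter = 0.5 * (scatter + scatter.transpose(0, 2, 1))

    if cov_equal_across_classes and K > 1:
        covs = _constrained_cov_update(scatter, Nk, prev_covs, refine=refine_cov)
    else:
        covs = scatter

    # residual variances over observed cells
    num = np.zeros((K, T))
    den = np.zeros((K, T))
    for pi, (o, idx) in enumerate(estep.patterns):
        Lo = L[o]
        cols = np.flatnonzero(o)
        Yo = Y[np.ix_(idx, cols)]
        for c in range(K):
            pred = estep.post_mean[idx, c, :] @ Lo.T
            extra = np.einsum(
                "tf,fg,tg->t", Lo, estep.pattern_cov[pi, c], Lo
            )  # diag(Lo V Lo'), constant over units in the pattern
            r = resp[idx, c]
            num[c, cols] += r @ ((Yo - pred) ** 2) + r.sum() * extra
            den[c, cols] += r.sum()
    if residuals_equal_across_classes:
        theta = num.sum(axis=0) / np.maximum(den.sum(axis=0), 1e-12)
        resid = np.tile(np.maximum(theta, _THETA_FLOOR), (K, 1))
    else:
        resid = np.maximum(num / np.maximum(den, 1e-12), _THETA_FLOOR)

    return GMMParams(
        weights=weights,
        means=means,
        covs=covs,
        resid_var=resid,
        cov_equal_across_classes=cov_equal_across_classes and K > 1,
        residuals_equal_across_classes=residuals_equal_across_classes,
    )


# ---------------------------------------------------------------------------
# driver


def count_params(
    spec: StageSpec,
    cov_equal_across_classes: bool = True,
    residuals_equal_across_classes: bool = True,
) -> int:
    """Free-parameter count: weights + growth means + factor (co)variances +
    residual variances under the equality constraints."""
    K, T = spec.K, spec.T
    p = (K - 1) + 2 * K
    p += 2 * K + 1 if (cov_equal_across_classes and K > 1) else 3 * K
    p += T if residuals_equal_across_classes else K * T
    return p


def canonicalize(params: GMMParams) -> tuple[GMMParams, np.ndarray]:
    """Relabel classes: descending weight, ties broken by ascending intercept
    mean.  Returns (relabeled params, permutation old->new order)."""
    order = np.lexsort((params.means[:, 0], -np.round(params.weights, 12)))
    return (
        dataclasses.replace(
            params,
            weights=params.weights[order],
            means=params.means[order],
            covs=params.covs[order],
            resid_var=params.resid_var[order],
        ),
        order,
    )


def _init_params(
    Y: np.ndarray,
    spec: StageSpec,
    rng: np.random.Generator,
    cov_equal: bool,
    resid_equal: bool,
) -> GMMParams:
    """Random-partition responsibilities perturbed by Dirichlet noise, mapped
    to parameters through one M-step."""
    n = len(Y)
    K = spec.K
    hard = np.zeros((n, K))
    hard[np.arange(n), rng.integers(K, size=n)] = 1.0
    resp = 0.7 * hard + 0.3 * rng.dirichlet(np.ones(K), size=n)
    resp /= resp.sum(axis=1, keepdims=True)

    # crude per-unit OLS growth factors on observed cells for moment seeding
    L = spec.loadings
    mu0 = np.nanmean(Y, axis=0)
    coef, *_ = np.linalg.lstsq(L, mu0, rcond=None)
    var0 = np.nanvar(Y, axis=0).mean()
    post_mean = np.tile(coef, (n, K, 1)) + 0.1 * rng.standard_normal((n, K, 2))
    patterns = _pattern_groups(Y)
    pattern_cov = np.tile(0.1 * var0 * np.eye(2), (len(patterns), K, 1, 1))
    est = EStepResult(-np.inf, resp, post_mean, patterns, pattern_cov)
    return m_step(Y, spec, est, cov_equal, resid_equal)


def _pack_params(p: GMMParams) -> np.ndarray:
    return np.concatenate(
        [p.weights, p.means.ravel(), p.covs.reshape(p.K, 4)[:, [0, 3, 1]].ravel(),
         p.resid_var.ravel()]
    )


def _unpack_params(x: np.ndarray, template: GMMParams) -> GMMParams:
    """Vector -> params with repairs (simplex weights, PSD covariances,
    positive residuals); used by the accelerated-EM extrapolation."""
    K = template.K
    T = template.resid_var.shape[1]
    w = np.clip(x[:K], 1e-8, None)
    w = w / w.sum()
    means = x[K : 3 * K].reshape(K, 2)
    cv = x[3 * K : 6 * K].reshape(K, 3)
    covs = np.empty((K, 2, 2))
    covs[:, 0, 0] = np.clip(cv[:, 0], 1e-10, None)
    covs[:, 1, 1] = np.clip(cv[:, 1], 1e-10, None)
    rho = cv[:, 2]
    lim = 0.999 * np.sqrt(covs[:, 0, 0] * covs[:, 1, 1])
    if template.cov_equal_across_classes and K > 1:
        rho = np.full(K, np.clip(rho.mean(), -lim.min(), lim.min()))
    else:
        rho = np.clip(rho, -lim, lim)
    covs[:, 0, 1] = covs[:, 1, 0] = rho
    resid = np.clip(x[6 * K :].reshape(K, T), _THETA_FLOOR, None)
    if template.residuals_equal_across_classes:
        resid = np.tile(resid.mean(axis=0), (K, 1))
    return dataclasses.replace(
        template, weights=w, means=means, covs=covs, resid_var=resid
    )


def _run_em(
    Y: np.ndarray,
    spec: StageSpec,
    params: GMMParams,
    tol: float,
    max_iter: int,
    cov_equal: bool,
    resid_equal: bool,
    trace: list[float],
    accelerate: bool = True,
) -> tuple[GMMParams, EStepResult, bool, int]:
    """EM with an optional SQUAREM-style extrapolation step.

    Each cycle takes two plain EM steps; the squared-iteration extrapolation
    candidate is accepted only when it does not lower the observed
    log-likelihood, so the retained trace stays non-decreasing (plain EM is
    the fallback).  ``it`` counts EM map evaluations.
    """
    def em_update(p, est, refine):
        p2 = m_step(Y, spec, est, cov_equal, resid_equal,
                    prev_covs=p.covs, refine_cov=refine)
        return p2, _e_step_matrix(p2, spec, Y)

    prev = -np.inf
    est = _e_step_matrix(params, spec, Y)
    converged = False
    it = 0
    cycle = 0
    while it < max_iter:
        cycle += 1
        # the shared-covariance quasi-Newton refinement is only needed near
        # a stationary point; the cheap GEM candidates keep monotonicity on
        # every other iteration
        refine = cov_equal and (cycle % 10 == 0)
        p1, e1 = em_update(params, est, refine)
        it += 1
        if accelerate and it < max_iter:
            p2, e2 = em_update(p1, e1, refine)
            it += 1
            x0, x1, x2 = _pack_params(params), _pack_params(p1), _pack_params(p2)
            r = x1 - x0
            v = (x2 - x1) - r
            vnorm = np.linalg.norm(v)
            params_new, est_new = p2, e2
            if vnorm > 1e-12:
                alpha = -max(1.0, np.linalg.norm(r) / vnorm)
                try:
                    cand = _unpack_params(x0 - 2 * alpha * r + alpha**2 * v, p2)
                    # stabilize the extrapolation with one EM step
                    cand, est_c = em_update(cand, _e_step_matrix(cand, spec, Y), refine)
                    it += 1
                    if est_c.loglik >= e2.loglik:
                        params_new, est_new = cand, est_c
                except (EmptyClassError, np.linalg.LinAlgError, ValueError):
                    pass
        else:
            params_new, est_new = p1, e1

        if est_new.loglik + 1e-7 * (1.0 + abs(est_new.loglik)) < prev:
            raise AssertionError(
                f"EM log-likelihood decreased: {prev} -> {est_new.loglik}"
            )
        params, est = params_new, est_new
        trace.append(est.loglik)
        if abs(est.loglik - prev) < tol:
            if cov_equal and not refine:
                params, est = em_update(params, est, True)
                it += 1
                trace.append(est.loglik)
                if abs(est.loglik - prev) >= tol:
                    prev = est.loglik
                    continue
            converged = True
            break
        prev = est.loglik
    return params, est, converged, it


def fit_gmm(
    data: PanelDataset | np.ndarray,
    spec: StageSpec,
    n_starts: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    cov_equal_across_classes: bool = True,
    residuals_equal_across_classes: bool = True,
    burn_in_iter: int = 50,
    n_final: int = 3,
) -> GMMFit:
    """Best-log-likelihood growth mixture over ``n_starts`` random starts.

    Every start runs a short EM burn-in; the ``n_final`` best continue to
    convergence (loglik change < ``tol``) and the winner is retained, with
    classes relabeled canonically (descending weight, then ascending
    intercept mean).
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    Y = _as_matrix(data, spec)
    seed_rng = np.random.default_rng(seed)
    start_seeds = seed_rng.integers(0, 2**31 - 1, size=n_starts)

    stage1: list[tuple[float, int, GMMParams, list[float]]] = []
    failures: list[str] = []
    for s in start_seeds:
        rng = np.random.default_rng(int(s))
        try:
            params = _init_params(
                Y, spec, rng, cov_equal_across_classes, residuals_equal_across_classes
            )
            trace: list[float] = []
            params, est, _, _ = _run_em(
                Y, spec, params, tol, burn_in_iter,
                cov_equal_across_classes, residuals_equal_across_classes, trace,
            )
            stage1.append((est.loglik, int(s), params, trace))
        except (EmptyClassError, np.linalg.LinAlgError) as exc:
            failures.append(f"start {s}: {exc}")
    if not stage1:
        raise EstimationError(
            "all random starts failed; diagnostics: " + "; ".join(failures[:5])
        )

    stage1.sort(key=lambda r: -r[0])
    best = None
    for loglik0, s, params, trace in stage1[: max(1, n_final)]:
        try:
            params, est, converged, it = _run_em(
                Y, spec, params, tol, max_iter,
                cov_equal_across_classes, residuals_equal_across_classes, trace,
            )
        except (EmptyClassError, np.linalg.LinAlgError):
            continue
        cand = (est.loglik, s, params, est, converged, len(trace), trace)
        if best is None or cand[0] > best[0]:
            best = cand
    if best is None:
        raise EstimationError("all refined starts degenerated")

    loglik, s, params, est, converged, n_iter, trace = best
    params, order = canonicalize(params)
    resp = est.responsibilities[:, order]
    return GMMFit(
        params=params,
        loglik=loglik,
        responsibilities=resp,
        n_params=count_params(
            spec, cov_equal_across_classes, residuals_equal_across_classes
        ),
        converged=converged,
        n_iter=n_iter,
        best_start_seed=s,
        loglik_trace=np.asarray(trace),
        degenerate=bool(np.min(params.weights) < _DEGENERATE_WEIGHT),
    )
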