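"""Information criteria, classification entropy, and class enumeration.

Class enumeration mirrors the usual mixture workflow: fit each candidate K,
tabulate -2LL / BIC / aBIC / entropy, and pick the minimum-aBIC model among
candidates whose smallest class is empirically meaningful (default >= 5% of
the sample) and non-degenerate.  aBIC is the primary index; an entropy below
0.6 is surfaced as a warning, not a gate.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .growth_mixture import GMMFit, StageSpec, fit_gmm
from .panel_io import PanelDataset

__all__ = ["SelectionRecord", "bic", "abic", "entropy", "enumerate_classes"]

ENTROPY_WARN_LEVEL = 0.6


def bic(minus2LL: float, p: int, n: int) -> float:
    """Bayesian information criterion: -2LL + p ln n."""
    if n < 1 or p < 0:
        raise ValueError("need n >= 1 and p >= 0")
    return minus2LL + p * math.log(n)


def abic(minus2LL: float, p: int, n: int) -> float:
    """Sample-size-adjusted BIC: the penalty uses (n + 2) / 24 in place of n."""
    if n < 1:
        raise ValueError("need n >= 1")
    return minus2LL + p * math.log((n + 2) / 24.0)


def entropy(responsibilities: np.ndarray) -> float:
    """Normalized classification certainty, 1 - sum(-p ln p) / (n ln K).

    1 means every unit is assigned with certainty; 0 means uniform
    responsibilities.  Undefined for K = 1: returns NaN as a sentinel.
    """
    p = np.asarray(responsibilities, dtype=float)
    n, K = p.shape
    if K < 2:
        return math.nan
    if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("responsibility rows must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, -p * np.log(p), 0.0)
    return 1.0 - float(plogp.sum()) / (n * math.log(K))


@dataclass(frozen=True)
class SelectionRecord:
    """One row of the model-comparison table."""

    model_label: str
    K: int
    minus2LL: float
    bic: float
    abic: float
    entropy: float
    n_params: int
    class_proportions: tuple[float, ...]
    degenerate: bool
    converged: bool
    warning: str = ""

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_proportions"] = list(self.class_proportions)
        return d


def enumerate_classes(
    data: PanelDataset | np.ndarray,
    spec_template: StageSpec,
    k_range,
    min_class_prop: float = 0.05,
    **fit_options,
) -> tuple[list[SelectionRecord], int, dict[int, GMMFit]]:
    """Fit the growth mixture for each K in ``k_range`` and select a model.

    Returns (records, selected K, fits).  Selection: minimum aBIC among
    non-degenerate candidates whose smallest class proportion passes the
    screen; if every candidate fails, fall back to the smallest K with a
    warning on its record.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range must be nonempty")
    records: list[SelectionRecord] = []
    fits: dict[int, GMMFit] = {}
    n = data.n if isinstance(data, PanelDataset) else len(data)
    for K in ks:
        spec = dataclasses.replace(spec_template, K=K)
        fit = fit_gmm(data, spec, **fit_options)
        fits[K] = fit
        minus2 = -2.0 * fit.loglik
        ent = entropy(fit.responsibilities) if K > 1 else math.nan
        warn = ""
        if K > 1 and ent < ENTROPY_WARN_LEVEL:
            warn = f"entropy {ent:.3f} below adequacy level {ENTROPY_WARN_LEVEL}"
        records.append(
            SelectionRecord(
                model_label=f"GMM_{K}c",
                K=K,
                minus2LL=minus2,
                bic=bic(minus2, fit.n_params, n),
                abic=abic(minus2, fit.n_params, n),
                entropy=ent,
                n_params=fit.n_params,
                class_proportions=tuple(float(w) for w in fit.params.weights),
                degenerate=fit.degenerate,
                converged=fit.converged,
                warning=warn,
            )
        )

    eligible = [
        r
        for r in records
        if not r.degenerate and min(r.class_proportions) >= min_class_prop
    ]
    if eligible:
        selected = min(eligible, key=lambda r: r.abic).K
    else:
        selected = ks[0]
        records[0] = dataclasses.replace(
            records[0],
            warning=(records[0].warning + "; " if records[0].warning else "")
            + "all candidates failed the class-size screen; fell back to smallest K",
        )
    return records, selected, fits
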