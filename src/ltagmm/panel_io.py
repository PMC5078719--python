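"""Wide-format longitudinal panel: data model, I/O, missingness, multiple imputation.

One row per child; repeated ability scores (IRT-scale) plus time-invariant
covariates (parent rating, teacher rating, SES, poverty).  Missing cells are
stored as NaN, so a cell is either observed-with-value or missing, never both.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelDataset",
    "MissingSummary",
    "PooledEstimate",
    "PanelFormatError",
    "PanelParseError",
    "load_panel",
    "write_panel",
    "summarize_missingness",
    "impute_multiply",
    "pool_rubin",
]

#: canonical covariate order used throughout the package
COVARIATE_NAMES = ("parent_rating", "teacher_rating", "ses", "poverty")


class PanelFormatError(ValueError):
    """A required column is absent or the table shape is inconsistent."""


class PanelParseError(ValueError):
    """A cell could not be parsed as a number or missing-value token."""


@dataclass
class PanelDataset:
    """Wide longitudinal table: indicators + covariates, NaN marks missing.

    Parameters
    ----------
    data
        One row per unit.  Must contain ``unit_col`` plus every indicator and
        covariate column; analysis columns are float with NaN for missing.
    indicator_cols
        Ordered repeated-measure columns (e.g. ``y1..y6``, or ``y1,y2,y3a,
        y3b,y4..y6`` when the stage knot is duplicated).
    covariate_cols
        Time-invariant covariate columns.
    truth
        Optional frame of generating quantities (class labels ``g1``/``g2``,
        latent growth factors, pre-masking indicator values); present only for
        synthetic panels.
    """

    data: pd.DataFrame
    indicator_cols: tuple[str, ...]
    covariate_cols: tuple[str, ...] = COVARIATE_NAMES
    truth: pd.DataFrame | None = None
    unit_col: str = "unit_id"

    def __post_init__(self) -> None:
        self.indicator_cols = tuple(self.indicator_cols)
        self.covariate_cols = tuple(self.covariate_cols)
        missing = [
            c
            for c in (self.unit_col, *self.indicator_cols, *self.covariate_cols)
            if c not in self.data.columns
        ]
        if missing:
            raise PanelFormatError(f"panel is missing column(s): {missing}")
        for c in self.analysis_cols:
            if not np.issubdtype(self.data[c].dtype, np.number):
                raise PanelFormatError(f"column {c!r} is not numeric")
        if self.truth is not None and len(self.truth) != len(self.data):
            raise PanelFormatError("truth block length differs from data length")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def analysis_cols(self) -> tuple[str, ...]:
        return self.indicator_cols + self.covariate_cols

    def values(self, cols: Sequence[str]) -> np.ndarray:
        """Float matrix (n, len(cols)) with NaN for missing cells."""
        for c in cols:
            if c not in self.data.columns:
                raise KeyError(f"unknown panel variable {c!r}")
        return self.data.loc[:, list(cols)].to_numpy(dtype=float)

    def mask(self, cols: Sequence[str]) -> np.ndarray:
        """Boolean matrix, True where the cell is missing."""
        return np.isnan(self.values(cols))

    def replace_values(self, cols: Sequence[str], values: np.ndarray) -> "PanelDataset":
        df = self.data.copy()
        df.loc[:, list(cols)] = values
        return dataclasses.replace(self, data=df)


@dataclass(frozen=True)
class MissingSummary:
    per_variable_rate: dict[str, float]
    overall_rate: float
    n_units_any_missing: int


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin-rules combination of one scalar across m imputations."""

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    se: float
    m: int


# ---------------------------------------------------------------------------
# I/O


def load_panel(
    path,
    column_map: Mapping[str, str] | None = None,
    indicator_cols: Sequence[str] | None = None,
    covariate_cols: Sequence[str] = COVARIATE_NAMES,
    unit_col: str = "unit_id",
) -> PanelDataset:
    """Read a delimited wide-format panel.

    ``column_map`` maps canonical names to file headers ({"y1": "C1SCORE"}).
    Empty cells and the literal token ``NA`` are read as missing.  Indicator
    columns default to every canonical name starting with ``y``.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    column_map = dict(column_map or {})
    rename = {v: k for k, v in column_map.items()}
    absent = [v for v in column_map.values() if v not in raw.columns]
    if absent:
        raise PanelFormatError(f"mapped column(s) not in file: {absent}")
    raw = raw.rename(columns=rename)

    if indicator_cols is None:
        indicator_cols = [c for c in raw.columns if c.startswith("y")]
    analysis = [*indicator_cols, *covariate_cols]
    for c in analysis:
        if c not in raw.columns:
            raise PanelFormatError(f"required column {c!r} not found in file")

    df = raw.copy()
    if unit_col not in df.columns:
        df[unit_col] = np.arange(len(df))
    for c in analysis:
        cleaned = df[c].str.strip().replace({"": None, "NA": None})
        numeric = pd.to_numeric(cleaned, errors="coerce")
        bad = numeric.isna() & cleaned.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise PanelParseError(
                f"non-numeric cell in column {c!r} at row {row}: {cleaned.iloc[row]!r}"
            )
        df[c] = numeric.astype(float)
    return PanelDataset(
        data=df[[unit_col, *analysis]],
        indicator_cols=tuple(indicator_cols),
        covariate_cols=tuple(covariate_cols),
        unit_col=unit_col,
    )


def load_column_map(path) -> dict[str, str]:
    """Read a ``columns:`` mapping (canonical name -> file header) from a
    YAML or JSON config file."""
    import json

    import yaml

    text = open(path).read()
    doc = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    if not isinstance(doc, dict) or "columns" not in doc:
        raise PanelFormatError(f"{path}: expected a mapping with a 'columns' section")
    cols = doc["columns"]
    if not isinstance(cols, dict):
        raise PanelFormatError(f"{path}: 'columns' must map names to headers")
    return {str(k): str(v) for k, v in cols.items()}


def write_panel(dataset: PanelDataset, path, truth_path=None) -> None:
    """Write the panel as CSV (empty cell = missing); optionally the truth block."""
    dataset.data.to_csv(path, index=False, na_rep="")
    if truth_path is not None and dataset.truth is not None:
        dataset.truth.to_csv(truth_path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Missingness summary


def summarize_missingness(
    dataset: PanelDataset, variables: Sequence[str] | None = None
) -> MissingSummary:
    """Per-variable and overall missing-cell fractions over ``variables``."""
    if variables is None:
        variables = dataset.analysis_cols
    variables = list(variables)
    if not variables:
        raise ValueError("variables must be nonempty")
    mask = dataset.mask(variables)
    per_var = {v: float(mask[:, j].mean()) for j, v in enumerate(variables)}
    return MissingSummary(
        per_variable_rate=per_var,
        overall_rate=float(mask.mean()),
        n_units_any_missing=int(mask.any(axis=1).sum()),
    )


# ---------------------------------------------------------------------------
# Multiple imputation under a joint normal model


def _mvn_em(Y: np.ndarray, max_iter: int = 200, tol: float = 1e-6):
    """ML mean/covariance of a multivariate normal with missing entries (EM)."""
    n, p = Y.shape
    obs = ~np.isnan(Y)
    mu = np.nanmean(Y, axis=0)
    filled = np.where(obs, Y, mu)
    sigma = np.cov(filled, rowvar=False) + 1e-6 * np.eye(p)

    patterns: dict[bytes, np.ndarray] = {}
    for i in range(n):
        patterns.setdefault(obs[i].tobytes(), []).append(i)  # type: ignore[arg-type]
    patterns = {k: np.asarray(v) for k, v in patterns.items()}

    for _ in range(max_iter):
        s_y = np.zeros(p)
        s_yy = np.zeros((p, p))
        for key, idx in patterns.items():
            o = np.frombuffer(key, dtype=bool)
            m = ~o
            Yo = Y[np.ix_(idx, np.flatnonzero(o))]
            if m.any():
                Soo = sigma[np.ix_(o, o)]
                Smo = sigma[np.ix_(m, o)]
                coef = np.linalg.solve(Soo, Smo.T).T  # (m, o)
                cond_cov = sigma[np.ix_(m, m)] - coef @ Smo.T
                Em = mu[m] + (Yo - mu[o]) @ coef.T
            ey = np.zeros((len(idx), p))
            ey[:, o] = Yo
            if m.any():
                ey[:, np.flatnonzero(m)] = Em
            s_y += ey.sum(axis=0)
            s_yy += ey.T @ ey
            if m.any():
                add = np.zeros((p, p))
                add[np.ix_(m, m)] = cond_cov * len(idx)
                s_yy += add
        mu_new = s_y / n
        sigma_new = s_yy / n - np.outer(mu_new, mu_new)
        sigma_new = 0.5 * (sigma_new + sigma_new.T) + 1e-10 * np.eye(p)
        delta = max(
            np.max(np.abs(mu_new - mu)), np.max(np.abs(sigma_new - sigma))
        )
        mu, sigma = mu_new, sigma_new
        if delta < tol:
            break
    return mu, sigma


def impute_multiply(
    dataset: PanelDataset,
    m: int = 10,
    seed: int = 0,
    columns: Sequence[str] | None = None,
) -> list[PanelDataset]:
    """Draw ``m`` completed panels from a joint-normal model of the analysis
    variables fitted to the observed data by EM.

    Observed cells are left untouched in every imputation; missing cells are
    drawn from their conditional normal given the unit's observed entries.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    if columns is None:
        columns = dataset.analysis_cols
    columns = list(columns)
    Y = dataset.values(columns)
    obs = ~np.isnan(Y)
    fully_missing = [c for j, c in enumerate(columns) if not obs[:, j].any()]
    if fully_missing:
        raise ValueError(f"cannot impute fully missing variable(s): {fully_missing}")
    if obs.all():
        return [dataclasses.replace(dataset) for _ in range(m)]

    mu, sigma = _mvn_em(Y)
    rng = np.random.default_rng(seed)
    out: list[PanelDataset] = []
    miss_rows = np.flatnonzero(~obs.all(axis=1))
    for _ in range(m):
        Yk = Y.copy()
        for i in miss_rows:
            o = obs[i]
            mm = ~o
            Soo = sigma[np.ix_(o, o)]
            Smo = sigma[np.ix_(mm, o)]
            if o.any():
                coef = np.linalg.solve(Soo, Smo.T).T
                cond_mu = mu[mm] + coef @ (Y[i, o] - mu[o])
                cond_cov = sigma[np.ix_(mm, mm)] - coef @ Smo.T
            else:
                cond_mu = mu[mm]
                cond_cov = sigma[np.ix_(mm, mm)]
            cond_cov = 0.5 * (cond_cov + cond_cov.T) + 1e-12 * np.eye(mm.sum())
            Yk[i, mm] = rng.multivariate_normal(cond_mu, cond_cov, method="cholesky")
        out.append(dataset.replace_values(columns, Yk))
    return out


def pool_rubin(estimates: Iterable[float], ses: Iterable[float]) -> PooledEstimate:
    """Combine per-imputation point estimates and standard errors.

    total variance = within + (1 + 1/m) * between; se = sqrt(total).
    """
    est = np.asarray(list(estimates), dtype=float)
    se = np.asarray(list(ses), dtype=float)
    if est.shape != se.shape:
        raise ValueError("estimates and ses must have equal length")
    m = est.size
    if m < 2:
        raise ValueError("need at least 2 imputations to pool")
    within = float(np.mean(se**2))
    between = float(np.var(est, ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    return PooledEstimate(
        estimate=float(np.mean(est)),
        within_var=within,
        between_var=between,
        total_var=total,
        se=math.sqrt(total),
        m=m,
    )
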