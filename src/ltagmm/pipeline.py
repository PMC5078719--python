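"""End-to-end 3-step workflow: stage-wise growth mixtures, classification
error, structural transition fit (optionally with covariates and with
multiple imputation of missing covariates)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .growth_mixture import GMMFit, StageSpec, fit_gmm
from .lta_threestep import (
    ErrorMatrix,
    LTAFit,
    classification_error,
    fit_step3,
    modal_assign,
    pool_step3_fits,
)
from .panel_io import PanelDataset, PooledEstimate, impute_multiply

__all__ = ["ThreeStepResult", "three_step_pipeline"]


@dataclass
class ThreeStepResult:
    stage1_fit: GMMFit
    stage2_fit: GMMFit
    q1: ErrorMatrix
    q2: ErrorMatrix
    lta: LTAFit
    pooled: dict[str, PooledEstimate] | None = None
    per_imputation: list[LTAFit] | None = None


def three_step_pipeline(
    panel: PanelDataset,
    stage1_spec: StageSpec,
    stage2_spec: StageSpec,
    covariates: Sequence[str] | None = None,
    n_starts: int = 20,
    seed: int = 0,
    m_imputations: int = 10,
    **fit_options,
) -> ThreeStepResult:
    """Run steps 1-3 on a panel.

    Step 1 fits each stage's growth mixture on its own indicator set
    (full-information over missing indicator cells).  Covariates with missing
    entries are multiply imputed and the step-3 fits pooled by Rubin's rules;
    the reported LTAFit is then the first completed dataset's fit with the
    pooled table attached.
    """
    rng = np.random.default_rng(seed)
    s1_seed, s2_seed, mi_seed = (int(s) for s in rng.integers(0, 2**31 - 1, 3))

    fit1 = fit_gmm(panel, stage1_spec, n_starts=n_starts, seed=s1_seed, **fit_options)
    fit2 = fit_gmm(panel, stage2_spec, n_starts=n_starts, seed=s2_seed, **fit_options)

    modal1 = modal_assign(fit1.responsibilities)
    modal2 = modal_assign(fit2.responsibilities)
    q1 = classification_error(fit1.responsibilities, modal1)
    q2 = classification_error(fit2.responsibilities, modal2)

    if covariates:
        covariates = tuple(covariates)
        X = panel.values(covariates)
        if np.isnan(X).any():
            completed = impute_multiply(
                panel, m=m_imputations, seed=mi_seed, columns=covariates
            )
            fits = [
                fit_step3(
                    modal1.classes,
                    modal2.classes,
                    d.values(covariates),
                    q1,
                    q2,
                    covariate_names=covariates,
                )
                for d in completed
            ]
            pooled = pool_step3_fits(fits)
            lta = fits[0]
            lta.per_imputation = fits
            lta.pooled = pooled
            return ThreeStepResult(fit1, fit2, q1, q2, lta, pooled, fits)
        lta = fit_step3(
            modal1.classes, modal2.classes, X, q1, q2, covariate_names=covariates
        )
    else:
        lta = fit_step3(modal1.classes, modal2.classes, None, q1, q2)
    return ThreeStepResult(fit1, fit2, q1, q2, lta)
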