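import numpy as np
import pandas as pd
import pytest

from ltagmm import PanelDataset, StageSpec


@pytest.fixture
def toy_spec():
    """Three indicators at the kindergarten-stage time scores."""
    return StageSpec(1, ("y1", "y2", "y3"), (0.0, 0.5, 1.5), K=2)


@pytest.fixture
def tiny_panel():
    """Fully observed 4-unit panel with covariates."""
    rng = np.random.default_rng(7)
    df = pd.DataFrame(
        {
            "unit_id": [0, 1, 2, 3],
            "y1": [-1.2, -1.0, -1.5, -0.8],
            "y2": [-0.7, -0.5, -1.1, -0.4],
            "y3": [0.2, 0.4, -0.3, 0.5],
            "parent_rating": [3.1, 3.2, 2.9, 3.3],
            "teacher_rating": [3.0, 3.4, 2.5, 3.2],
            "ses": [0.1, 0.5, -0.6, 0.3],
            "poverty": [1.8, 1.9, 1.7, 1.9],
        }
    )
    return PanelDataset(
        data=df, indicator_cols=("y1", "y2", "y3")
    )


@pytest.fixture(scope="session")
def small_two_class_data():
    """Well-separated 2-class growth data for enumeration/recovery checks."""
    import ltagmm

    cfg = ltagmm.final_model_null(n=600, seed=11)
    return ltagmm.generate(cfg)
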