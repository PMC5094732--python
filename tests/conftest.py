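import numpy as np
import pandas as pd
import pytest

from npcomb import (
    ModalityKind,
    OmicsDataset,
    OutcomeType,
    StudyDesign,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_design(n_per_group: int, covariates: pd.DataFrame | None = None) -> StudyDesign:
    n = 2 * n_per_group
    return StudyDesign(
        sample_ids=[f"s{i}" for i in range(n)],
        outcome=pd.Series(["ctrl"] * n_per_group + ["case"] * n_per_group),
        outcome_type=OutcomeType.DICHOTOMOUS,
        covariates=covariates,
    )


def make_dataset(
    values: np.ndarray,
    kind=ModalityKind.CONTINUOUS,
    modality_id: str = "m1",
    sample_ids=None,
) -> OmicsDataset:
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    return OmicsDataset(
        modality_id=modality_id,
        feature_ids=[f"g{i}" for i in range(g)],
        sample_ids=sample_ids or [f"s{i}" for i in range(n)],
        values=values,
        kind=kind,
    )


@pytest.fixture
def small_design():
    return make_design(3)


@pytest.fixture
def gaussian_dataset(rng):
    return make_dataset(rng.standard_normal((20, 10)))
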