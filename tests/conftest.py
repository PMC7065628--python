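"""Shared fixtures: small synthetic cohorts reused across the suite."""

import numpy as np
import pytest

from tcellact.evaluation import CellDataset
from tcellact.preprocess import cells_from_synthetic, run_preprocessing
from tcellact.synthetic import default_profiles, generate_cohort


@pytest.fixture(scope="session")
def six_donor_dataset() -> CellDataset:
    """Six donors x 40 clean cells, full class effect, augmented x6."""
    profiles = default_profiles(n_cells=40)
    cohort = generate_cohort(profiles, rng_seed=20240901)
    cells = [c for cs in cohort.values() for c in cs]
    processed, _ = run_preprocessing(cells_from_synthetic(cells))
    return CellDataset.from_processed(processed)


@pytest.fixture(scope="session")
def balanced_three_donor_dataset() -> CellDataset:
    """Three balanced donors x 30 cells, for the neural-model tests."""
    profiles = default_profiles(n_cells=30, skews=(0.5, 0.5, 0.5))
    cohort = generate_cohort(profiles, rng_seed=77)
    cells = [c for cs in cohort.values() for c in cs]
    processed, _ = run_preprocessing(cells_from_synthetic(cells))
    return CellDataset.from_processed(processed)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
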