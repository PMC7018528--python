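from pathlib import Path

import numpy as np
import pytest

from mbclock import CohortConfig, FeatureTable, ModelConfig, generate_cohort

DATA_DIR = Path(__file__).parent / "data"

#: small tuning grid used throughout the tests; forest sizes are scaled to
#: desk runtime while keeping the 5-fold CV layout of the full default
QUICK_MODEL = ModelConfig(
    n_trees=100, mtry_fractions=(0.33,), min_node_sizes=(5,), cv_folds=5, seed=0
)


@pytest.fixture(scope="session")
def metadata_fixture_path() -> Path:
    return DATA_DIR / "metadata_fixture.tsv"


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded draw of the default synthetic cohort (500 x 200)."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture()
def tiny_table() -> FeatureTable:
    return FeatureTable(
        ["s1", "s2"],
        ["f1", "f2", "f3"],
        np.array([[0.2, 0.3, 0.5], [0.1, 0.1, 0.8]]),
    )
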