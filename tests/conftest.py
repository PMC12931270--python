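import numpy as np
import pytest

from bpdnet import CohortConfig, CountTable, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_table():
    """3 samples x 4 taxa with known totals."""
    return CountTable(
        ["s1", "s2", "s3"],
        ["t1", "t2", "t3", "t4"],
        np.array([[5, 0, 1, 10],
                  [3, 1, 0, 20],
                  [2, 0, 0, 30]]),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort reused across tests (expensive to regenerate)."""
    config = CohortConfig(
        group_sizes={"non": 8, "I": 8, "II": 6, "III": 5},
        n_taxa=40, depth_range=(3000, 5000),
        planted_modules={"non": [(6, 0.7)], "I": [(6, 0.7)],
                         "II": [(8, 0.75)], "III": [(3, 0.6)]},
        n_contaminant_taxa=4, n_singleton_taxa=5, seed=7,
    )
    return generate_cohort(config)
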