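import numpy as np
import pandas as pd
import pytest

from oligogrn.de import normalize
from oligogrn.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort exercising every stage (shared across tests)."""
    cfg = CohortConfig(
        n_per_subgroup=(40, 20, 8),
        n_genes=2000,
        n_tfs=60,
        grade_de_genes=30,
        grade_de_lfc=2.0,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_norm(small_cohort):
    return normalize(small_cohort.counts)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_matrix():
    return pd.DataFrame(
        [[0.1, -0.2], [0.3, 0.4], [-0.5, 0.0]],
        index=["GA", "GB", "GC"],
        columns=["S1", "S2"],
    )
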