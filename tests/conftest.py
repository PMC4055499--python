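import numpy as np
import pytest

from mpmri.cohort import CohortConfig, generate_cohort, generate_phenotypes
from mpmri.integration import compute_feature_table


@pytest.fixture(scope="session")
def small_cohort():
    """Default-dimension cohort at reduced n, shared across test modules."""
    cfg = CohortConfig(n_per_group=20, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return compute_feature_table(small_cohort)


@pytest.fixture(scope="session")
def small_cohort_with_phenotypes(small_cohort, small_features):
    return generate_phenotypes(small_cohort, small_cohort.config,
                               features=small_features.data)


def random_graph(rng: np.random.Generator, n: int, p: float):
    """Symmetric Erdos-Renyi adjacency as a BinaryGraph."""
    from mpmri.networks import BinaryGraph

    a = (rng.random((n, n)) < p).astype(np.uint8)
    a = np.triu(a, 1)
    return BinaryGraph(a | a.T)
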