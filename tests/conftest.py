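import numpy as np
import pytest

import cryptistat as cs


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small coupled dataset shared by io/pipeline tests."""
    scenario = cs.SimScenario(
        n_species=5, n_nests_per_species=6, n_workers_per_nest=2,
        n_loci=80, n_aflp_individuals_per_species=5,
        n_localities_per_species=6, seed=42)
    return cs.simulate_dataset(scenario)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_distance_matrix(rng, n, labels=None):
    """Random symmetric matrix with zero diagonal (not metric in general)."""
    M = rng.uniform(0.1, 2.0, (n, n))
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 0.0)
    labels = labels or tuple(f"t{i}" for i in range(n))
    return cs.DistanceMatrix(tuple(labels), M)
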