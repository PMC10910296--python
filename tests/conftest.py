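import numpy as np
import pytest

import vnscluster as vc


@pytest.fixture
def two_pair():
    return vc.two_pair_instance()


@pytest.fixture
def two_pair_D(two_pair):
    """Pure spatial distance on the canonical 4-cell instance."""
    return vc.build_distance_model(two_pair, alpha=0.0)


@pytest.fixture
def random_instance():
    """Factory for small random instances: uniform coordinates in [0, 10]^2,
    unit-sphere embeddings."""

    def make(n, m_dim=8, seed=0):
        rng = np.random.default_rng(seed)
        emb = rng.standard_normal((n, m_dim))
        emb /= np.linalg.norm(emb, axis=1, keepdims=True)
        coords = rng.uniform(0.0, 10.0, size=(n, 2))
        return vc.CellDataset([f"c{i}" for i in range(n)], coords, emb)

    return make


def assert_feasible(solution, D, k):
    """Structural feasibility of a medoid solution: exactly k distinct open
    centroids, every cell assigned to exactly one of them at minimum
    distance, every centroid assigned to itself."""
    assert solution.Y.size == k
    solution.check(D)  # raises SolutionError on any violation
    assert solution.F >= 0.0


@pytest.fixture
def feasibility_check():
    return assert_feasible
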