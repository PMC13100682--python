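import numpy as np
import pytest

from topofc import (
    CorrelationMatrix,
    SyntheticSpec,
    generate_cohort,
    square_fixture,
    two_ring_fixture,
)


@pytest.fixture
def square():
    return square_fixture()


@pytest.fixture
def two_ring():
    return two_ring_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """10 + 10 subjects, 30 nodes, default planted ring; session-cached."""
    spec = SyntheticSpec(seed=2024, n_per_group=10)
    return generate_cohort(spec)


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random metric-free symmetric matrix with entries in (0, 2)."""
    d = rng.uniform(0.05, 1.95, size=(n, n))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def correlation_from_distance(dvals: np.ndarray, subject_id: str = "s") -> CorrelationMatrix:
    """Invert the linear transform so to_distance() reproduces ``dvals``."""
    c = 1.0 - dvals / 2.0
    np.fill_diagonal(c, 1.0)
    ids = [f"n{i}" for i in range(len(c))]
    return CorrelationMatrix(c, ids, {i: "all" for i in ids}, subject_id)
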