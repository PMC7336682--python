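import numpy as np
import pytest

from driftdock import generate_fixture, make_docking_space
from driftdock.space import SearchSpace


@pytest.fixture(scope="session")
def fixture_ntor2():
    """Shipped regression fixture: 2-torsion ligand, default box."""
    return generate_fixture(seed=1, n_torsions=2)


@pytest.fixture(scope="session")
def fixture_ntor6():
    """Shipped regression fixture: 6-torsion ligand, default box."""
    return generate_fixture(seed=1, n_torsions=6)


@pytest.fixture
def box_space() -> SearchSpace:
    """Plain 5-D box [-5, 5]^5, no periodic dimensions."""
    return SearchSpace(
        lower=np.full(5, -5.0), upper=np.full(5, 5.0), periodic=np.zeros(5, bool)
    )


@pytest.fixture
def docking_space() -> SearchSpace:
    return make_docking_space(np.zeros(3), 22.5, 3)


def sphere(X: np.ndarray) -> np.ndarray:
    """Batched sphere function, the standard unimodal benchmark."""
    X = np.atleast_2d(X)
    return np.sum(X * X, axis=1)


def rastrigin(X: np.ndarray) -> np.ndarray:
    """Batched Rastrigin function, the standard multimodal benchmark."""
    X = np.atleast_2d(X)
    return 10.0 * X.shape[1] + np.sum(X * X - 10.0 * np.cos(2 * np.pi * X), axis=1)


class CountingObjective:
    """Wraps a batched objective and counts every row it evaluates."""

    def __init__(self, fn):
        self.fn = fn
        self.calls = 0

    def __call__(self, X):
        X = np.atleast_2d(X)
        self.calls += X.shape[0]
        return self.fn(X)
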