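import numpy as np
import pytest

from ilmf.containers import AssociationMatrix, SideNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_similarity(n: int, rng: np.random.Generator, connected: bool = True) -> SideNetwork:
    """A random symmetric similarity network with unit diagonal.

    Entries are positive (uniform in (0.05, 1]) so the graph is connected.
    """
    A = rng.uniform(0.05, 1.0, size=(n, n))
    S = 0.5 * (A + A.T)
    np.fill_diagonal(S, 1.0)
    return SideNetwork(S, [f"e{i}" for i in range(n)])


def random_association(n: int, m: int, rng: np.random.Generator, density: float = 0.3) -> AssociationMatrix:
    """A random binary association matrix with at least one 1 and one 0."""
    while True:
        Y = (rng.random((n, m)) < density).astype(float)
        if 0 < Y.sum() < Y.size:
            return AssociationMatrix(Y, [f"d{i}" for i in range(n)], [f"m{j}" for j in range(m)])


@pytest.fixture
def small_assoc(rng):
    return random_association(8, 10, rng)
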