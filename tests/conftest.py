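import numpy as np
import pytest

from netflux import GRNModel, PathwayModel


def random_stable_system(rng, n, m=1, radius=0.8, p_out=None):
    """A random stable (A, B, D) triple for gain cross-checks."""
    A = rng.normal(size=(n, n))
    sr = np.max(np.abs(np.linalg.eigvals(A)))
    if sr > 0:
        A *= radius / sr
    B = rng.normal(size=(n, m))
    if p_out is None:
        D = np.eye(n)
    else:
        D = np.zeros((1, n))
        D[0, rng.integers(n)] = 1.0
    return A, B, D


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def scalar_pathway():
    return PathwayModel(C=[[0.5]], H=[0.0], B=[[1.0]],
                        node_ids=["p1"], input_ids=["u1"])


@pytest.fixture
def two_node_pathway():
    # u drives node b, which feeds node a with weight 0.5
    return PathwayModel(C=[[0.0, 0.5], [0.0, 0.0]], H=[0.0, 0.0],
                        B=[[0.0], [1.0]], node_ids=["a", "b"], input_ids=["u1"])


@pytest.fixture
def chain_grn():
    # g1 -> g2 (0.5) -> g3 (0.4)
    A = np.zeros((3, 3))
    A[1, 0] = 0.5
    A[2, 1] = 0.4
    return GRNModel(A=A, node_ids=["g1", "g2", "g3"], semantics="static")
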