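import numpy as np
import pytest

from conneff.connectome import Connectome


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def chain3():
    """A-B-C chain: both edges 2 mm, unit weights, no direct A-C edge."""
    w = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
    l = np.array([[0.0, 2.0, 0.0], [2.0, 0.0, 2.0], [0.0, 2.0, 0.0]])
    return Connectome(w, l)


@pytest.fixture
def triangle():
    """Complete 3-node graph, all lengths 1 mm, all weights 1."""
    w = np.ones((3, 3)) - np.eye(3)
    l = np.ones((3, 3)) - np.eye(3)
    return Connectome(w, l)


@pytest.fixture
def star4():
    """Hub connected to three mutually unconnected leaves (unit edges)."""
    w = np.zeros((4, 4))
    w[0, 1:] = w[1:, 0] = 1.0
    l = np.where(w > 0, 1.0, 0.0)
    return Connectome(w, l)


def complete_uniform(n: int, length: float = 1.0, weight: float = 1.0) -> Connectome:
    w = np.full((n, n), weight)
    l = np.full((n, n), length)
    np.fill_diagonal(w, 0.0)
    np.fill_diagonal(l, 0.0)
    return Connectome(w, l)
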