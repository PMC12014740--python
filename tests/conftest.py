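import numpy as np
import pytest

from braindyn import synthetic
from braindyn.cartography import SignedGraph, Partition


@pytest.fixture
def two_cliques():
    """Two disjoint positive 3-cliques with unit weights, and the true partition."""
    w = np.zeros((6, 6))
    for block in ([0, 1, 2], [3, 4, 5]):
        for i in block:
            for j in block:
                if i != j:
                    w[i, j] = 1.0
    return SignedGraph.from_weights(w), Partition(np.array([0, 0, 0, 1, 1, 1]))


@pytest.fixture
def small_atlas():
    return synthetic.make_synthetic_atlas(n_cortical=20, n_subcortical=6, seed=0)


@pytest.fixture
def random_signed_matrices():
    """A suite of random symmetric signed matrices (<= 10 nodes)."""
    rng = np.random.default_rng(12345)
    mats = []
    for _ in range(30):
        n = int(rng.integers(4, 11))
        w = rng.uniform(-0.6, 1.0, size=(n, n))
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        mats.append(w)
    return mats
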