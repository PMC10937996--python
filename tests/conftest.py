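import numpy as np
import pytest

from netricci import StarParams, make_random_pin, make_star
from netricci.network import MatchedNetwork


@pytest.fixture
def star():
    """Factory for k-star fixtures."""

    def make(k: int, eps: float) -> object:
        return make_star(StarParams(k=k, eps=eps))

    return make


@pytest.fixture
def random_pair():
    """Factory for start/end network pairs sharing a random topology.

    The end state redraws the expression vector (log-normal), emulating a
    strongly rewired transcriptomic state on the same interactome.
    """

    def make(seed: int, n: int = 40, mean_degree: float = 4.0):
        net = make_random_pin(n, mean_degree, seed=seed)
        rng = np.random.default_rng(seed + 10_000)
        x2 = rng.lognormal(0.0, 1.0, net.n)
        return net, MatchedNetwork(net.node_ids, net.adjacency, x2)

    return make
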