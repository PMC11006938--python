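import networkx as nx
import numpy as np
import pytest

from asyncoop.coalescence import RateProfile
from asyncoop.netio import Network, from_networkx, generate_network


@pytest.fixture(scope="session")
def k2():
    return generate_network("complete", n=2)


@pytest.fixture(scope="session")
def k3():
    return generate_network("complete", n=3)


@pytest.fixture(scope="session")
def path3():
    return Network(3, ((0, 1), (1, 2)))


@pytest.fixture(scope="session")
def star4():
    return Network(4, ((0, 1), (0, 2), (0, 3)))


@pytest.fixture(scope="session")
def star4_rates():
    # hub rate 1, leaf rates 1.25, 1.75, 2
    return RateProfile(np.array([1.0, 1.25, 1.75, 2.0]))


@pytest.fixture(scope="session")
def cycle6():
    return generate_network("cycle", n=6)


@pytest.fixture(scope="session")
def double_star5():
    return generate_network("double_star", leaves=5)


@pytest.fixture(scope="session")
def ba100():
    return generate_network("scale_free_ba", n=100, m=3, seed=42)


@pytest.fixture(scope="session")
def lattice98():
    return generate_network("lattice", rows=7, cols=14)


@pytest.fixture(scope="session")
def regular100():
    return generate_network("random_regular", n=100, k=6, seed=5)


@pytest.fixture(scope="session")
def small_fixtures(k2, k3, path3, star4, cycle6):
    """All graphs small enough for the exact 2^N chain."""
    return {"k2": k2, "k3": k3, "path3": path3, "star4": star4,
            "cycle6": cycle6}


def random_connected_graph(n: int, rng: np.random.Generator,
                           p: float = 0.5) -> Network:
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
        if nx.is_connected(g):
            return from_networkx(g)


def random_rates(n: int, rng: np.random.Generator,
                 low: float = 0.3, high: float = 3.0) -> RateProfile:
    return RateProfile(rng.uniform(low, high, n))
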