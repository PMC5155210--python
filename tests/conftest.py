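import numpy as np
import pytest

from targetspread import Network

TOY_EDGES = {
    # path5: t - a - b - c - d  (target usually {t})
    "path5": [("t", "a"), ("a", "b"), ("b", "c"), ("c", "d")],
    # star5: center c with leaves l1..l4
    "star5": [("c", "l1"), ("c", "l2"), ("c", "l3"), ("c", "l4")],
    # triangle a,b,c with pendant d hanging off a
    "triangle_pendant": [("a", "b"), ("b", "c"), ("c", "a"), ("a", "d")],
    "cycle4": [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")],
    # path4: t - a - b - c
    "path4": [("t", "a"), ("a", "b"), ("b", "c")],
}


def toy(name: str) -> Network:
    return Network.from_label_pairs(TOY_EDGES[name])


@pytest.fixture
def path5():
    return toy("path5")


@pytest.fixture
def star5():
    return toy("star5")


@pytest.fixture
def triangle_pendant():
    return toy("triangle_pendant")


@pytest.fixture
def cycle4():
    return toy("cycle4")


@pytest.fixture
def path4():
    return toy("path4")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_er_network(n: int, p: float, seed: int) -> Network:
    import networkx as nx

    return Network.from_networkx(nx.gnp_random_graph(n, p, seed=seed))
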