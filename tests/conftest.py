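import networkx as nx
import numpy as np
import pytest

from patrolspread import SocialNetwork, realize_network, star_network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def path3():
    return SocialNetwork(graph=nx.path_graph(3))


@pytest.fixture
def path10():
    return SocialNetwork(graph=nx.path_graph(10))


@pytest.fixture
def star10():
    return star_network(10)


@pytest.fixture
def cycle8():
    return SocialNetwork(graph=nx.cycle_graph(8))


@pytest.fixture
def skewed8():
    """A small hand-sized community with a hub and several leaves."""
    return realize_network([5, 3, 2, 2, 1, 1, 1, 1], rng=99, enforce_connected=True)
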