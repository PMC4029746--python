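import networkx as nx
import pytest

from ppiclass.graphlets import build_orbit_catalog
from ppiclass.network import InteractionNetwork


@pytest.fixture(scope="session")
def catalog():
    """The 30-graphlet / 69-orbit catalog (built once; ~2 s)."""
    return build_orbit_catalog()


@pytest.fixture()
def triangle():
    g = nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])
    return InteractionNetwork(g)


@pytest.fixture()
def path3():
    return InteractionNetwork(nx.Graph([("A", "B"), ("B", "C")]))


def make_net(edges) -> InteractionNetwork:
    return InteractionNetwork(nx.Graph(edges))
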