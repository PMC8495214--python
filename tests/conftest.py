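import networkx as nx
import pytest

from netgenes.io import Interactome


def build_net(edges, nodes=None, weight=0.5, taxon_id="test", name="test"):
    """Construct an Interactome from (u, v) or (u, v, weight) tuples."""
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    for e in edges:
        if len(e) == 3:
            g.add_edge(e[0], e[1], weight=e[2])
        else:
            g.add_edge(e[0], e[1], weight=weight)
    return Interactome(taxon_id=taxon_id, graph=g, name=name)


@pytest.fixture
def net_factory():
    return build_net


@pytest.fixture
def triangle():
    return build_net([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def star4():
    """Star with a center and four leaves."""
    return build_net([("c", f"l{i}") for i in range(4)])


@pytest.fixture
def path3():
    return build_net([("a", "b"), ("b", "c")])
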