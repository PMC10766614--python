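import networkx as nx
import numpy as np
import pytest

from morphonet.core_model import MorphNetwork


def net_from_edges(edges, name="g", nodes=None):
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return MorphNetwork(name=name, graph=g)


def path_net(n):
    labels = [f"v{i}" for i in range(n)]
    return net_from_edges(zip(labels, labels[1:]), name=f"path{n}", nodes=labels)


def star_net(n_leaves):
    leaves = [f"leaf{i}" for i in range(n_leaves)]
    return net_from_edges((("hub", l) for l in leaves), name=f"star{n_leaves}",
                          nodes=["hub"] + leaves)


def cycle_net(n):
    labels = [f"v{i}" for i in range(n)]
    return net_from_edges(list(zip(labels, labels[1:])) + [(labels[-1], labels[0])],
                          name=f"cycle{n}", nodes=labels)


def complete_net(n):
    labels = [f"v{i}" for i in range(n)]
    return net_from_edges(((a, b) for i, a in enumerate(labels)
                           for b in labels[i + 1:]), name=f"k{n}", nodes=labels)


def random_connected_net(n, p, seed):
    """Seeded Erdos-Renyi graph, resampled until connected."""
    rng = np.random.default_rng(seed)
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
        if g.number_of_nodes() >= 2 and nx.is_connected(g):
            break
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
    return MorphNetwork(name=f"er{n}_{seed}", graph=g)


@pytest.fixture
def path3():
    return path_net(3)


@pytest.fixture
def path4():
    return path_net(4)


@pytest.fixture
def star3():
    return star_net(3)


@pytest.fixture
def triangle():
    return complete_net(3)


@pytest.fixture
def single_edge():
    return net_from_edges([("a", "b")], name="edge")
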