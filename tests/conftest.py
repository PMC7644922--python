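import numpy as np
import pytest

from dppn.graph_kernel import diffusion_kernel, ecc_all, weighted_adjacency
from dppn.network_io import PPINetwork, edge_key
from dppn.synthetic_data import SyntheticConfig, generate


def make_network(edges, extra_nodes=()):
    """Build a PPINetwork from an iterable of (u, v) pairs."""
    edge_set = {edge_key(u, v) for u, v in edges}
    nodes = sorted({n for e in edge_set for n in e} | set(extra_nodes))
    return PPINetwork(nodes=nodes, edges=edge_set)


@pytest.fixture
def triangle():
    return make_network([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path3():
    return make_network([("A", "B"), ("B", "C")])


@pytest.fixture
def star():
    return make_network([("hub", f"leaf{i}") for i in range(4)])


@pytest.fixture
def k4():
    nodes = ["A", "B", "C", "D"]
    return make_network([(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]])


@pytest.fixture(scope="session")
def two_communities():
    """Two 8-cliques joined by a single edge: perfectly separable communities.

    Returns (network, labels) with community membership as the location label
    (Nucleus vs Cytosol).
    """
    a_nodes = [f"a{i}" for i in range(8)]
    b_nodes = [f"b{i}" for i in range(8)]
    edges = [(u, v) for i, u in enumerate(a_nodes) for v in a_nodes[i + 1:]]
    edges += [(u, v) for i, u in enumerate(b_nodes) for v in b_nodes[i + 1:]]
    edges.append((a_nodes[0], b_nodes[0]))
    network = make_network(edges)
    labels = {n: "Nucleus" for n in a_nodes}
    labels.update({n: "Cytosol" for n in b_nodes})
    return network, labels


@pytest.fixture(scope="session")
def community_kernel(two_communities):
    network, _ = two_communities
    W = weighted_adjacency(network, pcc=None, ecc=ecc_all(network))
    return diffusion_kernel(W, 1.1)


@pytest.fixture(scope="session")
def synthetic_instance():
    """The default desk-scale benchmark instance (seed 7)."""
    return generate(SyntheticConfig())


def random_graph_adjacency(rng, n, p=0.3, signed=True):
    """Random symmetric zero-diagonal weighted adjacency matrix."""
    mask = np.triu(rng.random((n, n)) < p, k=1)
    weights = rng.uniform(-1 if signed else 0.05, 1, size=(n, n))
    A = np.where(mask, weights, 0.0)
    return A + A.T
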