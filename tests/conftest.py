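import networkx as nx
import numpy as np
import pytest

from ddjkm.graph_core import Partition


@pytest.fixture
def path3() -> nx.Graph:
    """Path a-b-c on nodes 0-1-2."""
    return nx.path_graph(3)


@pytest.fixture
def k5() -> nx.Graph:
    return nx.complete_graph(5)


@pytest.fixture
def two_k5() -> nx.Graph:
    """Two disjoint 5-cliques on nodes 0-4 and 5-9."""
    G = nx.complete_graph(5)
    H = nx.relabel_nodes(nx.complete_graph(5), {i: i + 5 for i in range(5)})
    return nx.union(G, H)


@pytest.fixture
def two_k5_partition() -> Partition:
    return Partition({v: 0 if v < 5 else 1 for v in range(10)})


@pytest.fixture
def karate() -> nx.Graph:
    return nx.karate_club_graph()


@pytest.fixture
def karate_truth(karate) -> Partition:
    return Partition({v: karate.nodes[v]["club"] for v in karate.nodes})


def random_graph(rng: np.random.Generator, n_max: int = 50) -> nx.Graph:
    """A random Erdos-Renyi graph with at least one node (test helper)."""
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.05, 0.5))
    G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    return G


def random_partition(rng: np.random.Generator, nodes, k_max: int = 6) -> Partition:
    nodes = list(nodes)
    k = int(rng.integers(1, min(k_max, len(nodes)) + 1))
    labels = rng.integers(0, k, size=len(nodes))
    return Partition({v: int(l) for v, l in zip(nodes, labels)})
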