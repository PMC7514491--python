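"""Per-node measures: entropy, density, DD, Jaccard, and their matrices.

The vectorised whole-graph computations are checked against the explicit
per-node BFS reference layer, which is itself checked against hand
calculations on tiny graphs.
"""

import math

import networkx as nx
import numpy as np
import pytest
import scipy.sparse as sp

from conftest import random_graph
from ddjkm.graph_core import Partition, bfs_ball, canonical_node_order, induced_subgraph
from ddjkm.node_measures import (
    _ball_stats_python,
    adjacency_csr,
    dd_score,
    dd_vector,
    ddj_matrix,
    density,
    density_vector,
    jaccard_matrix,
    jaccard_similarity,
    measure_table,
    membership_distribution,
    uncertainty,
)


class TestMembershipDistribution:
    def test_ball_inside_one_community(self):
        """A 2-hop ball fully inside one of three communities gives (1,0,0)."""
        G = nx.complete_graph(3)
        G.add_edge(10, 11)
        G.add_edge(20, 21)
        P = Partition({0: "a", 1: "a", 2: "a", 10: "b", 11: "b", 20: "c", 21: "c"})
        p, labels = membership_distribution(G, 0, 2, P)
        assert dict(zip(labels, p)) == {"a": 1.0, "b": 0.0, "c": 0.0}

    def test_even_split(self):
        G = nx.path_graph(2)
        P = Partition({0: "a", 1: "b"})
        p, _ = membership_distribution(G, 0, 1, P)
        assert np.allclose(sorted(p), [0.5, 0.5])

    def test_zero_hops_indicator(self):
        G = nx.path_graph(3)
        P = Partition({0: "a", 1: "b", 2: "b"})
        p, labels = membership_distribution(G, 0, 0, P)
        assert dict(zip(labels, p)) == {"a": 1.0, "b": 0.0}

    def test_sums_to_one(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            G = random_graph(rng, 20)
            P = Partition({v: int(v % 3) for v in G.nodes})
            for v in G.nodes:
                p, _ = membership_distribution(G, v, 2, P)
                assert math.isclose(p.sum(), 1.0)


class TestUncertainty:
    def test_degenerate_distribution_is_zero(self):
        G = nx.complete_graph(3)
        G.add_edge(10, 11)
        G.add_edge(20, 21)
        P = Partition({0: "a", 1: "a", 2: "a", 10: "b", 11: "b", 20: "c", 21: "c"})
        assert uncertainty(G, 0, 2, P) == 0.0

    def test_uniform_over_two_is_one_bit(self):
        G = nx.path_graph(2)
        P = Partition({0: "a", 1: "b"})
        assert math.isclose(uncertainty(G, 0, 1, P), 1.0)

    def test_uniform_over_four_is_two_bits(self):
        G = nx.star_graph(3)  # center 0 + three leaves: ball of 4 nodes
        P = Partition({0: "a", 1: "b", 2: "c", 3: "d"})
        assert math.isclose(uncertainty(G, 0, 1, P), 2.0)

    def test_bounded_by_log2_m(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            G = random_graph(rng, 15)
            P = Partition({v: int(v % 4) for v in G.nodes})
            m = len(set(P.assignment.values()))
            for v in G.nodes:
                assert 0.0 <= uncertainty(G, v, 2, P) <= math.log2(m) + 1e-12


class TestDensity:
    def test_clique_saturates(self, k5):
        for v in k5.nodes:
            assert density(k5, v, 1) == 1.0

    def test_path_ends_and_middle(self, path3):
        assert density(path3, 0, 1) == 1.0  # 2 nodes, 1 edge
        assert math.isclose(density(path3, 1, 1), 2 / 3)  # 3 nodes, 2 edges

    def test_five_nodes_five_edges_is_half(self):
        # 5-cycle seen from node 0: the 2-hop ball is all 5 nodes, 5 edges
        G = nx.Graph([(0, 1), (0, 2), (1, 3), (2, 4), (3, 4)])
        ball = bfs_ball(G, 0, 2)
        assert len(ball) == 5
        assert induced_subgraph(G, ball).number_of_edges() == 5
        assert density(G, 0, 2) == 0.5

    def test_isolated_node_zero(self):
        G = nx.Graph()
        G.add_node(7)
        assert density(G, 7, 1) == 0.0

    def test_h_zero_rejected(self, k5):
        with pytest.raises(ValueError):
            density(k5, 0, 0)

    def test_density_one_iff_ball_is_clique(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            G = random_graph(rng, 15)
            for v in G.nodes:
                ball = bfs_ball(G, v, 1)
                d = density(G, v, 1)
                assert 0.0 <= d <= 1.0
                if len(ball) >= 2:
                    H = induced_subgraph(G, ball)
                    is_clique = H.number_of_edges() == len(ball) * (len(ball) - 1) // 2
                    assert (d == 1.0) == is_clique


class TestDDScore:
    def test_isolated_zero(self):
        G = nx.Graph()
        G.add_node(0)
        assert dd_score(G, 0, 1) == 0.0

    def test_k4(self):
        G = nx.complete_graph(4)
        assert dd_score(G, 0, 1) == 3.0

    def test_star_center(self):
        G = nx.star_graph(4)  # center + 4 leaves: ball density 4/10
        assert math.isclose(dd_score(G, 0, 1), (4 / 10) * 4)


class TestDensityVector:
    def test_k3_all_ones(self):
        assert np.allclose(density_vector(nx.complete_graph(3), 1), 1.0)

    def test_disjoint_cliques_all_ones(self, two_k5):
        assert np.allclose(density_vector(two_k5, 1), 1.0)

    def test_path3_hand_values(self, path3):
        assert np.allclose(density_vector(path3, 1), [1.0, 2 / 3, 1.0])

    @pytest.mark.parametrize("h", [1, 2, 3])
    def test_matches_per_node_reference(self, h):
        """Vectorised (numba) densities equal the explicit BFS reference."""
        rng = np.random.default_rng(17)
        for _ in range(15):
            G = random_graph(rng, 40)
            order = canonical_node_order(G)
            expected = [density(G, v, h) for v in order]
            assert np.allclose(density_vector(G, h, order), expected, atol=1e-12)

    def test_sparse_fallback_matches_reference(self):
        """The boolean-matrix-power fallback agrees with the BFS reference."""
        rng = np.random.default_rng(23)
        for h in (1, 2, 3):
            G = random_graph(rng, 30)
            order = canonical_node_order(G)
            A = adjacency_csr(G, order)
            sizes, edges = _ball_stats_python(A, h)
            for i, v in enumerate(order):
                ball = bfs_ball(G, v, h)
                assert sizes[i] == len(ball)
                assert edges[i] == induced_subgraph(G, ball).number_of_edges()

    def test_dd_vector_is_density_times_degree(self, two_k5):
        order = canonical_node_order(two_k5)
        dd = dd_vector(two_k5, 1, order)
        assert np.allclose(dd, [density(two_k5, v, 1) * two_k5.degree(v) for v in order])


class TestJaccard:
    def test_self_pair_is_one(self, k5):
        assert jaccard_similarity(k5, 0, 0) == 1.0

    def test_hand_case(self):
        G = nx.Graph([("a", 1), ("a", 2), ("a", 3), ("b", 2), ("b", 3), ("b", 4)])
        assert jaccard_similarity(G, "a", "b") == 0.5

    def test_disjoint_neighbourhoods(self):
        G = nx.Graph([(0, 1), (2, 3)])
        assert jaccard_similarity(G, 0, 2) == 0.0

    def test_two_isolated_nodes(self):
        G = nx.Graph()
        G.add_nodes_from([0, 1])
        assert jaccard_similarity(G, 0, 1) == 0.0

    def test_unknown_node(self, k5):
        with pytest.raises(KeyError):
            jaccard_similarity(k5, 0, 99)

    def test_k3_matrix(self):
        J = jaccard_matrix(nx.complete_graph(3)).toarray()
        expected = np.full((3, 3), 1 / 3)
        np.fill_diagonal(expected, 1.0)
        assert np.allclose(J, expected)

    def test_edgeless_graph_identity(self):
        G = nx.Graph()
        G.add_nodes_from(range(4))
        assert np.allclose(jaccard_matrix(G).toarray(), np.eye(4))

    def test_matrix_matches_pairwise(self):
        """Matrix entries equal the brute-force pairwise computation."""
        rng = np.random.default_rng(31)
        for _ in range(20):
            G = random_graph(rng, 30)
            order = canonical_node_order(G)
            J = jaccard_matrix(G, order).toarray()
            expected = np.array(
                [[jaccard_similarity(G, a, b) for b in order] for a in order]
            )
            assert np.allclose(J, expected, atol=1e-12)
            assert np.allclose(J, J.T)


class TestDDJMatrix:
    def test_unit_densities_give_jaccard(self, two_k5):
        J = jaccard_matrix(two_k5)
        DDJ = ddj_matrix(np.ones(10), J)
        assert np.allclose(DDJ.toarray(), J.toarray())

    def test_zero_densities_give_zero(self, two_k5):
        J = jaccard_matrix(two_k5)
        assert ddj_matrix(np.zeros(10), J).nnz == 0 or np.allclose(
            ddj_matrix(np.zeros(10), J).toarray(), 0.0
        )

    def test_matches_elementwise_product(self):
        rng = np.random.default_rng(41)
        G = random_graph(rng, 10)
        n = G.number_of_nodes()
        D = rng.uniform(0, 1, n)
        J = jaccard_matrix(G)
        expected = np.outer(D, D) * J.toarray()
        assert np.allclose(ddj_matrix(D, J).toarray(), expected, atol=1e-12)

    def test_symmetric_nonnegative(self):
        rng = np.random.default_rng(43)
        for _ in range(10):
            G = random_graph(rng, 20)
            D = density_vector(G, 2)
            M = ddj_matrix(D, jaccard_matrix(G)).toarray()
            assert np.allclose(M, M.T) and (M >= 0).all()

    def test_dimension_mismatch(self, two_k5):
        with pytest.raises(ValueError):
            ddj_matrix(np.ones(3), jaccard_matrix(two_k5))


class TestMarginalNodeOrdering:
    def test_bridge_nodes_less_dense_than_interior(self):
        """In cliques bridged by single edges, the bridge endpoints have
        strictly lower 1-hop density than their bridge-free clique-mates."""
        from ddjkm.synthetic_networks import ring_of_cliques

        inst = ring_of_cliques(3, 5)
        G = inst.graph
        bridge_nodes = {u for u, v in G.edges if v // 5 != u // 5} | {
            v for u, v in G.edges if v // 5 != u // 5
        }
        interior = set(G.nodes) - bridge_nodes
        worst_interior = min(density(G, v, 1) for v in interior)
        best_bridge = max(density(G, v, 1) for v in bridge_nodes)
        assert best_bridge < worst_interior


def test_matrix_coo_round_trip(tmp_path, two_k5):
    from ddjkm.node_measures import write_matrix_coo

    J = jaccard_matrix(two_k5)
    p = tmp_path / "J.coo"
    write_matrix_coo(J, p)
    rows = [l.split() for l in p.read_text().splitlines() if not l.startswith("#")]
    back = np.zeros(J.shape)
    for i, j, v in rows:
        back[int(i), int(j)] = float(v)
    assert np.allclose(back, J.toarray(), atol=1e-9)


def test_measure_table_columns(two_k5):
    df = measure_table(two_k5, 1)
    assert list(df.columns) == ["node_id", "degree", "density", "dd"]
    assert (df["dd"] == df["density"] * df["degree"]).all()
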