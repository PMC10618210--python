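import math

import networkx as nx
import numpy as np
import pytest

from nethub.graph_core import (
    DisconnectedError,
    Edge,
    InfeasibleSubsetError,
    Network,
    SpanningTree,
    UndirectedGraph,
    enumerate_spanning_trees,
    kruskal_decode,
    spanning_tree_count_kirchhoff,
    total_edge_cost,
    total_pairwise_distance,
    tree_distance_matrix,
    undirected_projection,
)

from .conftest import complete_graph, cycle_graph, path_graph, random_connected_graph, star_graph


class TestNetworkValidation:
    def test_rejects_self_loop(self):
        with pytest.raises(ValueError, match="self-loop"):
            Edge("A", "A")

    def test_rejects_duplicate_nodes(self):
        with pytest.raises(ValueError, match="unique"):
            Network(["A", "A"], [Edge("A", "B")])

    def test_rejects_disconnected(self):
        with pytest.raises(DisconnectedError) as err:
            Network(["A", "B", "C", "D"], [Edge("A", "B"), Edge("C", "D")])
        assert [["A", "B"], ["C", "D"]] == sorted(err.value.components)

    def test_probability_bounds(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            Edge("A", "B", "+", 1.2)

    def test_cost_is_one_minus_p(self):
        assert Edge("A", "B", "+", 0.8).cost == pytest.approx(0.2)


class TestUndirectedProjection:
    def test_antiparallel_pair_collapses(self):
        net = Network(["A", "B"], [Edge("A", "B"), Edge("B", "A")])
        g = undirected_projection(net)
        assert g.n_edges == 1

    def test_bidirectional_clique_collapses_to_k4(self):
        nodes = ["A", "B", "C", "D"]
        edges = [Edge(u, v) for u in nodes for v in nodes if u != v]
        assert len(edges) == 12
        g = undirected_projection(Network(nodes, edges))
        assert g.n_edges == 6

    def test_signs_dropped_on_collapse(self):
        # opposite-signed antiparallel regulation becomes one structural edge
        net = Network(["A", "B"], [Edge("A", "B", "+"), Edge("B", "A", "-")])
        g = undirected_projection(net)
        assert g.n_edges == 1 and g.edge_labels(0) == ("A", "B")

    @pytest.mark.parametrize(
        "merge,expected_cost", [("max", 0.2), ("mean", 0.4), ("min", 0.6)]
    )
    def test_collapse_probability_merge(self, merge, expected_cost):
        net = Network(["A", "B"], [Edge("A", "B", "+", 0.8), Edge("B", "A", "-", 0.4)])
        g = undirected_projection(net, merge=merge)
        assert g.costs[0] == pytest.approx(expected_cost)

    def test_edge_order_sorted_by_label_pair(self):
        net = Network(
            ["Z", "M", "A"], [Edge("Z", "M"), Edge("M", "A"), Edge("A", "Z")]
        )
        g = undirected_projection(net)
        assert [g.edge_labels(i) for i in range(3)] == [
            ("A", "M"), ("A", "Z"), ("M", "Z")
        ]

    def test_unweighted_when_any_probability_missing(self):
        net = Network(["A", "B", "C"], [Edge("A", "B", "+", 0.9), Edge("B", "C")])
        assert not undirected_projection(net).weighted


class TestTreeMetrics:
    def test_two_node_tree(self):
        g = path_graph(2)
        t = SpanningTree(frozenset({0}), g)
        assert tree_distance_matrix(t) == [[0, 1], [1, 0]]
        assert total_pairwise_distance(t) == 2

    def test_three_node_path_distances(self):
        g = path_graph(3)
        t = SpanningTree(frozenset({0, 1}), g)
        d = tree_distance_matrix(t)
        assert d[0][2] == 2 and d[0][1] == 1
        assert total_pairwise_distance(t) == 8

    def test_star_distances(self):
        g = star_graph(3)
        t = SpanningTree(frozenset(range(3)), g)
        d = tree_distance_matrix(t)
        assert d[0][1] == 1  # center-leaf
        assert d[1][2] == 2  # leaf-leaf
        assert total_pairwise_distance(t) == 18

    def test_path_p4_ordered_distance(self):
        # brute-force: sum |i-j| over ordered pairs = 2 * 10
        g = path_graph(4)
        t = SpanningTree(frozenset(range(3)), g)
        expected = sum(abs(i - j) for i in range(4) for j in range(4))
        assert total_pairwise_distance(t) == expected == 20

    def test_distance_matrix_matches_networkx(self):
        _, g = random_connected_graph(42)
        tree = next(iter(enumerate_spanning_trees(g)))
        nxt = nx.Graph(
            [g.edge_pairs[i] for i in tree.edge_indices]
        )
        d = tree_distance_matrix(tree)
        for s, lengths in nx.all_pairs_shortest_path_length(nxt):
            for t_, ln in lengths.items():
                assert d[s][t_] == ln

    def test_total_edge_cost(self):
        g = path_graph(3)
        g.costs = [0.3, 0.5]
        g.weighted = True
        t = SpanningTree(frozenset({0, 1}), g)
        assert total_edge_cost(t) == pytest.approx(0.8)

    def test_total_edge_cost_all_certain_edges(self):
        g = path_graph(3)
        g.costs = [0.0, 0.0]  # p = 1 on every edge
        g.weighted = True
        assert total_edge_cost(SpanningTree(frozenset({0, 1}), g)) == 0.0

    def test_total_edge_cost_requires_weights(self):
        g = path_graph(3)
        with pytest.raises(ValueError, match="unweighted"):
            total_edge_cost(SpanningTree(frozenset({0, 1}), g))

    def test_spanning_tree_invariants_enforced(self):
        g = cycle_graph(4)
        with pytest.raises(ValueError, match="needs"):
            SpanningTree(frozenset({0, 1}), g)  # too few edges
        k4 = complete_graph(4)
        # edges 0=(0,1) 1=(0,2) 3=(1,2) form a triangle -> cycle
        with pytest.raises(ValueError, match="cycle"):
            SpanningTree(frozenset({0, 1, 3}), k4)


class TestKruskalDecode:
    def test_cycle_unit_costs_drops_highest_index(self):
        g = cycle_graph(5)
        t = kruskal_decode(frozenset(range(5)), g)
        assert t.edge_indices == frozenset({0, 1, 2, 3})

    def test_triangle_picks_cheapest_two(self):
        g = UndirectedGraph(
            ["a", "b", "c"], [(0, 1), (0, 2), (1, 2)], [0.1, 0.9, 0.2], weighted=True
        )
        t = kruskal_decode(frozenset({0, 1, 2}), g)
        assert t.edge_indices == frozenset({0, 2})

    def test_isolated_vertex_infeasible(self):
        g = cycle_graph(4)
        with pytest.raises(InfeasibleSubsetError):
            kruskal_decode(frozenset({0}), g)

    def test_bad_index_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            kruskal_decode(frozenset({99}), cycle_graph(4))

    def test_decode_cost_minimal_over_induced_subgraph(self):
        # the decoded tree is an MST of the chromosome's subgraph
        rng = np.random.default_rng(5)
        for seed in range(5):
            _, g = random_connected_graph(seed + 300)
            g.costs = list(rng.uniform(0.1, 0.9, g.n_edges))
            g.weighted = True
            full = frozenset(range(g.n_edges))
            decoded = kruskal_decode(full, g)
            best = min(
                total_edge_cost(t) for t in enumerate_spanning_trees(g)
            )
            assert total_edge_cost(decoded) == pytest.approx(best)


class TestEnumeration:
    @pytest.mark.parametrize(
        "graph,expected",
        [(cycle_graph(5), 5), (complete_graph(4), 16)],
        ids=["C5", "K4"],
    )
    def test_known_counts(self, graph, expected):
        trees = enumerate_spanning_trees(graph)
        assert len(trees) == expected
        assert len({t.signature for t in trees}) == expected

    def test_tree_input_yields_itself(self):
        g = path_graph(5)
        trees = enumerate_spanning_trees(g)
        assert len(trees) == 1 and trees[0].edge_indices == frozenset(range(4))

    def test_size_refusal(self):
        with pytest.raises(ValueError, match="max_nodes"):
            enumerate_spanning_trees(complete_graph(4), max_nodes=3)

    def test_count_matches_kirchhoff_on_random_graphs(self):
        for seed in range(30):
            _, g = random_connected_graph(seed, n_lo=5, n_hi=8)
            assert len(enumerate_spanning_trees(g)) == spanning_tree_count_kirchhoff(g)

    def test_count_matches_networkx_iterator(self):
        for seed in (0, 7, 21):
            _, g = random_connected_graph(seed)
            nxg = nx.Graph(g.edge_pairs)
            nx_count = sum(1 for _ in nx.SpanningTreeIterator(nxg))
            assert len(enumerate_spanning_trees(g)) == nx_count

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_star_minimizes_total_distance(self, n):
        # over all trees on n nodes, the star attains the minimum
        trees = enumerate_spanning_trees(complete_graph(n), max_combinations=10**6)
        scores = {t.signature: total_pairwise_distance(t) for t in trees}
        best = min(scores.values())
        star_score = n * (n - 1) + (n - 1) * (n - 2)  # ordered pairs, diameter 2
        assert best == star_score
        for t in trees:
            if scores[t.signature] == best:
                assert max(t.degrees()) == n - 1  # every optimum is a star

    def test_distance_total_always_even(self):
        for seed in range(5):
            _, g = random_connected_graph(seed + 100)
            for t in enumerate_spanning_trees(g):
                assert total_pairwise_distance(t) % 2 == 0
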