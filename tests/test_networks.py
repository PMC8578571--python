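from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from samnet.networks import (Edge, RelationGraph, betweenness,
                             build_gene_network, build_pathway_network,
                             core_filter, node_degrees, pathway_features,
                             rank_hubs, read_edge_list, write_edge_list)
from samnet.synthetic import random_relation_graph


def graph_of(edge_tuples, nodes=None):
    edges = [Edge(*t) for t in edge_tuples]
    if nodes is None:
        nodes = sorted({e.source for e in edges} | {e.target for e in edges})
    return RelationGraph({n: {} for n in nodes}, edges)


def oracle_betweenness(g: RelationGraph) -> dict[str, Fraction]:
    """Exhaustive shortest-path enumeration in exact rational arithmetic.

    For every ordered pair (s, t): find the shortest distance by BFS, then
    enumerate every path of exactly that length by depth-limited search,
    and award each interior node sigma_st(i)/sigma_st.
    """
    adj = g.adjacency()
    nodes = list(adj.nodes)
    out = {n: Fraction(0) for n in nodes}
    for s in nodes:
        lengths = nx.single_source_shortest_path_length(adj, s)
        for t in nodes:
            if t == s or t not in lengths:
                continue
            L = lengths[t]
            paths = []

            def extend(path):
                last = path[-1]
                if len(path) - 1 == L:
                    if last == t:
                        paths.append(tuple(path))
                    return
                for nxt in adj.successors(last):
                    if nxt not in path:
                        path.append(nxt)
                        extend(path)
                        path.pop()

            extend([s])
            sigma = len(paths)
            for path in paths:
                for mid in path[1:-1]:
                    out[mid] += Fraction(1, sigma)
    return out


class TestBuildNetworks:
    def test_induced_subgraph_drops_outside_relations(self):
        rel = [Edge("A", "B"), Edge("A", "C")]
        net = build_pathway_network(["A", "B"], rel)
        assert net.n_edges == 1
        assert net.edges[0].source == "A" and net.edges[0].target == "B"

    def test_empty_relations_leave_isolated_nodes(self):
        net = build_pathway_network(["A", "B", "C"], [])
        assert net.n_nodes == 3 and net.n_edges == 0

    def test_chain_degrees(self):
        net = build_pathway_network(["A", "B", "C"], [Edge("A", "B"), Edge("B", "C")])
        deg = node_degrees(net)
        assert list(deg["indegree"]) == [0, 1, 1]
        assert list(deg["outdegree"]) == [1, 1, 0]

    def test_gene_network_keeps_features_and_types(self):
        net = build_gene_network({"x": "Up", "y": "Down"},
                                 [Edge("x", "y", "c", False), Edge("x", "z", "a")])
        assert net.n_edges == 1
        assert net.edges[0].etype == "c" and not net.edges[0].directed
        assert net.nodes["x"]["feature"] == "Up"

    def test_empty_deg_list_errors(self):
        with pytest.raises(ValueError):
            build_gene_network({}, [])

    def test_unknown_edge_type_rejected(self):
        with pytest.raises(ValueError, match="edge type"):
            Edge("a", "b", "bogus")

    def test_self_loops_dropped(self):
        net = graph_of([("A", "A", "c", False), ("A", "B", "c", False)], ["A", "B"])
        assert net.n_edges == 1

    def test_duplicate_undirected_edges_stored_once(self):
        net = graph_of([("A", "B", "c", False), ("B", "A", "c", False)])
        assert net.n_edges == 1


class TestDegrees:
    def test_isolated_node(self):
        deg = node_degrees(RelationGraph({"A": {}}, []))
        assert list(deg.loc["A", ["indegree", "outdegree", "degree"]]) == [0, 0, 0]

    def test_seven_up_four_down_gives_degree_eleven(self):
        edges = [Edge(f"u{i}", "hub") for i in range(7)]
        edges += [Edge("hub", f"d{i}") for i in range(4)]
        nodes = ["hub"] + [f"u{i}" for i in range(7)] + [f"d{i}" for i in range(4)]
        deg = node_degrees(RelationGraph({n: {} for n in nodes}, edges))
        assert deg.loc["hub", "indegree"] == 7
        assert deg.loc["hub", "outdegree"] == 4
        assert deg.loc["hub", "degree"] == 11

    def test_undirected_edge_counts_both_ways(self):
        deg = node_degrees(graph_of([("A", "B", "c", False)]))
        for n in ("A", "B"):
            assert list(deg.loc[n, ["indegree", "outdegree", "degree"]]) == [1, 1, 2]

    @pytest.mark.parametrize("seed", range(6))
    def test_degree_identity_and_arc_balance(self, seed):
        g = random_relation_graph(10, edge_prob=0.35, seed=seed)
        deg = node_degrees(g)
        assert (deg["degree"] == deg["indegree"] + deg["outdegree"]).all()
        n_arcs = g.adjacency().number_of_edges()
        assert deg["indegree"].sum() == n_arcs
        assert deg["outdegree"].sum() == n_arcs


class TestCoreFilter:
    def test_all_isolated_gives_empty_core(self):
        deg = node_degrees(RelationGraph({"A": {}, "B": {}}, []))
        assert len(core_filter(deg)) == 0

    def test_min_degree_one_keeps_exactly_edge_endpoints(self):
        g = graph_of([("A", "B", "link", True)], ["A", "B", "C"])
        core = core_filter(node_degrees(g))
        assert set(core.index) == {"A", "B"}

    def test_sorted_by_decreasing_degree(self, rng):
        g = random_relation_graph(12, edge_prob=0.3, seed=3)
        core = core_filter(node_degrees(g))
        assert (np.diff(core["degree"]) <= 0).all()
        assert list(core["rank"]) == list(range(1, len(core) + 1))


class TestBetweenness:
    def test_directed_path_middle_bridges_once(self):
        b = betweenness(graph_of([("A", "B"), ("B", "C")]))
        assert b.loc["B", "betweenness"] == 1.0
        assert b.loc["A", "betweenness"] == 0.0
        assert b.loc["C", "betweenness"] == 0.0

    def test_undirected_path_counts_ordered_pairs(self):
        b = betweenness(graph_of([("A", "B", "c", False), ("B", "C", "c", False)]))
        assert b.loc["B", "betweenness"] == 2.0

    def test_four_cycle_splits_credit(self):
        edges = [("A", "B", "c", False), ("B", "C", "c", False),
                 ("C", "D", "c", False), ("D", "A", "c", False)]
        b = betweenness(graph_of(edges))
        # two equal shortest paths between each opposite corner pair
        for n in "ABCD":
            assert b.loc[n, "betweenness"] == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [3, 5, 8])
    def test_star_centre_k_leaves(self, k):
        edges = [("hub", f"l{i}", "c", False) for i in range(k)]
        b = betweenness(graph_of(edges))
        assert b.loc["hub", "betweenness"] == pytest.approx(k * (k - 1))

    def test_degree_le_one_has_zero_betweenness(self):
        g = graph_of([("A", "B"), ("B", "C")], ["A", "B", "C", "D"])
        b = betweenness(g)
        low = b[b["degree"] <= 1]
        assert (low["betweenness"] == 0).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed):
        g = random_relation_graph(9, edge_prob=0.3, seed=100 + seed)
        b = betweenness(g)
        oracle = oracle_betweenness(g)
        for node in b.index:
            assert b.loc[node, "betweenness"] == pytest.approx(float(oracle[node]),
                                                               abs=1e-10)


class TestRankHubs:
    def test_strict_ordering_for_distinct_values(self):
        g = graph_of([("A", "B", "c", False), ("B", "C", "c", False),
                      ("C", "D", "c", False)])
        hubs = rank_hubs(betweenness(g), top_k=4)
        assert list(hubs.index[:2]) in (["B", "C"], ["C", "B"])
        assert (np.diff(hubs["betweenness"]) <= 0).all()

    def test_top_k_larger_than_node_count_returns_all(self):
        g = graph_of([("A", "B")])
        assert len(rank_hubs(betweenness(g), top_k=10)) == 2

    def test_non_positive_top_k_errors(self):
        g = graph_of([("A", "B")])
        with pytest.raises(ValueError):
            rank_hubs(betweenness(g), top_k=0)


class TestEdgeListIO:
    def test_round_trip_identity(self, tmp_path):
        g = random_relation_graph(10, edge_prob=0.4, seed=5)
        path = tmp_path / "edges.tsv"
        write_edge_list(g.edges, path)
        back = read_edge_list(path)
        assert back == g.edges

    def test_malformed_line_errors(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("a\tb\tc\n")
        with pytest.raises(ValueError, match="malformed"):
            read_edge_list(p)


class TestPathwayFeatures:
    def test_union_of_member_directions(self):
        feats = pathway_features(
            {"p1": ["g1", "g2"], "p2": ["g1"], "p3": ["g3"], "p4": []},
            {"g1": "up", "g2": "down", "g3": "down"})
        assert feats == {"p1": "Up|down", "p2": "Up", "p3": "Down", "p4": ""}
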