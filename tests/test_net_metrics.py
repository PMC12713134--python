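"""Network measures: hand-computed cases, symmetries, and oracle agreement."""

import math

import networkx as nx
import numpy as np
import pytest

import oracles
from syllnet.net_metrics import (
    DISCONNECT_SENTINEL,
    WEIGHT_MODES,
    all_pairs_distances,
    average_degree_connectivity,
    average_neighbor_degree,
    betweenness_centrality,
    closeness_centrality,
    closeness_vitality,
    strength,
    summarize_distribution,
    wiener_index,
)
from syllnet.transitions import replicate_edges


def directed_cycle(n, weight=1):
    g = nx.DiGraph()
    for i in range(n):
        g.add_edge(i, (i + 1) % n, weight=weight)
    return g


def bidirectional(edges):
    g = nx.DiGraph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
        g.add_edge(v, u, weight=w)
    return g


class TestStrength:
    def test_total_in_out(self):
        g = nx.DiGraph()
        g.add_edge(1, 2, weight=20)
        g.add_edge(3, 1, weight=3)
        assert strength(g, 1, "total") == 23
        assert strength(g, 1, "out") == 20
        assert strength(g, 1, "in") == 3

    def test_isolated_node_zero(self):
        g = nx.DiGraph()
        g.add_node(5)
        assert strength(g, 5) == 0

    def test_unknown_node_errors(self):
        with pytest.raises(KeyError):
            strength(nx.DiGraph(), 1)

    def test_replicated_equals_weighted(self, rng):
        for _ in range(100):
            net = oracles.random_digraph(rng, max_nodes=6)
            multi = replicate_edges(net)
            for v in net.nodes:
                for direction in ("in", "out", "total"):
                    assert strength(net, v, direction) == strength(multi, v, direction)


class TestAverageNeighborDegree:
    def test_star_hand_value(self):
        # Center <-> 3 leaves, all weights 1: every leaf has degree 2,
        # center strength 6, pair weight 2 -> (1/6)(2*2*3) = 2.
        g = bidirectional([(0, i, 1) for i in (1, 2, 3)])
        assert average_neighbor_degree(g, 0) == pytest.approx(2.0)

    def test_single_edge_hand_value(self):
        g = nx.DiGraph()
        g.add_edge(0, 1, weight=5)
        assert average_neighbor_degree(g, 0) == pytest.approx(1.0)

    def test_cycle_symmetry(self):
        g = directed_cycle(5)
        vals = {average_neighbor_degree(g, v) for v in g.nodes}
        assert len({round(v, 12) for v in vals}) == 1

    def test_isolated_node_is_missing(self):
        g = nx.DiGraph()
        g.add_node(0)
        g.add_edge(1, 2, weight=1)
        assert math.isnan(average_neighbor_degree(g, 0))


class TestAverageDegreeConnectivity:
    def test_cycle_single_key(self):
        g = directed_cycle(6)
        table = average_degree_connectivity(g)
        assert list(table) == [2]
        assert table[2] == pytest.approx(average_neighbor_degree(g, 0))

    def test_isolated_node_excluded(self):
        g = nx.DiGraph()
        g.add_edge(1, 2, weight=1)
        g.add_node(9)
        assert 0 not in average_degree_connectivity(g)

    def test_matches_two_pass_brute_force(self, rng):
        for _ in range(50):
            net = oracles.random_digraph(rng, max_nodes=7)
            table = average_degree_connectivity(net)
            groups = {}
            for v in net.nodes:
                k = net.in_degree(v) + net.out_degree(v)
                if k > 0:
                    groups.setdefault(k, []).append(average_neighbor_degree(net, v))
            assert set(table) == set(groups)
            for k in groups:
                assert table[k] == pytest.approx(np.mean(groups[k]))


class TestDistances:
    def test_three_cycle_unit(self):
        g = directed_cycle(3)
        oracle = all_pairs_distances(g, "unweighted")
        ds = [oracle.dist[s][t] for s in g for t in g if s != t]
        assert sorted(ds) == [1, 1, 1, 2, 2, 2]
        assert wiener_index(g, "unweighted") == 9

    def test_inverse_mode_scaling(self, rng):
        net = oracles.random_digraph(rng, max_nodes=6)
        doubled = net.copy()
        for u, v, d in doubled.edges(data=True):
            d["weight"] *= 2
        a = all_pairs_distances(net, "inverse")
        b = all_pairs_distances(doubled, "inverse")
        for s in net.nodes:
            for t, d in a.dist[s].items():
                assert b.dist[s][t] == pytest.approx(d / 2)

    def test_agrees_with_floyd_warshall(self, rng):
        for _ in range(150):
            net = oracles.random_digraph(rng, max_nodes=8)
            mode = ("raw", "inverse", "unweighted")[int(rng.integers(3))]
            nodes, d = oracles.floyd_warshall(net, mode)
            oracle = all_pairs_distances(net, mode)
            for i, s in enumerate(nodes):
                for j, t in enumerate(nodes):
                    if math.isfinite(d[i, j]):
                        assert oracle.dist[s][t] == pytest.approx(d[i, j])
                    else:
                        assert not oracle.reachable(s, t)

    def test_nonpositive_weight_errors(self):
        g = nx.DiGraph()
        g.add_edge(0, 1, weight=0)
        with pytest.raises(ValueError):
            all_pairs_distances(g, "raw")


class TestVitality:
    def test_cycle_closed_form(self):
        # Unit-weight directed n-cycle: W = n^2 (n-1) / 2.
        for n in (3, 4, 6):
            assert wiener_index(directed_cycle(n), "raw") == n * n * (n - 1) / 2

    def test_path_leaf_removal(self):
        g = bidirectional([(0, 1, 1), (1, 2, 1)])
        assert wiener_index(g, "raw") == 8
        assert closeness_vitality(g, 0, "raw") == 6

    def test_disconnecting_removal_returns_sentinel(self):
        g = bidirectional([(0, 1, 1), (1, 2, 1)])
        assert closeness_vitality(g, 1, "raw") == DISCONNECT_SENTINEL

    def test_matches_oracle_on_random_graphs(self, rng):
        for _ in range(60):
            net = oracles.random_digraph(rng, max_nodes=6)
            mode = ("raw", "inverse", "unweighted")[int(rng.integers(3))]
            for v in net.nodes:
                expected = oracles.vitality_fw(net, v, mode)
                got = closeness_vitality(net, v, mode)
                if expected == -math.inf:
                    assert got == DISCONNECT_SENTINEL
                else:
                    assert got == pytest.approx(expected)


class TestBetweenness:
    def test_star_center_carries_all_pairs(self):
        g = bidirectional([(0, i, 1) for i in (1, 2, 3, 4)])
        b = betweenness_centrality(g, "raw")
        assert b[0] == pytest.approx(12.0)
        assert all(b[i] == 0 for i in (1, 2, 3, 4))

    def test_complete_digraph_is_zero(self):
        g = nx.complete_graph(5, create_using=nx.DiGraph)
        nx.set_edge_attributes(g, 1, "weight")
        assert all(v == 0 for v in betweenness_centrality(g, "raw").values())

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(50):
            mode = ("raw", "inverse", "unweighted")[int(rng.integers(3))]
            # Dyadic weights keep inverse lengths exact, so shortest-path
            # ties are unambiguous for both routes.
            net = oracles.random_digraph(rng, max_nodes=5, dyadic=(mode == "inverse"))
            expected = oracles.betweenness_enum(net, mode)
            got = betweenness_centrality(net, mode)
            for v in net.nodes:
                assert got[v] == pytest.approx(expected[v]), (v, mode)

    def test_normalization_divides_by_pair_count(self):
        g = bidirectional([(0, i, 1) for i in (1, 2, 3, 4)])
        n = g.number_of_nodes()
        raw = betweenness_centrality(g, "raw")
        norm = betweenness_centrality(g, "raw", normalized=True)
        assert norm[0] == pytest.approx(raw[0] / ((n - 1) * (n - 2)))


class TestCloseness:
    def test_cycle_closed_form(self):
        for n in (3, 4, 5):
            g = directed_cycle(n)
            for v in g.nodes:
                assert closeness_centrality(g, v, "raw") == pytest.approx(2 / n)

    def test_complete_digraph_is_one(self):
        g = nx.complete_graph(4, create_using=nx.DiGraph)
        nx.set_edge_attributes(g, 1, "weight")
        assert all(
            c == pytest.approx(1.0)
            for c in closeness_centrality(g, weight_mode="raw").values()
        )

    def test_unreachable_node_scores_zero(self):
        g = nx.DiGraph()
        g.add_edge(0, 1, weight=1)
        g.add_node(2)
        assert closeness_centrality(g, 2, "raw") == 0.0

    def test_matches_oracle(self, rng):
        for _ in range(60):
            net = oracles.random_digraph(rng, max_nodes=7)
            mode = ("raw", "inverse", "unweighted")[int(rng.integers(3))]
            for v in net.nodes:
                assert closeness_centrality(net, v, mode) == pytest.approx(
                    oracles.closeness_fw(net, v, mode)
                )


class TestPermutationEquivariance:
    def test_relabeling_permutes_metrics(self, rng):
        net = oracles.random_digraph(rng, max_nodes=6)
        mapping = {v: v + 100 for v in net.nodes}
        relabeled = nx.relabel_nodes(net, mapping)
        b0 = betweenness_centrality(net, "raw")
        b1 = betweenness_centrality(relabeled, "raw")
        for v in net.nodes:
            assert b1[mapping[v]] == pytest.approx(b0[v])
            assert strength(relabeled, mapping[v]) == strength(net, v)
            assert closeness_centrality(relabeled, mapping[v], "raw") == pytest.approx(
                closeness_centrality(net, v, "raw")
            )


class TestSummaries:
    def test_robust_max_is_mean_of_top_three(self):
        s = summarize_distribution([1, 2, 3, 4, 5])
        assert s["robust_max"] == 4.0

    def test_constant_values(self):
        s = summarize_distribution([7, 7, 7])
        assert s == {"first_quartile": 7.0, "robust_max": 7.0}

    def test_quartile_linear_interpolation(self):
        assert summarize_distribution([0, 1, 2, 3])["first_quartile"] == pytest.approx(
            np.percentile([0, 1, 2, 3], 25)
        ) == pytest.approx(0.75)

    def test_robust_max_missing_below_three(self):
        assert math.isnan(summarize_distribution([1, 2])["robust_max"])

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize_distribution([])
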