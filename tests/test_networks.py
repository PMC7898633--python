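"""PPI graph analytics: Steiner subnetworks, betweenness, expansion,
enrichment."""

import numpy as np
import pytest

from herbimeta.io import PPIEdge, PPINetwork
from herbimeta.networks import (
    enrich_terms,
    expand_network,
    minimum_connected_network,
    node_centralities,
    recurrent_hubs,
    steiner_forest,
    top_betweenness,
)

from oracles import (
    brute_betweenness,
    brute_steiner_edges,
    hypergeom_upper_tail,
    random_graph,
)


def net_from_edges(edges, scores=None):
    net = PPINetwork()
    for k, (a, b) in enumerate(edges):
        c, e = (scores[k] if scores else (999, 500))
        net.add_edge(PPIEdge(a, b, c, e))
    return net


def nx_from_adj(adj):
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(adj)
    for u, nbrs in adj.items():
        for v in nbrs:
            g.add_edge(u, v)
    return g


class TestMinimumConnectedNetwork:
    def test_star_retains_the_only_connector(self):
        net = net_from_edges([("hub", f"leaf{i}") for i in range(4)])
        sub, dropped = minimum_connected_network(net, {"leaf0", "leaf1"})
        assert sub.nodes == {"hub", "leaf0", "leaf1"}
        assert not dropped

    def test_adjacent_seeds_need_no_extras(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c"),
                              ("a", "x"), ("x", "y")])
        sub, _ = minimum_connected_network(net, {"a", "b", "c"})
        assert sub.nodes == {"a", "b", "c"}

    def test_absent_seeds_are_dropped(self):
        net = net_from_edges([("a", "b")])
        sub, dropped = minimum_connected_network(net, {"a", "ghost"})
        assert dropped == {"ghost"}
        assert "a" in sub.nodes

    def test_empty_seed_set_errors(self):
        net = net_from_edges([("a", "b")])
        with pytest.raises(ValueError):
            minimum_connected_network(net, set())

    def test_seeds_in_one_component_stay_connected(self, rng):
        import networkx as nx

        for _ in range(30):
            adj = random_graph(rng, n_max=10, p=0.35, connected=True)
            g = nx_from_adj(adj)
            nodes = sorted(adj)
            k = int(rng.integers(2, min(4, len(nodes)) + 1))
            seeds = set(rng.choice(nodes, size=k, replace=False).tolist())
            retained, edges = steiner_forest(g, seeds)
            t = nx_from_adj({v: [] for v in retained})
            t.add_edges_from(edges)
            assert seeds <= retained
            assert nx.is_connected(t)

    def test_heuristic_within_twice_optimum(self, rng):
        for _ in range(25):
            adj = random_graph(rng, n_max=10, p=0.3, connected=True)
            g = nx_from_adj(adj)
            nodes = sorted(adj)
            k = int(rng.integers(2, min(4, len(nodes)) + 1))
            seeds = set(rng.choice(nodes, size=k, replace=False).tolist())
            _, edges = steiner_forest(g, seeds)
            opt = brute_steiner_edges(adj, seeds)
            assert opt is not None
            if opt == 0:
                assert len(edges) == 0
            else:
                assert len(edges) <= 2 * opt


class TestCentralities:
    def test_path_graph(self):
        net = net_from_edges([("a", "b"), ("b", "c")])
        stats = node_centralities(net)
        assert stats.at["b", "betweenness"] == 1.0
        assert stats.at["a", "betweenness"] == 0.0

    def test_complete_graph_all_zero(self):
        nodes = "abcd"
        net = net_from_edges([(u, v) for i, u in enumerate(nodes)
                              for v in nodes[i + 1:]])
        assert (node_centralities(net)["betweenness"] == 0).all()

    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(30):
            adj = random_graph(rng, n_max=8, p=0.4, connected=True)
            net = net_from_edges(
                [(u, v) for u, nbrs in adj.items() for v in nbrs if u < v]
            )
            stats = node_centralities(net)
            brute = brute_betweenness(adj)
            for node, expected in brute.items():
                assert stats.at[node, "betweenness"] == pytest.approx(expected)

    def test_expression_annotation_has_na_for_linkers(self):
        net = net_from_edges([("a", "b"), ("b", "c")])
        stats = node_centralities(net, seeds={"a", "c"},
                                  expression={"a": 2.5, "c": -1.0})
        assert stats.at["a", "expression"] == 2.5
        assert np.isnan(stats.at["b", "expression"])
        assert not stats.at["b", "is_seed"]


class TestTopBetweenness:
    def test_star_hub_first(self):
        net = net_from_edges([("hub", f"x{i}") for i in range(6)])
        stats = node_centralities(net)
        assert top_betweenness(stats, 1) == ["hub"]

    def test_all_zero_falls_back_to_degree_then_name(self):
        net = net_from_edges([("a", "b"), ("a", "c"), ("b", "c"),
                              ("c", "d"), ("b", "d"), ("a", "d")])
        stats = node_centralities(net)
        assert top_betweenness(stats, 4) == ["a", "b", "c", "d"]


class TestRecurrentHubs:
    def test_common_core_across_rankings(self):
        core = ["H1", "H2", "H3"]
        rankings = [core + [f"x{i}{j}" for j in range(12)] for i in range(4)]
        assert recurrent_hubs(rankings) == set(core)

    def test_disjoint_rankings_empty(self):
        assert recurrent_hubs([["a"], ["b"]]) == set()

    def test_needs_two_rankings(self):
        with pytest.raises(ValueError):
            recurrent_hubs([["a"]])


class TestExpandNetwork:
    def test_single_candidate_added_first_round(self):
        net = net_from_edges([("s", "n"), ("n", "far")])
        trace = expand_network(net, {"s"}, rounds=1, per_round=5)
        assert [n for n, _ in trace.rounds[0]] == ["n"]

    def test_higher_attachment_score_wins(self):
        net = net_from_edges(
            [("s1", "strong"), ("s2", "strong"), ("s1", "weak")],
            scores=[(999, 500), (999, 500), (999, 500)],
        )
        trace = expand_network(net, {"s1", "s2"}, rounds=1, per_round=1)
        assert trace.rounds[0][0][0] == "strong"

    def test_growth_is_nested_and_deterministic(self, rng):
        for _ in range(20):
            adj = random_graph(rng, n_max=10, p=0.35, connected=True)
            net = net_from_edges(
                [(u, v) for u, nbrs in adj.items() for v in nbrs if u < v]
            )
            seeds = {sorted(adj)[0]}
            t1 = expand_network(net, seeds, rounds=4, per_round=2)
            t2 = expand_network(net, seeds, rounds=4, per_round=2)
            assert t1.rounds == t2.rounds
            for r in range(len(t1.rounds)):
                assert t1.nodes_after_round(r) <= t1.nodes_after_round(r + 1)

    def test_truncates_when_exhausted(self):
        net = net_from_edges([("s", "a")])
        trace = expand_network(net, {"s"}, rounds=5, per_round=2)
        assert trace.truncated
        assert len(trace.rounds) == 1


class TestEnrichTerms:
    def test_worked_hypergeometric_example(self):
        universe = {f"u{i}" for i in range(20)}
        term = {f"u{i}" for i in range(5)}
        query = {f"u{i}" for i in range(4)} | {"u10"}
        table = enrich_terms(query, {"T": term}, universe)
        assert table.loc["T", "overlap"] == 4
        assert table.loc["T", "p"] == pytest.approx(4.902e-3, rel=1e-3)

    def test_matches_exact_enumeration(self, rng):
        for _ in range(30):
            M = int(rng.integers(8, 26))
            universe = {f"u{i}" for i in range(M)}
            term = set(rng.choice(sorted(universe),
                                  rng.integers(1, M), replace=False).tolist())
            query = set(rng.choice(sorted(universe),
                                   rng.integers(1, M), replace=False).tolist())
            table = enrich_terms(query, {"T": term}, universe)
            k = len(term & query)
            if k == 0:
                assert table.empty
            else:
                expected = hypergeom_upper_tail(M, len(term), len(query), k)
                assert table.loc["T", "p"] == pytest.approx(expected,
                                                            rel=1e-9)

    def test_term_equal_to_query_is_most_significant(self):
        universe = {f"u{i}" for i in range(15)}
        query = {"u0", "u1", "u2"}
        annotation = {"exact": set(query), "half": {"u0", "u5", "u6"},
                      "other": {"u9"}}
        table = enrich_terms(query, annotation, universe)
        assert table.index[0] == "exact"
        assert table.loc["exact", "p"] == min(table["p"])

    def test_holm_properties(self, rng):
        universe = {f"u{i}" for i in range(25)}
        annotation = {
            f"T{j}": set(rng.choice(sorted(universe), 6,
                                    replace=False).tolist())
            for j in range(8)
        }
        query = set(rng.choice(sorted(universe), 8, replace=False).tolist())
        table = enrich_terms(query, annotation, universe)
        if table.empty:
            return
        assert (table["p_adjusted"] >= table["p"] - 1e-15).all()
        sorted_adj = table.sort_values("p")["p_adjusted"].to_numpy()
        assert (np.diff(sorted_adj) >= -1e-15).all()

    def test_single_term_adjustment_is_identity(self):
        universe = {"a", "b", "c", "d"}
        table = enrich_terms({"a", "b"}, {"T": {"a", "c"}}, universe)
        assert table.loc["T", "p_adjusted"] == table.loc["T", "p"]

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            enrich_terms({"x"}, {"T": {"a"}}, {"a", "b"})
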