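import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cytometa import (
    central_nodes,
    centrality,
    fisher_enrichment,
    merge_networks,
    neighborhood,
    simulate_ppi,
)


def edge_df(pairs):
    return pd.DataFrame(pairs, columns=["a", "b"])


def brute_force_betweenness(g: nx.Graph) -> dict:
    """O(V^3) all-pairs shortest-path enumeration oracle."""
    nodes = list(g.nodes)
    btw = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for path in paths:
            for v in path[1:-1]:
                btw[v] += 1.0 / len(paths)
    return btw


class TestMergeNetworks:
    def test_edge_in_two_sources_recorded_once_with_both(self):
        g = merge_networks(
            [
                ("db1", edge_df([("A", "B"), ("B", "C"), ("C", "A")])),
                ("db2", edge_df([("b", "a"), ("c", "b"), ("a", "c")])),
            ]
        )
        assert g.number_of_edges() == 3
        assert g["A"]["B"]["sources"] == {"db1", "db2"}

    def test_self_loops_removed(self):
        g = merge_networks(
            [("db", edge_df([("A", "A"), ("A", "B"), ("B", "C"), ("C", "A")]))]
        )
        assert not any(u == v for u, v in g.edges)

    def test_degree_one_pruning_is_single_pass(self):
        # path A-B-C-D: A and D are degree-1, removed; B and C survive
        # even though the pass leaves them with degree 1
        g = merge_networks([("db", edge_df([("A", "B"), ("B", "C"), ("C", "D")]))])
        assert set(g.nodes) == {"B", "C"}
        assert g.has_edge("B", "C")

    def test_iterated_pruning_gives_two_core(self):
        with pytest.raises(ValueError):
            # the 2-core of a path is empty
            merge_networks(
                [("db", edge_df([("A", "B"), ("B", "C"), ("C", "D")]))],
                prune_iteratively=True,
            )

    def test_allow_list_filters_nonmatching_symbols(self):
        g = merge_networks(
            [("db", edge_df([("A", "B"), ("B", "C"), ("C", "A"), ("A", "X")]))],
            allowed_symbols={"A", "B", "C"},
        )
        assert "X" not in g.nodes

    def test_merge_is_idempotent(self):
        g = merge_networks(
            [("db", edge_df([("A", "B"), ("B", "C"), ("C", "A"), ("C", "D"), ("D", "A")]))]
        )
        again = merge_networks(
            [("m", pd.DataFrame(list(g.edges), columns=["a", "b"]))]
        )
        assert set(again.nodes) == set(g.nodes)
        assert set(map(frozenset, again.edges)) == set(map(frozenset, g.edges))

    def test_degree_sum_is_twice_edge_count(self):
        edges = simulate_ppi(60, 2, 0.08, seed=3)
        g = merge_networks([("sim", edges[["node_a", "node_b"]])])
        assert sum(d for _, d in g.degree()) == 2 * g.number_of_edges()


class TestNeighborhood:
    def test_all_nodes_as_seeds_returns_whole_graph(self):
        g = merge_networks([("db", edge_df([("A", "B"), ("B", "C"), ("C", "A")]))])
        sub = neighborhood(g, set(g.nodes))
        assert set(sub.nodes) == set(g.nodes)
        assert sub.number_of_edges() == g.number_of_edges()

    def test_star_center_seed_returns_star(self):
        star = nx.star_graph(5)
        g = nx.relabel_nodes(star, {i: f"N{i}" for i in star.nodes})
        sub = neighborhood(g, {"N0"})
        assert set(sub.nodes) == set(g.nodes)

    def test_toy_graph_matches_manual_expansion(self):
        g = nx.Graph(
            [
                ("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"),
                ("E", "F"), ("F", "G"), ("G", "H"), ("B", "G"),
            ]
        )
        sub = neighborhood(g, {"A", "E"})
        # A's neighbors: B; E's neighbors: D, F; induced edges among
        # {A, B, D, E, F}: A-B, D-E, E-F
        assert set(sub.nodes) == {"A", "B", "D", "E", "F"}
        expected_edges = {frozenset(e) for e in [("A", "B"), ("D", "E"), ("E", "F")]}
        assert set(map(frozenset, sub.edges)) == expected_edges

    def test_absent_seed_raises(self):
        g = nx.Graph([("A", "B")])
        with pytest.raises(ValueError):
            neighborhood(g, {"Z"})


class TestCentrality:
    def test_star_closed_form(self):
        g = nx.relabel_nodes(nx.star_graph(5), lambda i: f"N{i}")
        table = centrality(g)
        assert table.loc["N0", "betweenness"] == pytest.approx(10.0)  # C(5,2)
        assert (table.drop("N0")["betweenness"] == 0).all()
        assert table.loc["N0", "degree"] == 5

    def test_path_of_three_middle_node(self):
        g = nx.path_graph(3)
        table = centrality(nx.relabel_nodes(g, str))
        assert table.loc["1", "betweenness"] == pytest.approx(1.0)

    def test_matches_bruteforce_oracle_on_random_graphs(self):
        for seed in range(10):
            g = nx.gnp_random_graph(20, 0.2, seed=seed)
            g = nx.relabel_nodes(g, str)
            table = centrality(g)
            oracle = brute_force_betweenness(g)
            for node, expected in oracle.items():
                assert table.loc[node, "betweenness"] == pytest.approx(expected, abs=1e-9)


class TestCentralNodes:
    @staticmethod
    def _table(degree, btw, nodes=None):
        nodes = nodes or [f"n{i}" for i in range(len(degree))]
        return pd.DataFrame({"degree": degree, "betweenness": btw}, index=nodes)

    def test_identical_centralities_make_everyone_central(self):
        t = self._table([3] * 8, [1.0] * 8)
        central, top, _ = central_nodes(t)
        assert len(central) == 8 and len(top) == 8

    def test_high_degree_low_betweenness_excluded(self):
        degree = [10, 1, 1, 1, 1, 1, 1, 1, 1, 1]
        btw = [0.0, 5, 5, 5, 5, 5, 5, 5, 5, 9]
        central, _, _ = central_nodes(self._table(degree, btw), pct=90)
        assert "n0" not in central

    def test_planted_hubs_recovered(self):
        edges = simulate_ppi(100, 5, 0.05, seed=13)
        g = merge_networks([("sim", edges[["node_a", "node_b"]])])
        central, _, _ = central_nodes(centrality(g))
        hubs = {f"P{i:03d}" for i in range(1, 6)}
        assert hubs <= central

    def test_top_central_excludes_deg_encoded(self):
        t = self._table([5, 5, 1, 1], [2.0, 2.0, 0.0, 0.0])
        central, top, annotated = central_nodes(t, deg_encoded={"n0"}, pct=50)
        assert "n0" in central and "n0" not in top
        assert annotated.loc["n0", "is_central"]
        assert not annotated.loc["n0", "is_top_central"]

    def test_bad_percentile_rejected(self):
        t = self._table([1], [1.0])
        with pytest.raises(ValueError):
            central_nodes(t, pct=100)


class TestFisherEnrichment:
    def test_no_hits_gives_p_one(self):
        _, p = fisher_enrichment(0, 10, 5, 100)
        assert p == pytest.approx(1.0)

    def test_published_worked_example(self):
        """3 of 6 disease genes among 202 top-central nodes of a 5705-node
        network: one-sided p ~ 8.1e-4."""
        _, p = fisher_enrichment(3, 202, 6, 5705)
        assert p == pytest.approx(8.1e-4, abs=0.05e-3)

    def test_tail_matches_pmf_enumeration(self):
        from math import comb

        universe, category, draws = 10, 3, 4
        for hits in range(0, 4):
            _, p = fisher_enrichment(hits, draws, category, universe)
            oracle = sum(
                comb(category, k) * comb(universe - category, draws - k) / comb(universe, draws)
                for k in range(hits, min(draws, category) + 1)
            )
            assert p == pytest.approx(oracle, rel=1e-12)

    def test_monotone_in_hits(self):
        ps = [fisher_enrichment(h, 50, 20, 500)[1] for h in range(0, 21)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(7, 5, 10, 100)
        with pytest.raises(ValueError):
            fisher_enrichment(1, 5, 200, 100)
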