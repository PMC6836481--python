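"""Interaction-network construction, centrality, and key-node selection."""

from __future__ import annotations

import random

import pytest

from adiposcreen import (GeneSet, InteractionTable, build_network, centrality,
                         isolated_nodes, remove_nodes, select_key_nodes)
from adiposcreen.network import Network

from helpers import brute_force_betweenness

import networkx as nx


def _net(symbols, edges):
    g = nx.Graph()
    g.add_nodes_from(symbols)
    g.add_edges_from(edges)
    return Network(genes=GeneSet.from_symbols(symbols), graph=g)


class TestInteractionTable:
    def test_self_pairs_dropped_and_duplicates_keep_max(self):
        table = InteractionTable([("A", "A", 0.99), ("A", "B", 0.40),
                                  ("B", "A", 0.95)])
        assert table.rows == (("A", "B", 0.95),)

    def test_string_integer_scores_are_normalized(self):
        table = InteractionTable([("A", "B", 900), ("B", "C", 412)])
        assert table.rows == (("A", "B", 0.9), ("B", "C", 0.412))

    def test_out_of_range_confidence_rejected(self):
        with pytest.raises(ValueError):
            InteractionTable([("A", "B", 1234)])


class TestBuildNetwork:
    def test_threshold_keeps_high_confidence_edges_only(self):
        genes = GeneSet.from_symbols(["A", "B", "C"])
        table = InteractionTable([("A", "B", 0.95), ("B", "C", 0.50)])
        net = build_network(genes, table, 0.90)
        assert net.edges == (("A", "B"),)
        assert "C" in net.nodes  # present but unconnected

    def test_boundary_is_inclusive(self):
        genes = GeneSet.from_symbols(["A", "B"])
        net = build_network(genes, InteractionTable([("A", "B", 0.900)]), 0.900)
        assert net.edges == (("A", "B"),)

    def test_empty_gene_set_is_an_error(self):
        with pytest.raises(ValueError):
            build_network(GeneSet(), InteractionTable(), 0.9)

    def test_raising_threshold_never_adds_edges(self):
        rng = random.Random(5)
        rows = [(f"N{i}", f"N{j}", rng.random()) for i in range(8)
                for j in range(i + 1, 8)]
        genes = GeneSet.from_symbols([f"N{i}" for i in range(8)])
        table = InteractionTable(rows)
        previous = None
        for thr in (0.0, 0.25, 0.5, 0.75, 1.0):
            edges = set(build_network(genes, table, thr).edges)
            if previous is not None:
                assert edges <= previous
            previous = edges

    def test_synthetic_planted_edges_survive_threshold(self, default_bundle):
        m = default_bundle.manifest
        genes = GeneSet.from_symbols(m.network_genes)
        net = build_network(genes, default_bundle.interactions, 0.900)
        hubs = set(m.hub_genes)
        others = [v for v in m.network_genes
                  if v not in hubs and v != m.isolate_gene]
        expected = {tuple(sorted((h, o))) for h in hubs for o in others}
        expected |= {tuple(sorted(p)) for p in
                     [(a, b) for a in hubs for b in hubs if a < b]}
        assert set(net.edges) == expected


class TestIsolatesAndRemoval:
    def test_unconnected_node_is_isolated(self):
        net = _net(["A", "B", "C"], [("A", "B")])
        assert isolated_nodes(net).symbols == ("C",)

    def test_complete_graph_has_no_isolates(self):
        net = _net("ABCD", [(a, b) for a in "ABCD" for b in "ABCD" if a < b])
        assert len(isolated_nodes(net)) == 0

    def test_remove_nothing_is_identity(self):
        net = _net(["A", "B"], [("A", "B")])
        out = remove_nodes(net, GeneSet())
        assert out.nodes == net.nodes and out.edges == net.edges

    def test_remove_all_empties_the_network(self):
        net = _net(["A", "B"], [("A", "B")])
        out = remove_nodes(net, GeneSet.from_symbols(["A", "B"]))
        assert out.n_nodes == 0 and out.n_edges == 0

    def test_synthetic_isolate_detected_and_removed(self, default_bundle):
        m = default_bundle.manifest
        genes = GeneSet.from_symbols(m.network_genes)
        net = build_network(genes, default_bundle.interactions, 0.900)
        iso = isolated_nodes(net)
        assert iso.symbols == (m.isolate_gene,)
        trimmed = remove_nodes(net, iso)
        assert trimmed.n_nodes == len(m.network_genes) - 1


class TestCentrality:
    def test_path_graph(self):
        rep = centrality(_net("ABC", [("A", "B"), ("B", "C")]))
        assert rep.degree == {"A": 1, "B": 2, "C": 1}
        assert rep.betweenness == {"A": 0.0, "B": 1.0, "C": 0.0}
        assert rep.mean_degree == pytest.approx(4 / 3)
        assert rep.mean_betweenness == pytest.approx(1 / 3)

    def test_star_graph(self):
        rep = centrality(_net(["X", "L1", "L2", "L3"],
                              [("X", f"L{i}") for i in (1, 2, 3)]))
        assert rep.betweenness["X"] == pytest.approx(3.0)
        assert all(rep.betweenness[f"L{i}"] == 0.0 for i in (1, 2, 3))
        assert rep.mean_degree == pytest.approx(1.5)
        assert rep.mean_betweenness == pytest.approx(0.75)

    def test_complete_graph_betweenness_is_zero(self):
        net = _net("ABCDE", [(a, b) for a in "ABCDE" for b in "ABCDE" if a < b])
        rep = centrality(net)
        assert all(b == 0.0 for b in rep.betweenness.values())

    def test_double_count_flag_doubles_betweenness(self):
        net = _net("ABC", [("A", "B"), ("B", "C")])
        rep = centrality(net, double_count_pairs=True)
        assert rep.betweenness["B"] == pytest.approx(2.0)

    def test_empty_network_is_an_error(self):
        with pytest.raises(ValueError):
            centrality(_net([], []))

    def test_degree_sum_is_twice_edge_count_on_random_graphs(self):
        rng = random.Random(11)
        for _ in range(30):
            n = rng.randint(2, 9)
            nodes = [f"N{i}" for i in range(n)]
            edges = [(a, b) for i, a in enumerate(nodes)
                     for b in nodes[i + 1:] if rng.random() < 0.4]
            rep = centrality(_net(nodes, edges))
            assert sum(rep.degree.values()) == 2 * len(edges)

    def test_betweenness_matches_brute_force_enumeration(self):
        rng = random.Random(42)
        for _ in range(60):
            n = rng.randint(2, 7)
            nodes = [f"N{i}" for i in range(n)]
            edges = [(a, b) for i, a in enumerate(nodes)
                     for b in nodes[i + 1:] if rng.random() < 0.45]
            rep = centrality(_net(nodes, edges))
            oracle = brute_force_betweenness(nodes, edges)
            for v in nodes:
                assert rep.betweenness[v] == pytest.approx(oracle[v], abs=1e-9)


class TestSelectKeyNodes:
    def test_star_center_is_the_only_key_node(self):
        rep = centrality(_net(["X", "L1", "L2", "L3"],
                              [("X", f"L{i}") for i in (1, 2, 3)]))
        assert select_key_nodes(rep).symbols == ("X",)

    def test_path_middle_is_the_only_key_node(self):
        rep = centrality(_net("ABC", [("A", "B"), ("B", "C")]))
        assert select_key_nodes(rep).symbols == ("B",)

    def test_complete_graph_selects_everyone(self):
        net = _net("ABCD", [(a, b) for a in "ABCD" for b in "ABCD" if a < b])
        assert len(select_key_nodes(centrality(net))) == 4

    def test_some_node_always_meets_the_degree_mean(self):
        rng = random.Random(3)
        for _ in range(20):
            n = rng.randint(2, 8)
            nodes = [f"N{i}" for i in range(n)]
            edges = [(a, b) for i, a in enumerate(nodes)
                     for b in nodes[i + 1:] if rng.random() < 0.5]
            rep = centrality(_net(nodes, edges))
            assert any(rep.degree[v] >= rep.mean_degree for v in nodes)

    def test_synthetic_hubs_are_the_key_nodes(self, default_bundle):
        m = default_bundle.manifest
        genes = GeneSet.from_symbols(m.network_genes)
        net = build_network(genes, default_bundle.interactions, 0.900)
        trimmed = remove_nodes(net, isolated_nodes(net))
        keys = select_key_nodes(centrality(trimmed))
        assert sorted(keys.symbols) == m.hub_genes
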