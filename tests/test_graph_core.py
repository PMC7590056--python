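"""Interactome assembly, queries, and round-trip persistence."""

import itertools

import networkx as nx
import numpy as np
import pytest

from ppinet.graph_core import (
    ColumnSpec,
    EdgeRecord,
    Interactome,
    build_interactome,
    connected_components,
    induced_subgraph,
    merge,
    normalize_symbol,
    read_edge_list,
    read_graph,
    shortest_path_lengths,
    write_graph,
)

from helpers import build, components_oracle, distances_oracle, random_interactome


def rec(a, b, ta=None, tb=None, src=""):
    return EdgeRecord(a, b, ta, tb, src)


class TestReadEdgeList:
    def test_parses_all_rows(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene_a\tgene_b\nA\tB\nB\tC\nC\tA\n")
        records = read_edge_list(p)
        assert len(records) == 3
        assert records[0] == EdgeRecord("A", "B")

    def test_symbols_normalized(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene_a\tgene_b\n  app \tPsen1\n")
        (r,) = read_edge_list(p)
        assert (r.symbol_a, r.symbol_b) == ("APP", "PSEN1")
        assert normalize_symbol(normalize_symbol(" app ")) == "APP"

    def test_taxids_carried_through(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene_a\tgene_b\ttaxid_a\ttaxid_b\nA\tB\t10090\t10090\n")
        (r,) = read_edge_list(p)
        assert r.taxon_a == r.taxon_b == 10090

    def test_duplicates_kept_at_parse_then_collapsed_at_build(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene_a\tgene_b\nA\tB\nA\tB\n")
        records = read_edge_list(p)
        assert len(records) == 2
        g = build_interactome(records)
        assert g.number_of_edges() == 1

    @pytest.mark.parametrize(
        "content,err",
        [
            ("", "empty"),
            ("gene_a\tgene_b\n", "no rows"),
            ("wrong_a\tgene_b\nA\tB\n", "gene_a"),
        ],
    )
    def test_bad_files_raise(self, tmp_path, content, err):
        p = tmp_path / "e.tsv"
        p.write_text(content)
        with pytest.raises(ValueError, match=err):
            read_edge_list(p)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_edge_list(tmp_path / "nope.tsv")

    def test_malformed_rows_counted_not_silently_dropped(self, tmp_path, caplog):
        p = tmp_path / "e.tsv"
        p.write_text("gene_a\tgene_b\nA\tB\n\tC\nD\tE\n")
        with caplog.at_level("WARNING"):
            records = read_edge_list(p)
        assert len(records) == 2
        assert "1 malformed" in caplog.text


class TestBuildInteractome:
    def test_self_loops_and_duplicates_removed(self):
        g = build_interactome(
            [rec("A", "B"), rec("B", "A"), rec("A", "A"), rec("B", "C")]
        )
        assert g.edges == {("A", "B"), ("B", "C")}
        assert g.nodes == {"A", "B", "C"}
        assert g.build_report.removed_self == 1
        assert g.build_report.removed_dup == 1

    def test_taxon_filter_drops_foreign_edges(self):
        g = build_interactome(
            [rec("A", "B", 9606, 9606), rec("C", "D", 10090, 10090)],
            taxid_filter=9606,
        )
        assert g.edges == {("A", "B")}
        assert g.build_report.removed_taxon == 1

    def test_records_without_taxids_pass_filter(self):
        g = build_interactome([rec("A", "B")], taxid_filter=9606)
        assert g.edges == {("A", "B")}

    def test_all_filtered_out_raises(self):
        with pytest.raises(ValueError):
            build_interactome([rec("A", "B", 10090, 10090)], taxid_filter=9606)
        with pytest.raises(ValueError):
            build_interactome([])

    def test_counts_match_set_arithmetic_oracle(self, rng):
        # 50 random records vs a plain pair-set dedup
        syms = [f"N{i}" for i in range(12)]
        records = []
        for _ in range(50):
            a, b = rng.choice(len(syms), size=2)
            records.append(rec(syms[a], syms[b]))
        g = build_interactome(records)
        oracle_edges = {
            tuple(sorted((r.symbol_a, r.symbol_b)))
            for r in records
            if r.symbol_a != r.symbol_b
        }
        oracle_nodes = {s for r in records for s in (r.symbol_a, r.symbol_b)}
        assert g.edges == oracle_edges
        assert g.nodes == oracle_nodes


class TestMerge:
    def test_idempotent(self):
        g = build([("A", "B"), ("B", "C")])
        assert merge([g, g]) == g

    def test_disjoint_union_adds_edge_counts(self):
        g1 = build([("A", "B")])
        g2 = build([("C", "D"), ("D", "E")])
        assert merge([g1, g2]).number_of_edges() == 3

    def test_commutative_on_random_pairs(self, rng):
        for _ in range(20):
            g1 = random_interactome(rng, 15, 0.2)
            g2 = random_interactome(rng, 15, 0.2)
            assert merge([g1, g2]) == merge([g2, g1])

    def test_attrs_merged_max_count_union_sources(self):
        g1 = build([("A", "B")])
        g1.graph.nodes["A"].update(chemical_count=3, sources={"x"})
        g2 = build([("A", "C")])
        g2.graph.nodes["A"].update(chemical_count=7, sources={"y"})
        m = merge([g1, g2])
        assert m.chemical_count("A") == 7
        assert m.sources("A") == {"x", "y"}

    def test_node_union_conserved(self, rng):
        gs = [random_interactome(rng, 10, 0.3) for _ in range(3)]
        assert merge(gs).nodes == set().union(*(g.nodes for g in gs))


class TestInducedSubgraph:
    def test_identity_on_full_node_set(self):
        g = build([("A", "B"), ("B", "C")])
        assert induced_subgraph(g, g.nodes) == g

    def test_disjoint_genes_all_unmapped(self):
        g = build([("A", "B")])
        sub = induced_subgraph(g, {"X", "Y"})
        assert sub.number_of_nodes() == 0
        assert sub.n_unmapped == 2

    def test_triangle_with_pendant(self):
        g = build([("A", "B"), ("B", "C"), ("C", "A"), ("C", "D")])
        sub = induced_subgraph(g, {"A", "B", "D"})
        assert sub.nodes == {"A", "B", "D"}
        assert sub.edges == {("A", "B")}

    def test_edge_count_matches_brute_force(self, rng):
        g = random_interactome(rng, 20, 0.2)
        nodes = sorted(g.nodes)
        for _ in range(10):
            k = int(rng.integers(1, 15))
            s = {nodes[i] for i in rng.choice(len(nodes), size=k, replace=False)}
            expected = sum(1 for a, b in g.edges if a in s and b in s)
            assert induced_subgraph(g, s).number_of_edges() == expected


class TestConnectedComponents:
    def test_path_is_one_component(self):
        g = build([("A", "B"), ("B", "C")])
        assert connected_components(g) == [["A", "B", "C"]]

    def test_two_disjoint_edges(self):
        g = build([("A", "B"), ("C", "D")])
        comps = connected_components(g)
        assert [len(c) for c in comps] == [2, 2]
        assert comps[0][0] == "A"  # size tie broken by smallest symbol

    def test_matches_union_find_oracle(self, rng):
        g = random_interactome(rng, 100, 0.02)
        ours = [set(c) for c in connected_components(g)]
        oracle = components_oracle(g)
        assert sorted(map(sorted, ours)) == sorted(map(sorted, oracle))
        assert sum(len(c) for c in ours) == g.number_of_nodes()

    def test_empty_graph(self):
        assert connected_components(Interactome()) == []


class TestShortestPaths:
    def test_path_graph_end_to_end(self, path_graph):
        assert shortest_path_lengths(path_graph, {"A"}, {"E"}) == {"A": 4}

    def test_unreachable_absent_not_sentinel(self):
        g = build([("A", "B"), ("C", "D")])
        assert shortest_path_lengths(g, {"A"}, {"C"}) == {}

    def test_matches_matrix_power_oracle(self, rng):
        for _ in range(5):
            g = random_interactome(rng, 12, 0.25)
            dist = distances_oracle(g)
            nodes = sorted(g.nodes)
            targets = set(nodes[:4])
            got = shortest_path_lengths(g, set(nodes), targets)
            for s in nodes:
                cands = [dist[(s, t)] for t in targets if (s, t) in dist]
                if cands:
                    assert got[s] == min(cands)
                else:
                    assert s not in got

    def test_unknown_source_raises(self):
        g = build([("A", "B")])
        with pytest.raises(ValueError):
            shortest_path_lengths(g, {"Z"}, {"A"})


class TestRoundTrip:
    @pytest.fixture()
    def attributed_graph(self):
        g = build([("A", "B"), ("B", "C")], nodes=["LONER"])
        g.graph.nodes["A"].update(chemical_count=5, sources={"s1", "s2"})
        g.graph.nodes["LONER"].update(chemical_count=1, sources={"s1"})
        return g

    @pytest.mark.parametrize("fmt", ["tsv", "graphml"])
    def test_write_read_identity(self, tmp_path, attributed_graph, fmt):
        ext = "tsv" if fmt == "tsv" else "graphml"
        path = tmp_path / f"g.{ext}"
        write_graph(attributed_graph, path, format=fmt)
        assert read_graph(path, format=fmt) == attributed_graph

    def test_unknown_format_raises(self, tmp_path, attributed_graph):
        with pytest.raises(ValueError):
            write_graph(attributed_graph, tmp_path / "x", format="dot")
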