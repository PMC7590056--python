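"""Exact overrepresentation tests, BH-FDR, GMT I/O, and prioritization."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact

from ppinet.enrichment import (
    GeneSetCollection,
    bh_adjust,
    fisher_one_sided,
    hypergeom_upper_tail,
    module_enrichment,
    prioritize_modules,
    read_gmt,
    write_gmt,
)
from ppinet.mcode import NetworkModule

from helpers import bh_oracle, hypergeom_tail_oracle


class TestGmt:
    def test_two_line_file(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\tdesc one\tA\tB\tC\nS2\tdesc two\tD\tE\n")
        coll = read_gmt(p)
        assert len(coll) == 2
        assert coll.sets["S1"] == {"A", "B", "C"}
        assert coll.descriptions["S2"] == "desc two"

    def test_duplicate_gene_stored_once(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\td\tA\tA\tB\n")
        assert read_gmt(p).sets["S1"] == {"A", "B"}

    def test_empty_set_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\td\tA\nS2\td\t\t\n")
        with pytest.raises(ValueError, match=":2"):
            read_gmt(p)

    def test_round_trip_canonical_order(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S2\tsecond\tC\tB\nS1\tfirst\tZ\tA\n")
        coll = read_gmt(p)
        out = tmp_path / "out.gmt"
        write_gmt(coll, out)
        assert out.read_text() == "S1\tfirst\tA\tZ\nS2\tsecond\tB\tC\n"
        assert read_gmt(out).sets == coll.sets


class TestHypergeomUpperTail:
    def test_certain_event(self):
        assert hypergeom_upper_tail(3, 10, 3, 10) == 1.0

    def test_k_zero_is_one(self):
        assert hypergeom_upper_tail(0, 3, 3, 10) == 1.0

    def test_hand_combinatorics_example(self):
        # sum_{i=2,3} C(3,i) C(7,3-i) / C(10,3) = 22/120
        expected = hypergeom_tail_oracle(2, 3, 3, 10)
        assert expected == Fraction(22, 120)
        assert hypergeom_upper_tail(2, 3, 3, 10) == pytest.approx(float(expected))

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(5, 3, 3, 10)


class TestFisherOneSided:
    def test_equivalence_identity_on_worked_table(self):
        _, p = fisher_one_sided([[2, 1], [1, 6]])
        assert p == pytest.approx(hypergeom_upper_tail(2, 3, 3, 10))

    def test_zero_overlap_is_one(self):
        K, n, N = 4, 3, 12
        _, p = fisher_one_sided([[0, K], [n, N - K - n]])
        assert p == 1.0

    def test_odds_ratio_edge_cases(self):
        odds, _ = fisher_one_sided([[2, 0], [1, 6]])
        assert odds == float("inf")
        odds, _ = fisher_one_sided([[0, 3], [2, 6]])
        assert odds == 0.0

    def test_matches_enumeration_oracle_and_scipy(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            odds, p = fisher_one_sided([[a, b], [c, d]])
            exact = float(hypergeom_tail_oracle(a, a + b, a + c, a + b + c + d))
            assert p == pytest.approx(exact, abs=1e-12)
            # independent cross-check against the reference implementation
            sp = fisher_exact([[a, b], [c, d]], alternative="greater")
            assert p == pytest.approx(sp.pvalue, abs=1e-9)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_hand_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_adjust([0.01, 0.04, 0.9]) == pytest.approx([0.03, 0.06, 0.9])

    def test_tied_copies_stay_put(self):
        assert bh_adjust([0.2] * 5) == pytest.approx([0.2] * 5)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        ps=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20)
    )
    def test_matches_hand_oracle_and_order_invariance(self, ps):
        ours = bh_adjust(ps)
        assert ours == pytest.approx(bh_oracle(ps))
        assert np.all(ours >= np.asarray(ps) - 1e-12)
        rev = bh_adjust(ps[::-1])
        assert rev[::-1] == pytest.approx(list(ours))

    def test_discoveries_monotone_in_alpha(self, rng):
        ps = rng.uniform(0, 1, size=50)
        adj = bh_adjust(ps)
        counts = [np.sum(adj < a) for a in (0.01, 0.05, 0.1, 0.5)]
        assert counts == sorted(counts)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _module(label, genes):
    return NetworkModule(label, frozenset(genes), sorted(genes)[0], 1.0, 1)


class TestModuleEnrichment:
    def test_identical_module_and_set_is_near_minimal_p(self):
        universe = {f"G{i}" for i in range(1000)}
        genes = {f"G{i}" for i in range(20)}
        coll = GeneSetCollection("c", {"S": frozenset(genes)})
        df = module_enrichment([_module("M1", genes)], [coll], universe)
        row = df.iloc[0]
        assert row.k == row.n == 20
        assert row.p_value < 1e-30

    def test_disjoint_module_p_one_or_zero(self):
        universe = {f"G{i}" for i in range(100)}
        coll = GeneSetCollection("c", {"S": frozenset({"G1", "G2"})})
        df = module_enrichment(
            [_module("M1", {"G50", "G51", "G52"})], [coll], universe
        )
        assert df.iloc[0].p_value == 1.0
        assert df.iloc[0].odds_ratio == 0.0

    def test_planted_overlap_dwarfs_control(self):
        universe = {f"G{i:04d}" for i in range(5000)}
        module = {f"G{i:04d}" for i in range(60)}
        overlapping = frozenset(
            {f"G{i:04d}" for i in range(20)}  # 20 shared with the module
            | {f"G{i:04d}" for i in range(1000, 1080)}
        )
        control = frozenset({f"G{i:04d}" for i in range(2000, 2100)})
        coll = GeneSetCollection("c", {"hit": overlapping, "ctrl": control})
        df = module_enrichment([_module("M1", module)], [coll], universe)
        p_hit = df.loc[df.set_name == "hit", "p_value"].iloc[0]
        p_ctrl = df.loc[df.set_name == "ctrl", "p_value"].iloc[0]
        assert p_hit < 1e-6
        assert p_hit < p_ctrl * 1e-6

    def test_genes_outside_universe_dropped(self, caplog):
        universe = {"A", "B", "C", "D"}
        coll = GeneSetCollection("c", {"S": frozenset({"A", "ZZZ"})})
        with caplog.at_level("WARNING"):
            df = module_enrichment(
                [_module("M1", {"A", "B", "QQQ"})], [coll], universe
            )
        row = df.iloc[0]
        assert row.n == 2 and row.K == 1
        assert "outside universe" in caplog.text

    def test_bh_applied_within_collection(self):
        universe = {f"G{i}" for i in range(50)}
        c1 = GeneSetCollection("c1", {"S": frozenset({"G1", "G2"})})
        c2 = GeneSetCollection("c2", {"T": frozenset({"G3"})})
        df = module_enrichment([_module("M1", {"G1", "G2"})], [c1, c2], universe)
        assert set(df.collection) == {"c1", "c2"}
        assert (df.p_adjusted >= df.p_value - 1e-15).all()


class TestPrioritizeModules:
    def _results(self, rows):
        return pd.DataFrame(
            rows, columns=["module", "collection", "set_name", "p_value"]
        )

    def test_all_collections_rule_excludes_partial_hits(self):
        rows = [
            ("M1", "GWAS", "s", 0.001),
            ("M1", "DEG", "s", 0.01),
            ("M1", "BRAIN", "s", 0.2),  # misses the third collection
            ("M2", "GWAS", "s", 0.001),
            ("M2", "DEG", "s", 0.001),
            ("M2", "BRAIN", "s", 0.04),
        ]
        assert prioritize_modules(self._results(rows)) == ["M2"]

    def test_no_module_passes_gives_empty_list(self):
        rows = [("M1", "GWAS", "s", 0.9)]
        assert prioritize_modules(self._results(rows)) == []

    def test_ranked_by_combined_evidence(self):
        rows = [
            ("M1", "A", "s", 0.04),
            ("M1", "B", "s", 0.04),
            ("M2", "A", "s", 1e-8),
            ("M2", "B", "s", 1e-8),
        ]
        assert prioritize_modules(self._results(rows)) == ["M2", "M1"]

    def test_missing_required_collection_raises(self):
        rows = [("M1", "A", "s", 0.01)]
        with pytest.raises(ValueError):
            prioritize_modules(self._results(rows), required_collections=["A", "B"])


def test_exact_test_type_one_error_calibration(rng):
    """Resampled 2x2 tables at fixed margins reject at ~alpha (the exact
    test is slightly conservative; the band allows that)."""
    from scipy.stats import hypergeom

    N, K, n = 5000, 100, 60
    ks = hypergeom.rvs(N, K, n, size=2000, random_state=np.random.RandomState(7))
    ps = np.array([hypergeom_upper_tail(int(k), K, n, N) for k in ks])
    frac = float(np.mean(ps < 0.05))
    assert abs(frac - 0.05) < 0.02
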