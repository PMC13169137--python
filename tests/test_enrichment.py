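"""Over-representation testing, BH adjustment and term clustering."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.multitest import multipletests

from cisburden.enrichment import (
    EnrichmentResult, GeneSet, adjust_pvalues, bh_adjust, cluster_terms,
    hypergeom_ora, hypergeom_pvalue, read_gmt, significant, write_gmt,
)
from cisburden.errors import ConfigurationError, InputDataError


def enumeration_tail(k: int, N: int, K: int, n: int) -> float:
    """Exhaustive oracle: fraction of all n-draws from N with >= k successes."""
    items = list(range(N))
    successes = set(range(K))
    hits = sum(
        1 for draw in itertools.combinations(items, n)
        if len(successes.intersection(draw)) >= k
    )
    return hits / math.comb(N, n)


class TestReadGmt:
    def test_duplicate_genes_collapse(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("PATH1\tdesc\tA\tB\tA\n")
        (s,) = read_gmt(path)
        assert s.genes == frozenset({"A", "B"})

    def test_short_line_skipped(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("ONLYID\tdesc\nPATH1\tdesc\tA\n")
        assert [s.set_id for s in read_gmt(path)] == ["PATH1"]

    def test_empty_file_fatal(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("")
        with pytest.raises(InputDataError):
            read_gmt(path)

    def test_line_count_and_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        sets = [
            GeneSet(f"S{i}", f"set {i}",
                    frozenset(f"G{j}" for j in rng.choice(100, size=10, replace=False)))
            for i in range(30)
        ]
        path = tmp_path / "s.gmt"
        write_gmt(sets, path)
        back = read_gmt(path)
        assert len(back) == 30
        assert {s.set_id: s.genes for s in back} == {s.set_id: s.genes for s in sets}


class TestHypergeomOra:
    def test_complete_overlap_closed_form(self):
        # all 5 query genes inside a 5-gene set in a 20-gene universe
        assert hypergeom_pvalue(5, 20, 5, 5) == pytest.approx(1 / 15504, rel=1e-12)

    def test_zero_overlap_p_one(self):
        assert hypergeom_pvalue(0, 20, 5, 5) == 1.0

    def test_matches_enumeration_oracle_small_universes(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            N = int(rng.integers(4, 13))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert hypergeom_pvalue(k, N, K, n) == pytest.approx(
                enumeration_tail(k, N, K, n), abs=1e-12
            )

    def test_ora_counts_and_universe_intersection(self):
        universe = {f"G{i}" for i in range(20)}
        sets = [GeneSet("S1", "s", frozenset({"G0", "G1", "G2", "G3", "G4", "OUTSIDE"}))]
        results = hypergeom_ora({"G0", "G1", "G2", "G3", "G4"}, sets, universe)
        (r,) = results
        assert (r.k_overlap, r.K_set, r.n_query, r.N_universe) == (5, 5, 5, 20)
        assert r.p_value == pytest.approx(1 / 15504, rel=1e-12)

    def test_query_outside_universe_dropped_then_empty_fatal(self):
        sets = [GeneSet("S1", "s", frozenset({"A", "B", "C"}))]
        with pytest.raises(InputDataError):
            hypergeom_ora({"ZZ"}, sets, {"A", "B", "C"})

    def test_set_size_bounds(self):
        universe = {f"G{i}" for i in range(50)}
        sets = [
            GeneSet("TINY", "t", frozenset({"G0", "G1"})),
            GeneSet("OK", "o", frozenset({f"G{i}" for i in range(10)})),
        ]
        results = hypergeom_ora({"G0", "G1", "G2"}, sets, universe, min_set_size=3)
        assert [r.set_id for r in results] == ["OK"]


class TestBhAdjustment:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=60))
    def test_matches_statsmodels(self, pvals):
        ours = bh_adjust(pvals)
        reference = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(ours, reference, atol=1e-12)

    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=2, max_size=40))
    def test_monotone_in_raw_p(self, pvals):
        adjusted = bh_adjust(pvals)
        order = np.argsort(pvals)
        assert np.all(np.diff(adjusted[order]) >= -1e-15)

    def test_adjust_pvalues_preserves_order_and_fields(self):
        results = [
            EnrichmentResult("S1", "a", 3, 5, 5, 20, 0.04, frozenset()),
            EnrichmentResult("S2", "b", 1, 5, 5, 20, 0.5, frozenset()),
        ]
        adjusted = adjust_pvalues(results)
        assert [r.set_id for r in adjusted] == ["S1", "S2"]
        assert all(r.p_adjusted >= r.p_value for r in adjusted)


class TestSignificant:
    def test_strict_boundary(self):
        results = adjust_pvalues([
            EnrichmentResult("A", "a", 1, 1, 1, 10, 0.049, frozenset()),
        ])
        # force exact adjusted values for the boundary check
        from dataclasses import replace
        at = replace(results[0], p_adjusted=0.049)
        on = replace(results[0], set_id="B", p_adjusted=0.05)
        assert [r.set_id for r in significant([at, on])] == ["A"]

    def test_requires_adjustment_first(self):
        with pytest.raises(ConfigurationError):
            significant([EnrichmentResult("A", "a", 1, 1, 1, 10, 0.01, frozenset())])


class TestClusterTerms:
    def _result(self, sid, padj):
        return EnrichmentResult(sid, sid, 1, 5, 5, 20, padj, frozenset(), p_adjusted=padj)

    def test_identical_sets_one_cluster(self):
        sets = [GeneSet("A", "A", frozenset({"x", "y"})), GeneSet("B", "B", frozenset({"x", "y"}))]
        clusters = cluster_terms([self._result("A", 0.01), self._result("B", 0.02)], sets)
        assert len(clusters) == 1
        assert clusters[0].representative_set_id == "A"
        assert set(clusters[0].member_set_ids) == {"A", "B"}

    def test_disjoint_sets_singletons(self):
        sets = [GeneSet("A", "A", frozenset({"x"})), GeneSet("B", "B", frozenset({"y"}))]
        clusters = cluster_terms([self._result("A", 0.01), self._result("B", 0.02)], sets)
        assert sorted(len(c.member_set_ids) for c in clusters) == [1, 1]

    def test_single_linkage_chain(self):
        sets = [
            GeneSet("A", "A", frozenset({"1", "2", "3", "4"})),
            GeneSet("B", "B", frozenset({"3", "4", "5", "6"})),
            GeneSet("C", "C", frozenset({"5", "6", "7", "8"})),
        ]
        results = [self._result(s, p) for s, p in [("A", 0.01), ("B", 0.02), ("C", 0.03)]]
        # A~B and B~C share 2/6; A~C share 0
        clusters = cluster_terms(results, sets, tau=1 / 3)
        assert len(clusters) == 1 and set(clusters[0].member_set_ids) == {"A", "B", "C"}

    def test_clusters_partition_significant_terms(self):
        rng = np.random.default_rng(7)
        sets = [
            GeneSet(f"S{i}", f"S{i}",
                    frozenset(f"G{j}" for j in rng.choice(40, size=8, replace=False)))
            for i in range(12)
        ]
        results = [self._result(s.set_id, float(rng.uniform(0.001, 0.04))) for s in sets]
        clusters = cluster_terms(results, sets, tau=0.3)
        members = [sid for c in clusters for sid in c.member_set_ids]
        assert sorted(members) == sorted(r.set_id for r in results)
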