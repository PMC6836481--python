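"""Hypergeometric tail, multiple-testing correction, and term enrichment."""

from __future__ import annotations

from fractions import Fraction

import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from adiposcreen import (AnnotationDatabase, GeneSet, correct_pvalues, enrich,
                         genes_of, hypergeometric_tail)
from adiposcreen.enrichment import EnrichmentResult
from adiposcreen.fixtures import PATHWAY_ROWS

from helpers import enumerate_hypergeometric_tail


class TestHypergeometricTail:
    @pytest.mark.parametrize("k,K,n,N,expected", [
        (0, 5, 4, 10, 1.0),                    # P(X>=0) = 1
        (4, 5, 4, 10, 5 / 210),                # enumeration of C(10,4) draws
        (6, 6, 6, 6, 1.0),                     # every gene annotated
        (1, 2, 2, 4, Fraction(5, 6)),          # small exact case
    ])
    def test_known_values(self, k, K, n, N, expected):
        assert hypergeometric_tail(k, K, n, N) == pytest.approx(
            float(expected), abs=1e-15)

    @pytest.mark.parametrize("k,K,n,N", [
        (5, 4, 10, 10),   # k > min(K, n)
        (0, 11, 4, 10),   # K > N
        (0, 5, 11, 10),   # n > N
        (-1, 5, 4, 10),   # negative count
    ])
    def test_invalid_bounds_raise(self, k, K, n, N):
        with pytest.raises(ValueError):
            hypergeometric_tail(k, K, n, N)

    def test_matches_enumeration_on_a_small_grid(self):
        for N in range(1, 9):
            for n in range(1, N + 1):
                for K in range(N + 1):
                    for k in range(min(K, n) + 1):
                        exact = enumerate_hypergeometric_tail(k, K, n, N)
                        assert hypergeometric_tail(k, K, n, N) == \
                            pytest.approx(float(exact), abs=1e-12)

    @given(st.integers(1, 60).flatmap(
        lambda N: st.tuples(st.just(N), st.integers(0, N), st.integers(1, N))))
    def test_non_increasing_in_k_and_matches_scipy(self, KnN):
        N, K, n = KnN
        tails = [hypergeometric_tail(k, K, n, N)
                 for k in range(min(K, n) + 1)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))
        for k, t in enumerate(tails):
            sf = scipy.stats.hypergeom.sf(k - 1, N, K, n)
            assert t == pytest.approx(sf, rel=1e-9, abs=1e-12)

    def test_stays_positive_for_extreme_tails(self):
        p = hypergeometric_tail(300, 300, 300, 600)
        assert 0.0 < p < 1e-150


class TestCorrectPvalues:
    def test_single_bh_is_identity(self):
        assert correct_pvalues([0.04], "BH") == [pytest.approx(0.04)]

    def test_bh_step_up_with_cummin(self):
        # 0.01*3/1, 0.02*3/2, 0.03*3/3 then cumulative minimum from the top
        assert correct_pvalues([0.01, 0.02, 0.03], "BH") == \
            pytest.approx([0.03, 0.03, 0.03])

    def test_bonferroni_multiplies_by_m(self):
        assert correct_pvalues([0.05, 0.05], "bonferroni") == \
            pytest.approx([0.10, 0.10])

    def test_none_returns_input(self):
        assert correct_pvalues([0.2, 0.8], "none") == [0.2, 0.8]

    def test_unknown_method_raises(self):
        with pytest.raises(ValueError):
            correct_pvalues([0.5], "holm-sidak-ish")

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_out_of_range_pvalues_raise(self, bad):
        with pytest.raises(ValueError):
            correct_pvalues([bad])

    @given(st.lists(st.floats(1e-12, 1.0, exclude_min=False), min_size=1,
                    max_size=20))
    def test_bh_order_invariant_and_below_bonferroni(self, pvals):
        bh = correct_pvalues(pvals, "BH")
        bonf = correct_pvalues(pvals, "bonferroni")
        assert all(b <= f + 1e-12 for b, f in zip(bh, bonf))
        # reversing the input permutes the output identically
        rev = correct_pvalues(list(reversed(pvals)), "BH")
        assert rev == pytest.approx(list(reversed(bh)))


def _db(terms: dict[str, list[str]], N: int | None = None,
        namespace: str = "BP") -> AnnotationDatabase:
    return AnnotationDatabase(
        namespace=namespace,
        terms={t: GeneSet.from_symbols(s, label=t) for t, s in terms.items()},
        universe_size=N)


class TestEnrich:
    def test_single_term_example(self):
        """n=5 query against a K=5 term in a N=20 universe: k=4 and
        p = (5*15+1)/C(20,5) ~ 4.902e-3, retained at cutoff 0.01."""
        query = GeneSet.from_symbols([f"g{i}" for i in range(1, 6)])
        db = _db({"T": ["g1", "g2", "g3", "g4", "g6"]}, N=20)
        results = enrich(query, db, cutoff=0.01)
        assert [r.term for r in results] == ["T"]
        r = results[0]
        assert (r.k, r.K, r.n, r.N) == (4, 5, 5, 20)
        assert r.p_raw == pytest.approx(76 / 15504, abs=1e-15)
        assert r.p_corrected == pytest.approx(76 / 15504, abs=1e-15)
        assert sorted(r.genes.symbols) == ["G1", "G2", "G3", "G4"]

    def test_disjoint_query_yields_empty(self):
        query = GeneSet.from_symbols(["x1", "x2"])
        db = _db({"T": ["y1", "y2"]}, N=20)
        assert enrich(query, db, cutoff=0.5) == []

    def test_empty_query_is_an_error(self):
        with pytest.raises(ValueError):
            enrich(GeneSet(), _db({"T": ["a"]}, N=5), 0.5)

    def test_lowering_cutoff_never_adds_terms(self):
        query = GeneSet.from_symbols([f"g{i}" for i in range(10)])
        terms = {f"T{j}": [f"g{i}" for i in range(j)] + [f"z{j}{i}" for i in range(5)]
                 for j in range(1, 9)}
        db = _db(terms, N=100)
        previous: set[str] | None = None
        for cutoff in (0.9, 0.5, 0.1, 0.01, 1e-4):
            got = {r.term for r in enrich(query, db, cutoff)}
            if previous is not None:
                assert got <= previous
            previous = got

    def test_results_sorted_by_corrected_p_then_term(self):
        query = GeneSet.from_symbols([f"g{i}" for i in range(8)])
        db = _db({"B": ["g0", "g1", "g2", "n1"],
                  "A": ["g0", "g1", "g2", "n2"],
                  "C": ["g0", "n3", "n4", "n5"]}, N=60)
        results = enrich(query, db, cutoff=0.999)
        ps = [r.p_corrected for r in results]
        assert ps == sorted(ps)
        assert [r.term for r in results][:2] == ["A", "B"]  # tie on p

    def test_synthetic_planted_terms_recovered_exactly(self, default_bundle):
        m = default_bundle.manifest
        query = GeneSet.from_symbols(m.core_genes)
        results = enrich(query, default_bundle.bp_db, cutoff=1.00e-07)
        assert sorted(r.term for r in results) == m.bp_planted_terms
        for r in results:
            assert sorted(r.genes.symbols) == sorted(m.bp_overlaps[r.term])


class TestGenesOf:
    def test_empty(self):
        assert len(genes_of([])) == 0

    def test_union_of_two_results(self):
        def res(term, symbols):
            gs = GeneSet.from_symbols(symbols)
            return EnrichmentResult(term=term, k=len(gs), K=5, n=5, N=50,
                                    p_raw=0.01, p_corrected=0.02, genes=gs)
        union = genes_of([res("t1", ["A", "B"]), res("t2", ["B", "C"])])
        assert sorted(union.symbols) == ["A", "B", "C"]

    def test_printed_pathway_rows_union_to_27_genes(self):
        union = GeneSet()
        for row in PATHWAY_ROWS:
            union = union.union(row.gene_set())
        assert len(union) == 27


class TestAnnotationDatabase:
    def test_universe_defaults_to_annotated_union(self):
        db = _db({"T1": ["a", "b"], "T2": ["b", "c"]})
        assert db.universe_size == 3

    def test_universe_below_union_rejected(self):
        with pytest.raises(ValueError):
            _db({"T1": ["a", "b", "c"]}, N=2)

    def test_empty_term_rejected(self):
        with pytest.raises(ValueError):
            AnnotationDatabase(namespace="BP", terms={"T": GeneSet()})
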