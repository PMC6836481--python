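"""Gene-set enrichment against an annotation database.

The statistic is the hypergeometric upper tail: the probability of seeing
at least ``k`` annotated genes in a size-``n`` query drawn without
replacement from a size-``N`` universe containing ``K`` annotated genes,

    P(X >= k) = sum_{i=k}^{min(K,n)} C(K,i) C(N-K,n-i) / C(N,n).

It is evaluated in exact integer arithmetic (Python's unbounded ints via
``math.comb``), so the tail stays accurate and positive even when the
probability is far below double-precision normal range. Raw p-values are
corrected across the tested terms (Benjamini–Hochberg by default) and
terms passing a corrected-p cutoff are returned.

The cascade applies this twice: biological-process terms at cutoff
1.00e-07, then pathway terms — against the gene union of the first
stage's hits — at 1.00e-06.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

from statsmodels.stats.multitest import multipletests

from .genes import GeneSet

#: Annotation namespaces the two enrichment stages use.
NAMESPACES = ("BP", "PATHWAY")

# smallest positive double; used as a floor so the returned tail
# probability is always > 0, as the statistic itself is
_TINY = 5e-324


@dataclass
class AnnotationDatabase:
    """Term -> gene-set map in one namespace, with its gene universe size.

    ``universe_size`` defaults to the number of distinct genes appearing
    in any term (the annotation universe implied by the database) and may
    be overridden when the true universe is known to be larger.
    """

    namespace: str
    terms: dict[str, GeneSet]
    universe_size: int | None = None

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise ValueError(
                f"namespace must be one of {NAMESPACES}, got {self.namespace!r}")
        for name, gs in self.terms.items():
            if len(gs) == 0:
                raise ValueError(f"term {name!r} has an empty gene set")
        union_ids: set[str] = set()
        for gs in self.terms.values():
            union_ids.update(gs.gene_ids)
        if self.universe_size is None:
            self.universe_size = len(union_ids)
        elif self.universe_size < len(union_ids):
            raise ValueError(
                f"universe_size {self.universe_size} is smaller than the "
                f"{len(union_ids)} distinct annotated genes")

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class EnrichmentResult:
    """One enriched term: overlap counts, p-values, and overlap genes.

    ``k`` genes of the size-``n`` query fall in the term's size-``K``
    gene set within a size-``N`` universe.
    """

    term: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_corrected: float
    genes: GeneSet

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError(f"invalid overlap k={self.k} for K={self.K}, n={self.n}")
        if not (0.0 < self.p_raw <= 1.0 and 0.0 < self.p_corrected <= 1.0):
            raise ValueError("p-values must lie in (0, 1]")
        if self.p_corrected < self.p_raw:
            raise ValueError("corrected p-value cannot be below the raw p-value")
        if len(self.genes) != self.k:
            raise ValueError(
                f"overlap gene set has {len(self.genes)} members, expected k={self.k}")


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P(X >= k) of a hypergeometric draw.

    Draw ``n`` genes from a universe of ``N`` containing ``K`` annotated
    ones; return the probability of at least ``k`` annotated genes in the
    draw. Exact integer arithmetic; the result is clamped to stay > 0.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if K > N or n > N:
        raise ValueError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K, n)={min(K, n)}")
    if k == 0:
        return 1.0
    hi = min(K, n)
    numerator = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, hi + 1))
    p = float(Fraction(numerator, math.comb(N, n)))
    return max(p, _TINY) if numerator > 0 else _TINY


#: Supported multiple-testing corrections.
CORRECTION_METHODS = ("BH", "bonferroni", "none")


def correct_pvalues(pvals: Sequence[float], method: str = "BH") -> list[float]:
    """Multiple-testing correction, preserving input order.

    ``BH`` is the Benjamini–Hochberg step-up (with cumulative-minimum
    enforcement, capped at 1), ``bonferroni`` multiplies by the test
    count, ``none`` returns the values unchanged.
    """
    if method not in CORRECTION_METHODS:
        raise ValueError(f"unknown correction method {method!r}; "
                         f"choose from {CORRECTION_METHODS}")
    pvals = list(pvals)
    for p in pvals:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-values must lie in (0, 1], got {p!r}")
    if not pvals:
        return []
    if method == "none":
        return [float(p) for p in pvals]
    sm_method = {"BH": "fdr_bh", "bonferroni": "bonferroni"}[method]
    corrected = multipletests(pvals, method=sm_method)[1]
    return [float(p) for p in corrected]


def enrich(query: GeneSet, db: AnnotationDatabase, cutoff: float,
           method: str = "BH") -> list[EnrichmentResult]:
    """Terms whose corrected enrichment p-value passes ``cutoff``.

    Only terms overlapping the query (k >= 1) enter the correction; the
    returned list is sorted by corrected p-value, ties broken by term
    name. A query disjoint from every term yields an empty list.
    """
    if len(query) == 0:
        raise ValueError("query gene set must be nonempty")
    if not (0.0 < cutoff < 1.0):
        raise ValueError(f"cutoff must lie in (0, 1), got {cutoff!r}")
    n = len(query)
    N = db.universe_size
    assert N is not None
    tested: list[tuple[str, int, int, float, GeneSet]] = []
    for term in sorted(db.terms):
        term_set = db.terms[term]
        # annotation databases are symbol-keyed (GMT), so the overlap
        # joins on symbols; the query's own Gene records are carried
        term_symbols = set(term_set.symbols)
        overlap = GeneSet((g for g in query if g.symbol in term_symbols),
                          label=term)
        k = len(overlap)
        if k == 0:
            continue
        K = len(term_set)
        p_raw = hypergeometric_tail(k, K, min(n, N), N)
        tested.append((term, k, K, p_raw, overlap))
    if not tested:
        return []
    corrected = correct_pvalues([t[3] for t in tested], method=method)
    results = [
        EnrichmentResult(term=term, k=k, K=K, n=n, N=N, p_raw=p_raw,
                         p_corrected=p_corr, genes=overlap)
        for (term, k, K, p_raw, overlap), p_corr in zip(tested, corrected)
        if p_corr <= cutoff
    ]
    results.sort(key=lambda r: (r.p_corrected, r.term))
    return results


def genes_of(results: Sequence[EnrichmentResult]) -> GeneSet:
    """Deduplicated union of the overlap genes across enrichment results."""
    out = GeneSet(label="enriched-genes")
    for r in results:
        out = out.union(r.genes, label=out.label)
    return out
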