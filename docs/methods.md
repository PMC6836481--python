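# Methods notes

## The screening cascade

The package implements a desk screen for drug repositioning against
white-fat browning. It is a cascade of set-algebra and filtering
operations rather than a fitted model: each stage consumes a gene set
(or drug list) and emits a smaller one, except the anchor-augmentation
stage, which is the single point where the list grows. The stages and
their contracts are described below together with the choices that were
genuinely open and how they were settled.

## Literature mining

A local literature-association table stands in for a literature search
engine: documents carry keyword text and genes are linked to documents.
`query_genes` returns the genes linked to at least one document whose
text contains the query phrase as a **case-insensitive exact
substring**. No stemming, tokenization, or synonym expansion is applied:
the original screen delegated matching to an external engine whose rules
are unknown, and an exact-substring rule is the simplest contract that
is fully auditable in tests. Gene identity is the stable `gene_id`;
symbols are normalized to uppercase and may collide without merging
records. Outputs are ordered alphabetically by symbol (ties by id) so
all downstream artifacts are deterministic.

## Enrichment statistic

The enrichment p-value is the hypergeometric upper tail P(X ≥ k). It is
evaluated in **exact integer arithmetic** (`math.comb` over Python's
unbounded integers, converted through `fractions.Fraction`), not in
floating point: the sums involved are alternating-magnitude-free, so the
only rounding is the final conversion to double, and the tail remains
accurate and positive even when far below 1e−300 would underflow a
naive product. The result is floored at the smallest positive double so
the documented invariant p > 0 holds in all cases.

Terms that do not overlap the query (k = 0) are excluded *before*
multiple-testing correction: they carry no evidence and would only
inflate the correction burden — this mirrors how co-annotation tools
treat a query. Correction is Benjamini–Hochberg by default (step-up with
cumulative-minimum enforcement, capped at 1, delegated to
`statsmodels.stats.multitest`); Bonferroni and `none` are available. BH
was chosen because the original tool's correction is unnamed, BH is the
de-facto default for enrichment software, and corrected ≥ raw matches
the published table's column semantics. The annotation universe N
defaults to the number of distinct genes in the GMT file and can be
overridden when the true universe is known to be larger; the original
universe is unpublished, so printed p-values (e.g. 8.3154e−21) are not
reproduction targets — the statistic is instead verified against an
exhaustive draw-enumeration oracle.

The cascade applies the statistic twice, as published: process
annotations at cutoff 1.00e−07 against the text-mining intersection,
then pathway annotations at 1.00e−06 against the union of the passing
process terms' genes. Results sort by corrected p, ties by term name.

## Network stage

The interaction network is the induced graph over the candidate genes
with edges at confidence ≥ 0.900 (inclusive). The score dialect accepts
either a 0–999 integer (divided by 1000) or a 0–1 decimal; self-pairs
are dropped and duplicate unordered pairs keep the maximum score.

Betweenness follows the Freeman convention — undirected, unnormalized,
endpoints excluded, fractional attribution across equally short paths,
each unordered pair counted once — computed via networkx's Brandes
implementation and checked in the test suite against a hand-written
all-shortest-paths enumerator. A `double_count_pairs` flag doubles the
values for sensitivity checks against tools that count ordered pairs.
Key nodes must meet **both** the mean degree and the mean betweenness;
comparisons are inclusive, with both sides rounded to 10 decimals so an
exact tie can never be lost to float noise. Means are taken over the
analyzed network, i.e. after isolate removal, matching the published
order of operations (isolates flagged first, centrality run on the
remainder).

The published centrality summary itself (mean degree 32.00 over a
27-node network) is arithmetically impossible for a simple graph of that
size (max degree 26), so the printed means and the identity of the 9 key
genes are treated as packaged inputs, never as computation targets.

## Anchor augmentation and fixtures

The final list is the key nodes plus the genes of the anchor process
term, "brown fat cell differentiation" — deduplicated, key genes first,
novel anchor genes appended alphabetically. The packaged anchor row
lists 13 symbols against a printed count of 12; the symbols are taken as
authoritative because together with the 9 key genes they reproduce the
published 18-gene final list exactly. All fixture symbols are preserved
verbatim, including the evident typo "LPN1" (for LPIN1); a normalization
map can be applied explicitly but never is by default.

## Drug funnel

Drugs match if any target symbol is in the final gene list (drug
catalogs are symbol-keyed, so the join is on symbols). Three independent
predicates follow: a status whitelist (launched, phase I/II/III clinical
trial, pre-registration, registered — matched case-insensitively as
distinct tokens), a boolean development-detail flag (the original
screen's manual inspection of trial records is not mechanizable, so the
catalog carries the judgment as data), and a mechanism blacklist (beta-1
adrenoceptor agonists and antagonists, interleukin-6 antagonists,
CREB-binding protein inhibitors). The filters commute and are
idempotent; the funnel report asserts non-increasing counts. Combination
drugs are single records listing all component targets. The original
622/158/81/33 counts depended on a proprietary catalog and are not
reproduction targets; the funnel's correctness is certified on planted
synthetic catalogs instead.

## Synthetic studies: what they emulate, and what they do not

The generator plants unambiguous signal at every stage, with defaults
chosen once from design calculations (Poisson approximations of the
hypergeometric tails, closed-form centrality of the planted topology)
so that each planted effect clears its stage threshold with orders of
magnitude to spare and each decoy cannot reach it:

- **Genome**: 2,000 genes (`G0000`…), ids distinct from symbols.
- **Corpus**: a 30-gene common core linked to documents of all three
  query phrases, 50 extra genes per query, 120 decoy genes on neutral
  documents — so each query returns core+extras and the intersection is
  exactly the core. Query phrases must not be substrings of one another
  (validated), or substring matching could not separate them.
- **Process terms**: three planted terms with overlaps k = 15, 14, 16
  and sizes K = 40, 35, 60 against the 30-gene query in a ~900-gene
  annotation universe — tails around 1e−11 and below, versus a 1.00e−07
  cutoff — among 20 decoy terms that overlap the query in at most one
  gene (corrected p ≈ 0.5 or excluded at k = 0). Pathway terms: two
  planted (k = 14/K = 30, k = 13/K = 35) among 12 decoys, same logic at
  1.00e−06.
- **Network**: over the pathway-stage genes, 3 hubs are wired to every
  other non-isolate node (hub clique plus hub–periphery star) at
  confidence ≥ 0.900, one isolate receives only sub-threshold edges, and
  60 low-confidence decoy edges plus 40 background edges are added. In
  this topology hubs hold all the betweenness and the highest degrees,
  so the dual mean-threshold rule selects exactly the hubs; the
  generator re-checks this, and every other planted claim, with the
  pipeline's own modules at generation time and refuses to emit a bundle
  that violates its manifest.
- **Drugs**: 33 eligible drugs with the class composition of the
  published final list (18 PPAR-γ agonists, 4 β3-adrenoceptor agonists,
  1 insulin sensitizer, 3 insulins, 6 lipase-clearing-factor stimulants,
  1 other), plus 40 off-target, 25 wrong-status, 15 undocumented and 10
  blacklisted-mechanism drugs, giving a 123-drug catalog whose funnel
  counts (83 → 58 → 43 → 33) are known in advance.

What passing these tests shows: the set algebra, statistics, threshold
semantics, and plumbing of every stage are correct, deterministic, and
recover planted truth exactly. What they do not show: performance on
real literature (no linguistic ambiguity is emulated), real annotation
structure (no term overlap hierarchy), real interactome topology
(degree distributions are not matched), or real drug catalogs — the
separations here are planted to be clean, which real data never
guarantees.

## Determinism and degenerate inputs

All orderings are specified (alphabetical or explicitly documented), no
output file contains wall-clock content, and regeneration or re-running
under the same seed/config is byte-identical. Empty intermediate stages
are warnings, not errors — a strict enough cutoff legitimately empties a
screening cascade — and downstream stages then emit empty output. The
protein-expression verification of the original workflow is a manual
checkpoint recorded in provenance, not an executable stage.

## Problem sizes used in validation

The exhaustive hypergeometric oracle covers every valid (k, K, n, N)
with N ≤ 12 in tests (N ≤ 10 in the acceptance script, ~1,650 cases);
the betweenness oracle covers 200 random graphs of ≤ 7 nodes plus
closed-form path/star/complete cases; planted-truth recovery runs 20
independently seeded synthetic studies at the default design above.
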