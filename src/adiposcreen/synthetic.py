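"""Synthetic pipeline inputs with planted ground truth.

Generates all four input artifacts — literature corpus, two annotation
databases (biological process and pathway), weighted interaction edge
list, and drug catalog — together with a :class:`TruthManifest` that
records exactly what was planted. Every cascade stage can then be tested
against known truth without any external download:

* three query terms share a planted common core of genes, plus per-query
  extras, so the text-mining intersection recovers the core exactly;
* a few annotation terms are planted with overlaps large enough to clear
  the stage cutoff, among decoy terms that overlap the query in at most
  one gene and therefore cannot;
* the interaction network wires a small set of hub genes to every other
  (non-isolated) network gene at high confidence, leaves exactly one
  planted isolate without any high-confidence edge, and adds
  low-confidence decoy edges — so the confidence threshold cleanly
  separates planted topology and the hubs are the unique nodes clearing
  both centrality means;
* the drug catalog plants an eligible cohort (surviving all funnel
  stages, with a fixed mechanism-class composition) alongside off-target,
  wrong-status, undocumented, and blacklisted-mechanism cohorts that are
  removed at known stages.

Generation is deterministic under a fixed seed, and every planted claim
is re-checked at generation time with the pipeline's own modules; an
unsatisfiable design raises :class:`GenerationError` naming the violated
constraint.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io as asio
from .corpus import LiteratureCorpus, intersect_queries, query_genes
from .drugs import (DEFAULT_MECHANISM_BLACKLIST, DEFAULT_STATUS_WHITELIST,
                    DrugRecord, run_funnel)
from .enrichment import AnnotationDatabase, enrich, genes_of
from .genes import Gene, GeneSet
from .network import (InteractionTable, build_network, centrality,
                      isolated_nodes, remove_nodes, select_key_nodes)
from .prioritize import augment_with_anchor


class GenerationError(ValueError):
    """The generator design cannot be satisfied."""


@dataclass(frozen=True)
class PlantedTerm:
    """A term planted to be enriched: name, term size K, overlap size k."""

    name: str
    K: int
    k: int


@dataclass
class GeneratorConfig:
    """Design of the synthetic study, with planted signal at every stage.

    Defaults define the study conditions every planted-truth test runs
    under; they are sized so each stage's signal is unambiguous at the
    cascade's published cutoffs (enrichment 1.00e-07 / 1.00e-06,
    interaction confidence 0.900).
    """

    seed: int = 0
    genome_size: int = 2000
    query_terms: tuple[str, str, str] = (
        "brown-fat-like development", "brown fat", "brown adipose tissue")
    core_size: int = 30
    extra_per_query: int = 50
    decoy_documents: int = 40
    decoy_corpus_genes: int = 120

    bp_planted: tuple[PlantedTerm, ...] = (
        PlantedTerm("brown fat cell differentiation", K=40, k=15),
        PlantedTerm("response to cold", K=35, k=14),
        PlantedTerm("lipid metabolic process", K=60, k=16),
    )
    bp_decoy_count: int = 20
    pathway_planted: tuple[PlantedTerm, ...] = (
        PlantedTerm("PPAR signaling pathway", K=30, k=14),
        PlantedTerm("insulin signaling pathway", K=35, k=13),
    )
    pathway_decoy_count: int = 12
    decoy_term_size_range: tuple[int, int] = (20, 60)
    bp_cutoff: float = 1.00e-07
    pathway_cutoff: float = 1.00e-06
    anchor_term: str = "brown fat cell differentiation"

    hub_count: int = 3
    planted_score_range: tuple[int, int] = (900, 999)
    decoy_score_range: tuple[int, int] = (150, 850)
    decoy_edge_count: int = 60
    background_edge_count: int = 40
    min_confidence: float = 0.900
    allow_confidence_overlap: bool = False

    eligible_class_counts: dict[str, int] = field(default_factory=lambda: {
        "ppar-gamma agonist": 18,
        "beta-3 adrenoceptor agonist": 4,
        "insulin sensitizer": 1,
        "insulin": 3,
        "lipase clearing factor stimulant": 6,
        "other": 1,
    })
    off_target_count: int = 40
    bad_status_count: int = 25
    no_detail_count: int = 15
    blacklisted_count: int = 10

    def __post_init__(self) -> None:
        if len(self.query_terms) < 1:
            raise GenerationError("at least one query term is required")
        for t in self.query_terms:
            others = [o for o in self.query_terms if o != t]
            if any(t.lower() in o.lower() for o in others):
                raise GenerationError(
                    f"query term {t!r} is a substring of another query term; "
                    f"substring matching could not separate them")
        for planted in (*self.bp_planted, *self.pathway_planted):
            if planted.k > planted.K:
                raise GenerationError(
                    f"term {planted.name!r}: overlap k={planted.k} exceeds "
                    f"term size K={planted.K}")
        if any(p.k > self.core_size for p in self.bp_planted):
            raise GenerationError("a planted BP overlap exceeds the core size")
        if self.bp_planted and \
                self.anchor_term not in {p.name for p in self.bp_planted}:
            raise GenerationError(
                f"anchor term {self.anchor_term!r} is not a planted BP term")
        if self.pathway_planted and not self.bp_planted:
            raise GenerationError(
                "pathway terms cannot be planted without planted BP terms "
                "(the pathway stage queries the BP stage's genes)")
        needed = (self.core_size + len(self.query_terms) * self.extra_per_query
                  + self.decoy_corpus_genes)
        if needed > self.genome_size:
            raise GenerationError(
                f"genome_size {self.genome_size} too small for the corpus "
                f"design (needs {needed})")
        lo, hi = self.planted_score_range
        dlo, dhi = self.decoy_score_range
        if not (0 <= dlo <= dhi <= 999 and 0 <= lo <= hi <= 999):
            raise GenerationError("score ranges must lie in 0..999")
        if lo < int(round(self.min_confidence * 1000)):
            raise GenerationError(
                "planted scores must start at or above the confidence threshold")
        if dhi >= int(round(self.min_confidence * 1000)) \
                and not self.allow_confidence_overlap:
            raise GenerationError(
                "decoy score range crosses the confidence threshold; set "
                "allow_confidence_overlap=True if intended")
        if min(self.eligible_class_counts.values(), default=1) < 0:
            raise GenerationError("eligible class counts must be nonnegative")
        for cls in self.eligible_class_counts:
            if cls in DEFAULT_MECHANISM_BLACKLIST:
                raise GenerationError(
                    f"eligible class {cls!r} is on the mechanism blacklist")


@dataclass
class TruthManifest:
    """What was planted, stage by stage; the oracle for recovery tests."""

    seed: int
    core_genes: list[str]
    query_genes: dict[str, list[str]]
    bp_planted_terms: list[str]
    bp_overlaps: dict[str, list[str]]
    pathway_planted_terms: list[str]
    pathway_overlaps: dict[str, list[str]]
    stage1_genes: list[str]
    network_genes: list[str]
    hub_genes: list[str]
    isolate_gene: str | None
    anchor_term: str
    anchor_genes: list[str]
    final_genes: list[str]
    eligible_drugs: list[str]
    funnel_stage_counts: dict[str, int]
    class_tally: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=False)


@dataclass
class SyntheticBundle:
    """In-memory dataset bundle plus its truth manifest."""

    corpus: LiteratureCorpus
    bp_db: AnnotationDatabase
    pathway_db: AnnotationDatabase
    interactions: InteractionTable
    edge_rows: list[tuple[str, str, int]]
    catalog: list[DrugRecord]
    manifest: TruthManifest


def _symbols(indices: Sequence[int]) -> list[str]:
    return [f"G{i:04d}" for i in indices]


def _gene(i: int) -> Gene:
    return Gene(gene_id=f"SYN{i:05d}", symbol=f"G{i:04d}")


def generate(config: GeneratorConfig | None = None,
             out_dir: str | Path | None = None) -> SyntheticBundle:
    """Generate the full synthetic bundle (optionally writing it to disk)."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    genome = np.arange(config.genome_size)

    # -- partition the genome: core, per-query extras, corpus decoys ---
    perm = rng.permutation(genome)
    pos = 0
    core_idx = sorted(perm[pos:pos + config.core_size]); pos += config.core_size
    extras_idx: list[list[int]] = []
    for _ in config.query_terms:
        extras_idx.append(sorted(perm[pos:pos + config.extra_per_query]))
        pos += config.extra_per_query
    decoy_idx = sorted(perm[pos:pos + config.decoy_corpus_genes])
    pos += config.decoy_corpus_genes

    core = [_gene(i) for i in core_idx]
    core_set = GeneSet(core, label="planted-core")

    # -- literature corpus --------------------------------------------
    documents: dict[str, str] = {}
    links: list[tuple[Gene, str]] = []
    for qi, term in enumerate(config.query_terms):
        members = [_gene(i) for i in core_idx + extras_idx[qi]]
        n_docs = max(1, len(members) // 8)
        doc_ids = [f"doc_q{qi}_{j:03d}" for j in range(n_docs)]
        for j, doc_id in enumerate(doc_ids):
            text = f"observational study {j:03d} of {term} in human adipose biology"
            if any(o.lower() in text.lower()
                   for o in config.query_terms if o != term):
                raise GenerationError(
                    f"document text for {term!r} collides with another query term")
            documents[doc_id] = text
        for j, gene in enumerate(members):
            links.append((gene, doc_ids[j % n_docs]))
    for j in range(config.decoy_documents):
        documents[f"doc_bg_{j:03d}"] = \
            f"profiling report {j:03d} of hepatic lipid droplets and muscle tissue"
    bg_doc_ids = [f"doc_bg_{j:03d}" for j in range(config.decoy_documents)]
    if bg_doc_ids:
        for j, i in enumerate(decoy_idx):
            links.append((_gene(i), bg_doc_ids[j % len(bg_doc_ids)]))
    corpus = LiteratureCorpus.from_records(documents, links)

    # -- annotation databases ------------------------------------------
    noncore = [i for i in genome if i not in set(core_idx)]

    def _build_db(namespace: str, planted: Sequence[PlantedTerm],
                  decoy_count: int, query_idx: list[int],
                  decoy_prefix: str) -> tuple[AnnotationDatabase,
                                              dict[str, list[int]]]:
        """Plant terms overlapping query_idx; decoys overlap in <= 1 gene."""
        query_pool = np.array(query_idx)
        nonquery = np.array([i for i in genome if i not in set(query_idx)])
        terms: dict[str, GeneSet] = {}
        overlaps: dict[str, list[int]] = {}
        for p in planted:
            if p.k > len(query_pool):
                raise GenerationError(
                    f"term {p.name!r} needs overlap {p.k} but the query pool "
                    f"has only {len(query_pool)} genes")
            inside = sorted(rng.choice(query_pool, size=p.k, replace=False))
            filler = sorted(rng.choice(nonquery, size=p.K - p.k, replace=False))
            terms[p.name] = GeneSet([_gene(i) for i in inside + filler],
                                    label=p.name)
            overlaps[p.name] = [int(i) for i in inside]
        lo, hi = config.decoy_term_size_range
        for d in range(decoy_count):
            size = int(rng.integers(lo, hi + 1))
            # 0 or 1 query gene, so the decoy can never clear the cutoff
            n_in = int(rng.integers(0, 2)) if len(query_pool) else 0
            inside = (sorted(rng.choice(query_pool, size=n_in, replace=False))
                      if n_in else [])
            filler = sorted(rng.choice(nonquery, size=size - n_in,
                                       replace=False))
            terms[f"{decoy_prefix} {d:03d}"] = GeneSet(
                [_gene(i) for i in inside + filler],
                label=f"{decoy_prefix} {d:03d}")
        return AnnotationDatabase(namespace=namespace, terms=terms), overlaps

    bp_db, bp_overlaps = _build_db("BP", config.bp_planted,
                                   config.bp_decoy_count, core_idx,
                                   "decoy process")

    # stage-1 truth: genes carried into the pathway stage
    stage1_idx = sorted({i for ov in bp_overlaps.values() for i in ov})
    pathway_db, pw_overlaps = _build_db("PATHWAY", config.pathway_planted,
                                        config.pathway_decoy_count, stage1_idx,
                                        "decoy pathway")

    # -- self-check: planted terms pass, decoys fail -------------------
    stage1 = enrich(core_set, bp_db, cutoff=config.bp_cutoff)
    if {r.term for r in stage1} != {p.name for p in config.bp_planted}:
        raise GenerationError(
            f"BP planting failed: enrichment at {config.bp_cutoff} returned "
            f"{sorted(r.term for r in stage1)}")
    stage1_genes = genes_of(stage1)
    stage2 = (enrich(stage1_genes, pathway_db, cutoff=config.pathway_cutoff)
              if len(stage1_genes) else [])
    if {r.term for r in stage2} != {p.name for p in config.pathway_planted}:
        raise GenerationError(
            f"pathway planting failed: enrichment at {config.pathway_cutoff} "
            f"returned {sorted(r.term for r in stage2)}")

    # -- interaction network -------------------------------------------
    net_idx = sorted({i for ov in pw_overlaps.values() for i in ov})
    if config.pathway_planted and len(net_idx) < config.hub_count + 3:
        raise GenerationError(
            f"network design needs at least hub_count + 3 = "
            f"{config.hub_count + 3} genes, got {len(net_idx)}")
    if net_idx:
        net_perm = rng.permutation(np.array(net_idx))
        isolate: int | None = int(net_perm[0])
        hubs = sorted(int(i) for i in net_perm[1:1 + config.hub_count])
        periph = sorted(int(i) for i in net_perm[1 + config.hub_count:])
    else:
        isolate, hubs, periph = None, [], []

    slo, shi = config.planted_score_range
    dlo, dhi = config.decoy_score_range
    edge_rows: list[tuple[str, str, int]] = []
    planted_pairs: set[tuple[int, int]] = set()

    def _pair(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    for hi_i, h in enumerate(hubs):
        for other in hubs[hi_i + 1:] + periph:
            planted_pairs.add(_pair(h, other))
            edge_rows.append((f"G{h:04d}", f"G{other:04d}",
                              int(rng.integers(slo, shi + 1))))
    # low-confidence decoys among network genes (isolate included)
    candidates = [(a, b) for ai, a in enumerate(net_idx)
                  for b in net_idx[ai + 1:] if _pair(a, b) not in planted_pairs]
    n_decoy = min(config.decoy_edge_count, len(candidates))
    if n_decoy:
        chosen = rng.choice(len(candidates), size=n_decoy, replace=False)
        for ci in sorted(int(c) for c in chosen):
            a, b = candidates[ci]
            edge_rows.append((f"G{a:04d}", f"G{b:04d}",
                              int(rng.integers(dlo, dhi + 1))))
    # background edges among genes outside the network
    bg_pool = np.array([i for i in noncore if i not in set(net_idx)])
    for _ in range(config.background_edge_count):
        a, b = rng.choice(bg_pool, size=2, replace=False)
        edge_rows.append((f"G{int(a):04d}", f"G{int(b):04d}",
                          int(rng.integers(100, 1000))))
    interactions = InteractionTable(edge_rows)

    # -- self-check: threshold separates topology; hubs are the keys ---
    if net_idx:
        net_genes = GeneSet([_gene(i) for i in net_idx], label="network-genes")
        net = build_network(net_genes, interactions, config.min_confidence)
        iso = isolated_nodes(net)
        if set(iso.symbols) != {f"G{isolate:04d}"}:
            raise GenerationError(
                f"isolate planting failed: found {sorted(iso.symbols)}, "
                f"expected {{G{isolate:04d}}}")
        trimmed = remove_nodes(net, iso)
        keys = select_key_nodes(centrality(trimmed))
        if set(keys.symbols) != set(_symbols(hubs)):
            raise GenerationError(
                f"hub planting failed: key nodes {sorted(keys.symbols)} != "
                f"planted hubs {_symbols(hubs)}")
        # resolve key symbols back to the dataset's Gene records so the
        # augmentation union dedups on the shared gene-id namespace
        keys = GeneSet([_gene(i) for i in hubs], label="key-nodes")
    else:
        keys = GeneSet(label="key-nodes")

    # -- drug catalog ---------------------------------------------------
    anchor_overlap = bp_overlaps.get(config.anchor_term, [])
    anchor_genes = GeneSet([_gene(i) for i in anchor_overlap],
                           label=config.anchor_term)
    if len(keys) and len(anchor_genes):
        final = augment_with_anchor(keys, anchor_genes)
    else:
        final = GeneSet(list(keys) + list(anchor_genes),
                        label="final-targets", keep_order=True)
    final_symbols = list(final.symbols)
    n_planted_drugs = (sum(config.eligible_class_counts.values())
                       + config.bad_status_count + config.no_detail_count
                       + config.blacklisted_count)
    if not final_symbols and n_planted_drugs:
        raise GenerationError(
            "cannot plant on-target drug cohorts: the final gene list is "
            "empty under this design")
    nonfinal_symbols = _symbols([i for i in genome
                                 if f"G{i:04d}" not in set(final_symbols)])
    whitelist = list(DEFAULT_STATUS_WHITELIST)
    badlist = ["discontinued", "withdrawn", "suspended",
               "no development reported"]
    blacklist = list(DEFAULT_MECHANISM_BLACKLIST)
    ok_classes = sorted(config.eligible_class_counts) or ["other"]

    catalog: list[DrugRecord] = []
    eligible_names: list[str] = []
    serial = 0

    def _targets(pool: list[str]) -> GeneSet:
        n_t = int(rng.integers(1, 3))
        picked = rng.choice(np.array(pool), size=min(n_t, len(pool)),
                            replace=False)
        return GeneSet.from_symbols([str(s) for s in picked])

    for cls in sorted(config.eligible_class_counts):
        for _ in range(config.eligible_class_counts[cls]):
            name = f"drug{serial:04d}"; serial += 1
            catalog.append(DrugRecord(
                name=name, targets=_targets(final_symbols),
                global_status=whitelist[int(rng.integers(len(whitelist)))],
                mechanism_class=cls, has_trial_detail=True))
            eligible_names.append(name)
    for _ in range(config.off_target_count):
        name = f"drug{serial:04d}"; serial += 1
        catalog.append(DrugRecord(
            name=name, targets=_targets(nonfinal_symbols),
            global_status=(whitelist + badlist)[
                int(rng.integers(len(whitelist) + len(badlist)))],
            mechanism_class=ok_classes[int(rng.integers(len(ok_classes)))],
            has_trial_detail=bool(rng.integers(2))))
    for _ in range(config.bad_status_count):
        name = f"drug{serial:04d}"; serial += 1
        catalog.append(DrugRecord(
            name=name, targets=_targets(final_symbols),
            global_status=badlist[int(rng.integers(len(badlist)))],
            mechanism_class=ok_classes[int(rng.integers(len(ok_classes)))],
            has_trial_detail=bool(rng.integers(2))))
    for _ in range(config.no_detail_count):
        name = f"drug{serial:04d}"; serial += 1
        catalog.append(DrugRecord(
            name=name, targets=_targets(final_symbols),
            global_status=whitelist[int(rng.integers(len(whitelist)))],
            mechanism_class=ok_classes[int(rng.integers(len(ok_classes)))],
            has_trial_detail=False))
    for _ in range(config.blacklisted_count):
        name = f"drug{serial:04d}"; serial += 1
        catalog.append(DrugRecord(
            name=name, targets=_targets(final_symbols),
            global_status=whitelist[int(rng.integers(len(whitelist)))],
            mechanism_class=blacklist[int(rng.integers(len(blacklist)))],
            has_trial_detail=True))

    n_eligible = sum(config.eligible_class_counts.values())
    expected_stages = {
        "matched": n_eligible + config.bad_status_count
                   + config.no_detail_count + config.blacklisted_count,
        "status": n_eligible + config.no_detail_count
                  + config.blacklisted_count,
        "detail": n_eligible + config.blacklisted_count,
        "mechanism": n_eligible,
    }
    survivors, report = run_funnel(catalog, final)
    if dict(report.stages) != expected_stages:
        raise GenerationError(
            f"drug planting failed: funnel {dict(report.stages)} != "
            f"{expected_stages}")
    if {d.name for d in survivors} != set(eligible_names):
        raise GenerationError("drug planting failed: survivor roster mismatch")

    manifest = TruthManifest(
        seed=config.seed,
        core_genes=_symbols(core_idx),
        query_genes={t: _symbols(core_idx + extras_idx[qi])
                     for qi, t in enumerate(config.query_terms)},
        bp_planted_terms=sorted(p.name for p in config.bp_planted),
        bp_overlaps={t: _symbols(ov) for t, ov in sorted(bp_overlaps.items())},
        pathway_planted_terms=sorted(p.name for p in config.pathway_planted),
        pathway_overlaps={t: _symbols(ov)
                          for t, ov in sorted(pw_overlaps.items())},
        stage1_genes=_symbols(stage1_idx),
        network_genes=_symbols(net_idx),
        hub_genes=_symbols(hubs),
        isolate_gene=f"G{isolate:04d}" if isolate is not None else None,
        anchor_term=config.anchor_term,
        anchor_genes=list(anchor_genes.symbols),
        final_genes=final_symbols,
        eligible_drugs=eligible_names,
        funnel_stage_counts=expected_stages,
        class_tally=dict(sorted(config.eligible_class_counts.items())),
    )
    bundle = SyntheticBundle(corpus=corpus, bp_db=bp_db,
                             pathway_db=pathway_db, interactions=interactions,
                             edge_rows=edge_rows, catalog=catalog,
                             manifest=manifest)
    # sanity: the end-to-end corpus stage recovers the core
    recovered = intersect_queries([query_genes(corpus, t)
                                   for t in config.query_terms])
    if recovered != core_set:
        raise GenerationError("corpus planting failed: query intersection "
                              "does not recover the planted core")
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle's five artifacts plus the manifest; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "documents": out / "documents.tsv",
        "links": out / "links.tsv",
        "bp_gmt": out / "biological_process.gmt",
        "pathway_gmt": out / "pathway.gmt",
        "interactions": out / "interactions.tsv",
        "drugs": out / "drug_catalog.tsv",
        "manifest": out / "manifest.json",
    }
    asio.write_corpus(bundle.corpus, paths["documents"], paths["links"])
    asio.write_gmt(bundle.bp_db, paths["bp_gmt"])
    asio.write_gmt(bundle.pathway_db, paths["pathway_gmt"])
    asio.write_interactions(bundle.edge_rows, paths["interactions"])
    asio.write_drug_catalog(bundle.catalog, paths["drugs"])
    paths["manifest"].write_text(bundle.manifest.to_json() + "\n",
                                 encoding="utf-8")
    return paths
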