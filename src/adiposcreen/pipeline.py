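"""End-to-end cascade: corpus mining -> enrichment (two stages) ->
interaction network & key nodes -> anchor augmentation -> drug funnel.

``run_pipeline`` consumes file inputs named in a :class:`PipelineConfig`
and writes every intermediate gene list, the centrality report, the
final gene and drug lists, a funnel report, and a provenance record.
Outputs are deterministic: identical inputs and config produce
byte-identical files.

An empty intermediate result is a warning, not an error — screening
cascades legitimately empty out under strict thresholds — and downstream
stages then emit empty output.

``run_from_gene_lists`` is the fixture entry point: it starts the
cascade at the augmentation stage from supplied key-node and anchor gene
sets, which is how the published 18-gene list is reproduced offline (the
upstream stages depended on live web services).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import io as asio
from .corpus import intersect_queries, query_genes
from .drugs import (DEFAULT_MECHANISM_BLACKLIST, DEFAULT_STATUS_WHITELIST,
                    DrugRecord, FunnelReport, run_funnel)
from .enrichment import EnrichmentResult, enrich, genes_of
from .genes import GeneSet
from .network import (CentralityReport, build_network, centrality,
                      centrality_report_frame, isolated_nodes, remove_nodes,
                      select_key_nodes)
from .prioritize import DEFAULT_ANCHOR_TERM, augment_with_anchor

logger = logging.getLogger("adiposcreen")

DEFAULT_QUERY_TERMS = ("brown-fat-like development", "brown fat",
                       "brown adipose tissue")


@dataclass
class PipelineConfig:
    """All cascade parameters, defaulting to the published settings."""

    documents_path: str = "documents.tsv"
    links_path: str = "links.tsv"
    bp_gmt_path: str = "biological_process.gmt"
    pathway_gmt_path: str = "pathway.gmt"
    interactions_path: str = "interactions.tsv"
    drug_catalog_path: str = "drug_catalog.tsv"
    query_terms: tuple[str, ...] = DEFAULT_QUERY_TERMS
    bp_cutoff: float = 1.00e-07
    pathway_cutoff: float = 1.00e-06
    correction_method: str = "BH"
    min_confidence: float = 0.900
    anchor_term: str = DEFAULT_ANCHOR_TERM
    status_whitelist: tuple[str, ...] = DEFAULT_STATUS_WHITELIST
    mechanism_blacklist: tuple[str, ...] = DEFAULT_MECHANISM_BLACKLIST
    universe_size: int | None = None
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name, cut in (("bp_cutoff", self.bp_cutoff),
                          ("pathway_cutoff", self.pathway_cutoff)):
            if not (0.0 < cut < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {cut!r}")
        if not (0.0 <= self.min_confidence <= 1.0):
            raise ValueError("min_confidence must lie in [0, 1]")
        if not self.query_terms:
            raise ValueError("at least one query term is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("query_terms", "status_whitelist", "mechanism_blacklist"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PipelineResult:
    """Every stage's output, plus the funnel report and provenance."""

    query_results: dict[str, GeneSet]
    intersection: GeneSet
    stage1: list[EnrichmentResult]
    stage1_genes: GeneSet
    stage2: list[EnrichmentResult]
    stage2_genes: GeneSet
    isolates: GeneSet
    centrality_report: CentralityReport | None
    key_genes: GeneSet
    anchor_genes: GeneSet
    final_genes: GeneSet
    drugs: list[DrugRecord]
    funnel: FunnelReport
    provenance: dict = field(default_factory=dict)


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _empty_funnel() -> FunnelReport:
    return FunnelReport(stages=[("matched", 0), ("status", 0),
                                ("detail", 0), ("mechanism", 0)],
                        class_tally={})


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full cascade from the configured input files."""
    corpus = asio.read_corpus(config.documents_path, config.links_path)
    bp_db = asio.read_gmt(config.bp_gmt_path, "BP",
                          universe_size=config.universe_size)
    pathway_db = asio.read_gmt(config.pathway_gmt_path, "PATHWAY",
                               universe_size=config.universe_size)
    interactions = asio.read_interactions(config.interactions_path)
    catalog = asio.read_drug_catalog(config.drug_catalog_path)

    # stage 1: literature queries and their intersection
    query_results = {t: query_genes(corpus, t) for t in config.query_terms}
    for t, gs in query_results.items():
        logger.info("query %r matched %d genes", t, len(gs))
    intersection = intersect_queries(list(query_results.values()))
    logger.info("query intersection: %d genes", len(intersection))
    if len(intersection) == 0:
        logger.warning("query intersection is empty; downstream stages "
                       "will emit empty output")

    # stage 2: two-step enrichment
    stage1 = enrich(intersection, bp_db, config.bp_cutoff,
                    config.correction_method) if len(intersection) else []
    stage1_genes = genes_of(stage1)
    logger.info("biological-process stage: %d terms, %d genes",
                len(stage1), len(stage1_genes))
    if not stage1:
        logger.warning("no biological-process term passed the cutoff")
    stage2 = enrich(stage1_genes, pathway_db, config.pathway_cutoff,
                    config.correction_method) if len(stage1_genes) else []
    stage2_genes = genes_of(stage2)
    logger.info("pathway stage: %d terms, %d genes",
                len(stage2), len(stage2_genes))
    if stage1 and not stage2:
        logger.warning("no pathway term passed the cutoff")

    # stage 3: interaction network and key nodes
    if len(stage2_genes):
        net = build_network(stage2_genes, interactions, config.min_confidence)
        isolates = isolated_nodes(net)
        if len(isolates):
            logger.info("isolated gene(s) removed: %s",
                        ", ".join(isolates.symbols))
        trimmed = remove_nodes(net, isolates)
        if trimmed.n_nodes:
            report = centrality(trimmed)
            key_symbols = set(select_key_nodes(report).symbols)
            # carry the dataset's own Gene records (ids included) forward
            key_genes = GeneSet((g for g in stage2_genes
                                 if g.symbol in key_symbols),
                                label="key-nodes")
        else:
            report, key_genes = None, GeneSet(label="key-nodes")
    else:
        isolates, report, key_genes = GeneSet(), None, GeneSet(label="key-nodes")
    logger.info("key nodes: %d", len(key_genes))

    # stage 4: anchor augmentation
    anchor_genes = GeneSet(label=config.anchor_term)
    for r in stage1:
        if r.term.strip().lower() == config.anchor_term.strip().lower():
            anchor_genes = GeneSet(r.genes.members, label=config.anchor_term)
            break
    else:
        if stage1:
            logger.warning("anchor term %r not among enriched terms; "
                           "final list is the key-node list",
                           config.anchor_term)
    if len(key_genes) and len(anchor_genes):
        final = augment_with_anchor(key_genes, anchor_genes)
    elif len(key_genes) or len(anchor_genes):
        final = GeneSet((key_genes if len(key_genes) else anchor_genes).members,
                        label="final-targets", keep_order=True)
    else:
        final = GeneSet(label="final-targets")
    logger.info("final target list: %d genes", len(final))

    # stage 5: drug funnel
    if len(final):
        drugs, funnel = run_funnel(catalog, final, config.status_whitelist,
                                   config.mechanism_blacklist)
    else:
        drugs, funnel = [], _empty_funnel()
    logger.info("drug funnel: %s", dict(funnel.stages))

    provenance = {
        "parameters": {
            "query_terms": list(config.query_terms),
            "bp_cutoff": config.bp_cutoff,
            "pathway_cutoff": config.pathway_cutoff,
            "correction_method": config.correction_method,
            "min_confidence": config.min_confidence,
            "anchor_term": config.anchor_term,
            "status_whitelist": list(config.status_whitelist),
            "mechanism_blacklist": list(config.mechanism_blacklist),
            "universe_size": config.universe_size,
            "seed": config.seed,
        },
        "input_digests": {
            "documents": _digest(config.documents_path),
            "links": _digest(config.links_path),
            "bp_gmt": _digest(config.bp_gmt_path),
            "pathway_gmt": _digest(config.pathway_gmt_path),
            "interactions": _digest(config.interactions_path),
            "drug_catalog": _digest(config.drug_catalog_path),
        },
        "stage_counts": {
            **{f"query:{t}": len(gs) for t, gs in query_results.items()},
            "intersection": len(intersection),
            "bp_terms": len(stage1),
            "bp_genes": len(stage1_genes),
            "pathway_terms": len(stage2),
            "pathway_genes": len(stage2_genes),
            "isolates": len(isolates),
            "key_nodes": len(key_genes),
            "final_genes": len(final),
            **{f"drugs:{name}": count for name, count in funnel.stages},
        },
        "manual_checkpoints": [
            "protein-expression verification of key targets (tissue "
            "immunohistochemistry) is a manual step outside this pipeline",
        ],
    }
    result = PipelineResult(
        query_results=query_results, intersection=intersection,
        stage1=stage1, stage1_genes=stage1_genes,
        stage2=stage2, stage2_genes=stage2_genes,
        isolates=isolates, centrality_report=report, key_genes=key_genes,
        anchor_genes=anchor_genes, final_genes=final, drugs=drugs,
        funnel=funnel, provenance=provenance,
    )
    if config.out_dir is not None:
        write_outputs(result, config.out_dir)
    return result


def run_from_gene_lists(key_genes: GeneSet, anchor: GeneSet,
                        catalog: Sequence[DrugRecord] = (),
                        status_whitelist: Sequence[str] = DEFAULT_STATUS_WHITELIST,
                        mechanism_blacklist: Sequence[str] = DEFAULT_MECHANISM_BLACKLIST,
                        ) -> tuple[GeneSet, list[DrugRecord], FunnelReport]:
    """Fixture entry point: start at the augmentation stage.

    Returns the final gene list plus the drug-funnel output against the
    given catalog (empty catalog -> empty funnel).
    """
    final = augment_with_anchor(key_genes, anchor)
    if catalog:
        drugs, funnel = run_funnel(list(catalog), final, status_whitelist,
                                   mechanism_blacklist)
    else:
        drugs, funnel = [], _empty_funnel()
    return final, drugs, funnel


def write_outputs(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write every stage output; deterministic, no wall-clock content."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _p(name: str) -> Path:
        paths[name] = out / name
        return paths[name]

    asio.write_gene_list(result.intersection, _p("intersection_genes.tsv"))
    asio.write_enrichment_results(result.stage1, _p("bp_enrichment.tsv"))
    asio.write_gene_list(result.stage1_genes, _p("bp_genes.tsv"))
    asio.write_enrichment_results(result.stage2, _p("pathway_enrichment.tsv"))
    asio.write_gene_list(result.stage2_genes, _p("pathway_genes.tsv"))
    asio.write_gene_list(result.isolates, _p("isolated_genes.tsv"))
    if result.centrality_report is not None:
        centrality_report_frame(result.centrality_report, result.key_genes
                                ).to_csv(_p("centrality_report.tsv"),
                                         sep="\t", index=False)
    asio.write_gene_list(result.key_genes, _p("key_genes.tsv"))
    asio.write_gene_list(result.final_genes, _p("final_genes.tsv"))
    rows = [{"name": d.name, "targets": ";".join(d.targets.symbols),
             "global_status": d.global_status,
             "mechanism_class": d.mechanism_class} for d in result.drugs]
    pd.DataFrame(rows, columns=["name", "targets", "global_status",
                                "mechanism_class"]
                 ).to_csv(_p("final_drugs.tsv"), sep="\t", index=False)
    _p("funnel.json").write_text(result.funnel.to_json() + "\n",
                                 encoding="utf-8")
    _p("provenance.json").write_text(
        json.dumps(result.provenance, indent=2) + "\n", encoding="utf-8")
    return paths
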