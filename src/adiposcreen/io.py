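"""Readers and writers for the pipeline's plain-text formats.

* literature corpus: two TSVs — documents (doc_id, text) and links
  (gene_id, symbol, doc_id), UTF-8, header row required;
* annotation databases: GMT (term <TAB> description <TAB> gene symbols...);
* interaction edges: STRING-dialect TSV (protein1, protein2,
  combined_score), score either 0–999 integer or 0–1 decimal;
* drug catalog: TSV (name, targets semicolon-joined, global_status,
  mechanism_class, has_trial_detail).

Malformed files raise :class:`FormatError` naming the file, line and the
violated column contract.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .corpus import LiteratureCorpus
from .drugs import DEFAULT_STATUS_VOCABULARY, DrugRecord, validate_catalog
from .enrichment import AnnotationDatabase, EnrichmentResult
from .genes import Gene, GeneSet
from .network import InteractionTable


class FormatError(ValueError):
    """An input file violates its column contract."""


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise FormatError(f"{path}: cannot parse as TSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}; "
                          f"found {list(df.columns)}")
    return df


# -- literature corpus ------------------------------------------------

def read_corpus(documents_path: str | Path, links_path: str | Path
                ) -> LiteratureCorpus:
    docs_df = _read_tsv(documents_path, ["doc_id", "text"])
    links_df = _read_tsv(links_path, ["gene_id", "symbol", "doc_id"])
    documents = {}
    for i, row in docs_df.iterrows():
        if not row["doc_id"].strip():
            raise FormatError(f"{documents_path}: line {i + 2}: empty doc_id")
        documents[row["doc_id"]] = row["text"]
    links = []
    for i, row in links_df.iterrows():
        try:
            gene = Gene(gene_id=row["gene_id"], symbol=row["symbol"])
        except ValueError as exc:
            raise FormatError(f"{links_path}: line {i + 2}: {exc}") from exc
        if row["doc_id"] not in documents:
            raise FormatError(f"{links_path}: line {i + 2}: doc_id "
                              f"{row['doc_id']!r} not in documents file")
        links.append((gene, row["doc_id"]))
    return LiteratureCorpus.from_records(documents, links)


def write_corpus(corpus: LiteratureCorpus, documents_path: str | Path,
                 links_path: str | Path) -> None:
    docs = pd.DataFrame(sorted(corpus.documents.items()),
                        columns=["doc_id", "text"])
    docs.to_csv(documents_path, sep="\t", index=False)
    link_rows = sorted((g.gene_id, g.symbol, d) for g, d in corpus.links)
    links = pd.DataFrame(link_rows, columns=["gene_id", "symbol", "doc_id"])
    links.to_csv(links_path, sep="\t", index=False)


# -- GMT annotation databases ----------------------------------------

def read_gmt(path: str | Path, namespace: str,
             universe_size: int | None = None) -> AnnotationDatabase:
    path = Path(path)
    terms: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: GMT rows need "
                                  f"term, description and at least one gene")
            term, _desc, *symbols = parts
            symbols = [s for s in symbols if s.strip()]
            if not symbols:
                raise FormatError(f"{path}: line {lineno}: term {term!r} "
                                  f"lists no genes")
            if term in terms:
                raise FormatError(f"{path}: line {lineno}: duplicate term "
                                  f"{term!r}")
            terms[term] = GeneSet.from_symbols(symbols, label=term)
    return AnnotationDatabase(namespace=namespace, terms=terms,
                              universe_size=universe_size)


def write_gmt(db: AnnotationDatabase, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(db.terms):
            symbols = "\t".join(db.terms[term].symbols)
            fh.write(f"{term}\t{db.namespace}\t{symbols}\n")


# -- interaction edge list -------------------------------------------

def read_interactions(path: str | Path) -> InteractionTable:
    df = _read_tsv(path, ["protein1", "protein2", "combined_score"])
    rows = []
    for i, row in df.iterrows():
        try:
            score = float(row["combined_score"])
        except ValueError as exc:
            raise FormatError(f"{path}: line {i + 2}: combined_score "
                              f"{row['combined_score']!r} is not numeric") from exc
        if not row["protein1"].strip() or not row["protein2"].strip():
            raise FormatError(f"{path}: line {i + 2}: empty protein symbol")
        rows.append((row["protein1"], row["protein2"], score))
    try:
        return InteractionTable(rows)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_interactions(rows: Iterable[tuple[str, str, int]],
                       path: str | Path) -> None:
    """Write raw edge rows with 0-999 integer combined_score."""
    df = pd.DataFrame(list(rows), columns=["protein1", "protein2",
                                           "combined_score"])
    df.to_csv(path, sep="\t", index=False)


# -- drug catalog -----------------------------------------------------

_BOOL_TOKENS = {"true": True, "false": False, "1": True, "0": False,
                "yes": True, "no": False}


def read_drug_catalog(path: str | Path,
                      vocabulary: Sequence[str] = DEFAULT_STATUS_VOCABULARY
                      ) -> list[DrugRecord]:
    df = _read_tsv(path, ["name", "targets", "global_status",
                          "mechanism_class", "has_trial_detail"])
    catalog = []
    for i, row in df.iterrows():
        detail_token = row["has_trial_detail"].strip().lower()
        if detail_token not in _BOOL_TOKENS:
            raise FormatError(f"{path}: line {i + 2}: has_trial_detail must "
                              f"be true/false, got {row['has_trial_detail']!r}")
        symbols = [s for s in row["targets"].split(";") if s.strip()]
        if not symbols:
            raise FormatError(f"{path}: line {i + 2}: drug {row['name']!r} "
                              f"lists no targets")
        try:
            rec = DrugRecord(
                name=row["name"],
                targets=GeneSet.from_symbols(symbols, label=row["name"]),
                global_status=row["global_status"],
                mechanism_class=row["mechanism_class"],
                has_trial_detail=_BOOL_TOKENS[detail_token],
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {i + 2}: {exc}") from exc
        catalog.append(rec)
    try:
        validate_catalog(catalog, vocabulary)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return catalog


def write_drug_catalog(catalog: Sequence[DrugRecord], path: str | Path) -> None:
    rows = [{
        "name": d.name,
        "targets": ";".join(d.targets.symbols),
        "global_status": d.global_status,
        "mechanism_class": d.mechanism_class,
        "has_trial_detail": "true" if d.has_trial_detail else "false",
    } for d in catalog]
    pd.DataFrame(rows, columns=["name", "targets", "global_status",
                                "mechanism_class", "has_trial_detail"]
                 ).to_csv(path, sep="\t", index=False)


# -- result tables ----------------------------------------------------

def write_gene_list(genes: GeneSet, path: str | Path) -> None:
    pd.DataFrame({"gene_id": genes.gene_ids, "symbol": genes.symbols}
                 ).to_csv(path, sep="\t", index=False)


def write_enrichment_results(results: Sequence[EnrichmentResult],
                             path: str | Path) -> None:
    """Enrichment table mirroring the published columns."""
    rows = [{
        "term": r.term, "k": r.k, "K": r.K,
        "p_raw": f"{r.p_raw:.6e}", "p_corrected": f"{r.p_corrected:.6e}",
        "genes": ";".join(r.genes.symbols),
    } for r in results]
    pd.DataFrame(rows, columns=["term", "k", "K", "p_raw", "p_corrected",
                                "genes"]).to_csv(path, sep="\t", index=False)
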