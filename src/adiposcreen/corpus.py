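"""Literature-corpus mining: per-query gene lists and their intersection.

Emulates the first stage of the cascade, where each query phrase
("brown fat", "brown adipose tissue", "brown-fat-like development")
retrieves the genes linked to documents mentioning it, and the
intersection of the per-query lists seeds the downstream analysis.

Matching is a case-insensitive exact-substring test over each document's
keyword text — deliberately the simplest auditable rule; no stemming or
tokenization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce
from typing import Mapping, Sequence

from .genes import Gene, GeneSet


@dataclass
class LiteratureCorpus:
    """Documents (id -> keyword text) plus gene–document links.

    Every link must reference an existing document; the link set holds no
    duplicates. Genes are carried on the link side so a gene appears with
    a stable id and symbol.
    """

    documents: dict[str, str]
    links: frozenset[tuple[Gene, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        links = frozenset(self.links)
        for gene, doc_id in links:
            if doc_id not in self.documents:
                raise ValueError(
                    f"link ({gene.gene_id}, {doc_id}) references unknown document"
                )
        self.links = links

    @classmethod
    def from_records(cls, documents: Mapping[str, str],
                     links: Sequence[tuple[Gene, str]]) -> "LiteratureCorpus":
        return cls(documents=dict(documents), links=frozenset(links))

    def __len__(self) -> int:
        return len(self.documents)


def query_genes(corpus: LiteratureCorpus, term: str) -> GeneSet:
    """Genes linked to at least one document whose text contains ``term``.

    The match is a case-insensitive exact substring test. An empty corpus
    yields an empty result; an empty (or all-whitespace) term is an error.
    """
    if not term or not term.strip():
        raise ValueError("query term must be nonempty")
    needle = term.strip().lower()
    matching_docs = {doc_id for doc_id, text in corpus.documents.items()
                     if needle in text.lower()}
    hits = [gene for gene, doc_id in corpus.links if doc_id in matching_docs]
    return GeneSet(hits, label=term.strip())


def intersect_queries(sets: Sequence[GeneSet]) -> GeneSet:
    """Genes present in every input set (by gene_id).

    The label concatenates the input labels; at least one set is required.
    """
    if not sets:
        raise ValueError("intersect_queries requires at least one gene set")
    label = " & ".join(s.label for s in sets if s.label)
    if len(sets) == 1:
        return GeneSet(sets[0].members, label=label or sets[0].label)
    out = reduce(lambda a, b: a.intersection(b), sets)
    return GeneSet(out.members, label=label)
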