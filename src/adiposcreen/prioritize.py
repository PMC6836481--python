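"""Final target-list assembly: key nodes plus the anchor gene set.

The anchor is the gene membership of a designated enriched
biological-process term — by default "brown fat cell differentiation",
the process most directly tied to white-fat browning. Its genes are
merged into the key-node list; duplicates are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genes import GeneSet

DEFAULT_ANCHOR_TERM = "brown fat cell differentiation"


@dataclass
class AnchorSpec:
    """Which enriched term supplies the anchor genes."""

    term: str = DEFAULT_ANCHOR_TERM
    genes: GeneSet = field(default_factory=GeneSet)


def augment_with_anchor(key_genes: GeneSet, anchor: GeneSet) -> GeneSet:
    """Deduplicated union of key nodes and anchor genes.

    Order is deterministic: key genes first, in their own order, then the
    anchor genes not already present, alphabetically by symbol.
    """
    if len(key_genes) == 0 or len(anchor) == 0:
        raise ValueError("both key_genes and anchor must be nonempty")
    novel = sorted((g for g in anchor if g not in key_genes),
                   key=lambda g: (g.symbol, g.gene_id))
    return GeneSet(list(key_genes) + novel,
                   label="final-targets", keep_order=True)


def final_gene_table(key_genes: GeneSet, anchor: GeneSet,
                     final: GeneSet) -> pd.DataFrame:
    """Per-gene provenance table: source in {key_node, anchor, both}."""
    rows = []
    for g in final:
        in_key = g in key_genes
        in_anchor = g in anchor
        source = "both" if (in_key and in_anchor) else (
            "key_node" if in_key else "anchor")
        rows.append({"gene": g.symbol, "source": source})
    return pd.DataFrame(rows, columns=["gene", "source"])
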