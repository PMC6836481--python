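"""Packaged reference gene lists from the published screen.

These are the printed results of the original white-fat-browning screen:
the 16 enriched biological-process term rows, the 6 enriched pathway
rows, the 9 key genes from the interaction-network analysis, and the
18-gene final target list. They let the downstream half of the cascade
(anchor augmentation, drug funnel) run on the published inputs even
though the upstream web-service stages cannot be replayed offline.

Symbols are preserved exactly as printed, typos included — notably
"LPN1" in the triglyceride-biosynthesis row, where "LPIN1" was almost
certainly meant. ``SYMBOL_NORMALIZATION`` maps such typos to their
intended symbols and is applied only when explicitly requested.

Known internal inconsistencies of the printed tables, kept verbatim:

* the "Brown fat cell differentiation" row prints a query count of 12
  but lists 13 symbols (the symbols are authoritative: together with the
  9 key genes they reproduce the printed 18-gene final list exactly);
* the "Positive regulation of transcription..." row prints 20 against
  19 listed symbols;
* the pathway rows are said to contain 28 unique genes but their printed
  union has 27 distinct symbols.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genes import GeneSet

#: Typos in the printed tables mapped to the intended symbols.
SYMBOL_NORMALIZATION = {"LPN1": "LPIN1"}


@dataclass(frozen=True)
class FixtureRow:
    """One printed enrichment-table row, kept verbatim.

    ``printed_count`` is the "Genes in query set" column and
    ``genome_count`` the "Total genes in genome" column as printed;
    ``printed_count`` may disagree with ``len(symbols)`` (see module
    docstring), which is why this is not an :class:`EnrichmentResult`.
    """

    term: str
    printed_count: int
    genome_count: int
    printed_p: float
    symbols: tuple[str, ...]

    def gene_set(self, normalize: bool = False) -> GeneSet:
        symbols = self.symbols
        if normalize:
            symbols = tuple(SYMBOL_NORMALIZATION.get(s, s) for s in symbols)
        return GeneSet.from_symbols(symbols, label=self.term)


#: Enriched biological-process rows (16), verbatim.
BP_ROWS: tuple[FixtureRow, ...] = (
    FixtureRow("Brown fat cell differentiation", 12, 26, 8.3154e-21,
               ("PPARG", "PIK3R1", "MRAP", "PPARGC1A", "SLC2A4", "ADIG",
                "ADIPOQ", "ADRB1", "PRDM16", "ADRB3", "CEBPB", "FABP4", "UCP1")),
    FixtureRow("Response to cold", 10, 29, 7.84828e-16,
               ("PPARG", "ACOT11", "PMCH", "AGT", "ADRB1", "UCP3", "GMPR",
                "ADRB3", "TRH", "IL6")),
    FixtureRow("Positive regulation of transcription from RNA polymerase II promoter",
               20, 578, 2.90244e-12,
               ("NFKB1", "PPARG", "NFE2L2", "TWIST1", "SREBF1", "PPARA",
                "PIK3R1", "LPIN2", "ESR1", "CTNNB1", "HNF4A", "IL10", "RXRA",
                "EN1", "TGFB1", "ESRRA", "IL6", "CREBBP", "PPARGC1B")),
    FixtureRow("Lipid biosynthetic process", 8, 29, 7.45936e-12,
               ("SREBF1", "DGAT2L6", "MOGAT2", "DGAT2", "PRKAA2", "MOGAT3",
                "MOGAT1", "AWAT1")),
    FixtureRow("Cellular lipid metabolic process", 11, 128, 6.70379e-11,
               ("CYP7A1", "LPIN1", "PPARA", "DGAT2", "PRKAA2", "LPIN2", "AGT",
                "DGAT1", "RXRA", "CREBBP", "UCP1")),
    FixtureRow("Glucose homeostasis", 9, 64, 7.26406e-11,
               ("PPARG", "SLC2A4", "PMCH", "IRS1", "PRKAA2", "DBH", "HNF4A",
                "ADIPOQ", "INS")),
    FixtureRow("Response to drug", 14, 301, 1.68321e-10,
               ("PPARG", "FXN", "SREBF1", "PIK3R1", "CTNNB1", "HNF4A", "IL10",
                "LPL", "CYP19A1", "TGFB1", "NOS3", "IL6", "LIPE", "CFTR")),
    FixtureRow("Lipid metabolic process", 13, 241, 1.74841e-10,
               ("FADS2", "PPARG", "SREBF1", "PPARA", "LPIN2", "LEP", "LPL",
                "UCP3", "CIDEA", "APOC3", "LPIN3", "FABP4", "LIPE")),
    FixtureRow("Triglyceride biosynthetic process", 7, 33, 7.84617e-10,
               ("LPN1", "MOGAT2", "DGAT2", "LPIN2", "LPL", "DGAT1", "GPAT2")),
    FixtureRow("Response to hypoxia", 11, 175, 9.5641e-10,
               ("PPARA", "LEP", "NRF1", "MMP2", "UCP2", "UCP3", "TRH", "TGFB1",
                "ADIPOQ", "NOS3", "CREBBP")),
    FixtureRow("Positive regulation of MAPK cascade", 8, 61, 1.16264e-09,
               ("LEP", "CTNNB1", "AGT", "IGF1R", "CNTF", "ADRB3", "IL6", "INS")),
    FixtureRow("Response to insulin stimulus", 8, 62, 1.2526e-09,
               ("MC4R", "RETN", "PPARA", "IRS1", "LEP", "IL10", "UCP3", "IL6")),
    FixtureRow("Aging", 9, 114, 5.88491e-09,
               ("SREBF1", "AGT", "ADRB1", "UCP3", "ADRB3", "RXRA", "TGFB1",
                "NOS3", "IL6")),
    FixtureRow("Response to estradiol stimulus", 8, 89, 1.57804e-09,
               ("PIK3R1", "ESR1", "DBH", "NRF1", "CTNNB1", "CYP19A1", "TGFB1",
                "NOS3")),
    FixtureRow("Cellular lipid metabolic process", 7, 56, 1.62076e-08,
               ("PPARG", "LPIN1", "SLC2A4", "IRS1", "UCP2", "RXRA", "ADIPOQ")),
    FixtureRow("Response to organic cyclic compound", 8, 112, 8.05856e-08,
               ("FXN", "STC1", "DBH", "CYP19A1", "RXRA", "TRH", "NOS3", "IL6")),
)

#: Enriched pathway rows (6), verbatim.
PATHWAY_ROWS: tuple[FixtureRow, ...] = (
    FixtureRow("PPAR signaling pathway", 10, 70, 1.27872e-14,
               ("CYP7A1", "FADS2", "FABP4", "PPARA", "ADIPOQ", "UCP1", "LPL",
                "RXRA", "PPARG", "APOC3")),
    FixtureRow("Adipocytokine signaling pathway", 9, 67, 3.87352e-13,
               ("IRS1", "SLC2A4", "PPARA", "ADIPOQ", "NFKB1", "LEP", "PRKAA2",
                "RXRA", "PPARGC1A")),
    FixtureRow("Pathways in cancer", 11, 324, 1.10046e-09,
               ("IL6", "MMP2", "IGF1R", "FGF19", "NFKB1", "PIK3R1", "TGFB1",
                "CTNNB1", "CREBBP", "RXRA", "PPARG")),
    FixtureRow("Insulin signaling pathway", 8, 133, 4.39226e-09,
               ("IRS1", "LIPE", "SLC2A4", "SREBF1", "PIK3R1", "PRKAA2", "INS",
                "PPARGC1A")),
    FixtureRow("Prostate cancer", 6, 88, 1.89023e-07,
               ("IGF1R", "NFKB1", "PIK3R1", "INS", "CTNNB1", "CREBBP")),
    FixtureRow("Type II diabetes mellitus", 5, 46, 2.15133e-07,
               ("IRS1", "SLC2A4", "ADIPOQ", "PIK3R1", "INS")),
)

#: The 9 key genes from the network centrality analysis.
KEY_GENE_SYMBOLS: tuple[str, ...] = (
    "PPARG", "CREBBP", "LEP", "INS", "ADIPOQ", "LPL", "FABP4", "IL6", "PIK3R1",
)

#: Gene found isolated in the high-confidence interaction network.
ISOLATED_GENE_SYMBOL = "FADS2"

#: The anchor term whose member genes augment the key nodes.
ANCHOR_TERM = "Brown fat cell differentiation"

#: The published 18-gene final target list.
FINAL_GENE_SYMBOLS: tuple[str, ...] = (
    "PPARG", "CREBBP", "LEP", "INS", "ADIPOQ", "LPL", "FABP4", "IL6", "PIK3R1",
    "MRAP", "PPARGC1A", "SLC2A4", "ADIG", "ADRB1", "PRDM16", "ADRB3", "CEBPB",
    "UCP1",
)


@dataclass
class FixtureBundle:
    """All packaged reference lists in ready-to-use form."""

    bp_rows: tuple[FixtureRow, ...]
    pathway_rows: tuple[FixtureRow, ...]
    key_genes: GeneSet
    anchor: GeneSet
    final_genes: GeneSet

    @property
    def anchor_term(self) -> str:
        return ANCHOR_TERM


def load_published_fixtures() -> FixtureBundle:
    """The packaged printed gene lists as a single bundle."""
    anchor_row = next(r for r in BP_ROWS if r.term == ANCHOR_TERM)
    return FixtureBundle(
        bp_rows=BP_ROWS,
        pathway_rows=PATHWAY_ROWS,
        key_genes=GeneSet.from_symbols(KEY_GENE_SYMBOLS, label="key-nodes"),
        anchor=anchor_row.gene_set(),
        final_genes=GeneSet.from_symbols(FINAL_GENE_SYMBOLS,
                                         label="final-targets"),
    )
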