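"""High-confidence interaction network and key-node selection.

The candidate genes are joined on a weighted protein–protein interaction
edge list (STRING dialect); only edges at or above a confidence threshold
(0.900 by default in the pipeline) are kept. Isolated genes are reported
and removed, per-node degree and Freeman betweenness are computed, and
the key nodes are those whose degree AND betweenness both reach their
network-wide arithmetic means.

Betweenness follows the Freeman convention: undirected, unnormalized,
endpoints excluded, fractional attribution over shortest-path
multiplicity, each unordered pair counted once. Pairs in different
components contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .genes import GeneSet


@dataclass
class InteractionTable:
    """Symbol-keyed weighted edges with confidence scores in [0, 1].

    Self-pairs are dropped on ingest; unordered duplicate pairs collapse
    to the maximum confidence. Scores given on STRING's 0–999 integer
    scale are divided by 1000.
    """

    rows: tuple[tuple[str, str, float], ...] = ()

    def __init__(self, rows: Iterable[tuple[str, str, float]] = ()) -> None:
        best: dict[tuple[str, str], float] = {}
        for a, b, conf in rows:
            a = str(a).strip().upper()
            b = str(b).strip().upper()
            conf = float(conf)
            if conf > 1.0:  # STRING integer dialect (0-999)
                conf = conf / 1000.0
            if not (0.0 <= conf <= 1.0):
                raise ValueError(f"confidence {conf!r} outside [0, 1] for ({a}, {b})")
            if a == b:
                continue
            pair = (a, b) if a < b else (b, a)
            best[pair] = max(best.get(pair, 0.0), conf)
        self.rows = tuple((a, b, c) for (a, b), c in sorted(best.items()))

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class Network:
    """Simple undirected graph over a gene set (no loops, no multi-edges)."""

    genes: GeneSet
    graph: nx.Graph = field(repr=False)

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.graph.nodes))

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted(tuple(sorted(e)) for e in self.graph.edges))

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class CentralityReport:
    """Per-node degree and betweenness with their arithmetic means."""

    degree: dict[str, int]
    betweenness: dict[str, float]
    mean_degree: float
    mean_betweenness: float

    def to_frame(self, key_nodes: GeneSet | None = None) -> pd.DataFrame:
        nodes = sorted(self.degree)
        df = pd.DataFrame({
            "gene": nodes,
            "degree": [self.degree[v] for v in nodes],
            "betweenness": [self.betweenness[v] for v in nodes],
        })
        if key_nodes is not None:
            df["is_key"] = [v in key_nodes for v in nodes]
        return df


def build_network(genes: GeneSet, interactions: InteractionTable,
                  min_confidence: float) -> Network:
    """Induce the network of ``genes`` at a confidence threshold.

    Nodes are the input genes (by symbol); edges are interaction rows with
    both endpoints among the genes and confidence >= ``min_confidence``
    (inclusive boundary).
    """
    if len(genes) == 0:
        raise ValueError("cannot build a network over an empty gene set")
    if not (0.0 <= min_confidence <= 1.0):
        raise ValueError(f"min_confidence must lie in [0, 1], got {min_confidence!r}")
    g = nx.Graph()
    symbols = set(genes.symbols)
    g.add_nodes_from(sorted(symbols))
    thr = round(min_confidence, 10)
    for a, b, conf in interactions.rows:
        if a in symbols and b in symbols and round(conf, 10) >= thr:
            g.add_edge(a, b, confidence=conf)
    return Network(genes=genes, graph=g)


def isolated_nodes(net: Network) -> GeneSet:
    """Genes with no incident edge (degree zero)."""
    return GeneSet.from_symbols(
        [v for v in net.graph.nodes if net.graph.degree(v) == 0],
        label="isolated")


def remove_nodes(net: Network, drop: GeneSet) -> Network:
    """Induced subgraph on the nodes not in ``drop``."""
    drop_symbols = set(drop.symbols)
    keep = [v for v in net.graph.nodes if v not in drop_symbols]
    sub = net.graph.subgraph(keep).copy()
    kept_genes = GeneSet((g for g in net.genes if g.symbol not in drop_symbols),
                         label=net.genes.label)
    return Network(genes=kept_genes, graph=sub)


def centrality(net: Network, double_count_pairs: bool = False) -> CentralityReport:
    """Degree and Freeman betweenness for every node, with their means.

    ``double_count_pairs`` counts each unordered pair twice (an (s,t) /
    (t,s) convention some tools use); the default counts it once.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot compute centrality of an empty network")
    degree = {v: int(d) for v, d in net.graph.degree()}
    btw = nx.betweenness_centrality(net.graph, normalized=False)
    if double_count_pairs:
        btw = {v: 2.0 * b for v, b in btw.items()}
    n = net.n_nodes
    return CentralityReport(
        degree=degree,
        betweenness={v: float(b) for v, b in btw.items()},
        mean_degree=sum(degree.values()) / n,
        mean_betweenness=sum(btw.values()) / n,
    )


def select_key_nodes(report: CentralityReport) -> GeneSet:
    """Nodes whose degree and betweenness both reach their means.

    Comparisons are inclusive, with both sides rounded to 10 decimal
    places so float noise cannot turn an exact tie into a strict miss.
    """
    if not report.degree:
        raise ValueError("centrality report is empty")
    md = round(report.mean_degree, 10)
    mb = round(report.mean_betweenness, 10)
    keys = [v for v in report.degree
            if round(report.degree[v], 10) >= md
            and round(report.betweenness[v], 10) >= mb]
    return GeneSet.from_symbols(keys, label="key-nodes")


def centrality_report_frame(report: CentralityReport,
                            key_nodes: GeneSet) -> pd.DataFrame:
    """Tabular report (gene, degree, betweenness, is_key)."""
    return report.to_frame(key_nodes=key_nodes)
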