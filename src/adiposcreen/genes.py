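"""Gene identifiers and ordered, deduplicated gene sets.

A :class:`GeneSet` is the currency passed between every pipeline stage:
text-mining query results, enrichment-term memberships, network node sets,
the key-node list and the final target list are all gene sets. Membership
is keyed on ``gene_id``; symbols are normalized to uppercase on ingest so
that symbol comparison is case-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator


@dataclass(frozen=True)
class Gene:
    """A gene with an opaque stable identifier and an uppercase symbol.

    ``gene_id`` is the identity used for set algebra (two genes with the
    same symbol but different ids stay distinct); ``symbol`` is normalized
    to uppercase and stripped of surrounding whitespace.
    """

    gene_id: str
    symbol: str

    def __post_init__(self) -> None:
        sym = self.symbol.strip().upper()
        if not sym:
            raise ValueError("gene symbol must be nonempty")
        if not str(self.gene_id).strip():
            raise ValueError("gene_id must be nonempty")
        object.__setattr__(self, "symbol", sym)


def _sort_key(gene: Gene) -> tuple[str, str]:
    return (gene.symbol, str(gene.gene_id))


@dataclass
class GeneSet:
    """Ordered collection of :class:`Gene`, deduplicated by ``gene_id``.

    Default iteration order is alphabetical by symbol (ties broken by
    gene_id) for determinism. Pass ``keep_order=True`` to preserve the
    insertion order instead — used where a stage defines its own ordering,
    e.g. the final target list (key nodes first, then novel anchor genes).
    """

    members: tuple[Gene, ...] = ()
    label: str = ""
    _index: dict[str, Gene] = field(init=False, repr=False, compare=False)

    def __init__(self, genes: Iterable[Gene] = (), label: str = "",
                 keep_order: bool = False) -> None:
        seen: dict[str, Gene] = {}
        for g in genes:
            if not isinstance(g, Gene):
                raise TypeError(f"GeneSet members must be Gene, got {type(g)!r}")
            seen.setdefault(g.gene_id, g)
        ordered = list(seen.values())
        if not keep_order:
            ordered.sort(key=_sort_key)
        self.members = tuple(ordered)
        self.label = label
        self._index = {g.gene_id: g for g in self.members}

    @classmethod
    def from_symbols(cls, symbols: Iterable[str], label: str = "",
                     keep_order: bool = False) -> "GeneSet":
        """Build a set where each symbol doubles as its own gene_id.

        Convenient for symbol-only sources (printed tables, GMT files,
        interaction edge lists keyed on symbols).
        """
        genes = [Gene(gene_id=s.strip().upper(), symbol=s) for s in symbols]
        return cls(genes, label=label, keep_order=keep_order)

    # -- set algebra (by gene_id) -------------------------------------

    def intersection(self, other: "GeneSet", label: str = "") -> "GeneSet":
        return GeneSet((g for g in self.members if g.gene_id in other._index),
                       label=label)

    def union(self, other: "GeneSet", label: str = "") -> "GeneSet":
        return GeneSet(list(self.members) + list(other.members), label=label)

    def difference(self, other: "GeneSet", label: str = "") -> "GeneSet":
        return GeneSet((g for g in self.members if g.gene_id not in other._index),
                       label=label)

    def issubset(self, other: "GeneSet") -> bool:
        return all(gid in other._index for gid in self._index)

    # -- container protocol -------------------------------------------

    def __contains__(self, item: object) -> bool:
        if isinstance(item, Gene):
            return item.gene_id in self._index
        return str(item) in self._index

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSet):
            return NotImplemented
        return set(self._index) == set(other._index)

    def __repr__(self) -> str:
        label = f" label={self.label!r}" if self.label else ""
        return f"GeneSet(n={len(self)}{label})"

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(g.symbol for g in self.members)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in self.members)
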