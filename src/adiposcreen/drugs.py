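"""Drug-target screening funnel.

Candidate drugs are matched to the final target genes and filtered in
three independent passes: a development-status whitelist (launched,
clinical phases I–III, pre-registration, registered), a requirement that
the development process be documented in detail, and a mechanism-of-action
blacklist removing classes whose risk profile rules them out (beta-1
adrenoceptor agonists/antagonists, interleukin-6 antagonists,
CREB-binding protein inhibitors). The surviving drugs are tabulated by
mechanism class.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genes import GeneSet

#: Development statuses considered mature enough to pursue.
DEFAULT_STATUS_WHITELIST = (
    "launched",
    "phase i clinical trial",
    "phase ii clinical trial",
    "phase iii clinical trial",
    "pre-registration",
    "registered",
)

#: Statuses a catalog may also carry for drugs outside active late development.
DEFAULT_STATUS_VOCABULARY = DEFAULT_STATUS_WHITELIST + (
    "preclinical",
    "discontinued",
    "withdrawn",
    "suspended",
    "no development reported",
)

#: Mechanism classes excluded on efficacy/safety grounds.
DEFAULT_MECHANISM_BLACKLIST = (
    "beta-1 adrenoceptor antagonist",
    "beta-1 adrenoceptor agonist",
    "interleukin-6 antagonist",
    "creb-binding protein inhibitor",
)


def _norm(token: str) -> str:
    return str(token).strip().lower()


@dataclass(frozen=True)
class DrugRecord:
    """One drug: name, target genes, status, mechanism class, detail flag.

    Combination drugs are a single record whose targets list all component
    targets. ``has_trial_detail`` records whether the development process
    is documented in detail.
    """

    name: str
    targets: GeneSet
    global_status: str
    mechanism_class: str
    has_trial_detail: bool

    def __post_init__(self) -> None:
        if not self.name.strip():
            raise ValueError("drug name must be nonempty")
        if len(self.targets) == 0:
            raise ValueError(f"drug {self.name!r} has no targets")
        object.__setattr__(self, "global_status", _norm(self.global_status))
        object.__setattr__(self, "mechanism_class", _norm(self.mechanism_class))


def validate_catalog(catalog: Sequence[DrugRecord],
                     vocabulary: Iterable[str] = DEFAULT_STATUS_VOCABULARY) -> None:
    """Check name uniqueness and that statuses come from the vocabulary."""
    vocab = {_norm(v) for v in vocabulary}
    seen: set[str] = set()
    for rec in catalog:
        if rec.name in seen:
            raise ValueError(f"duplicate drug name {rec.name!r} in catalog")
        seen.add(rec.name)
        if rec.global_status not in vocab:
            raise ValueError(
                f"drug {rec.name!r} has status {rec.global_status!r} outside "
                f"the declared vocabulary")


def match_drugs(catalog: Sequence[DrugRecord], genes: GeneSet) -> list[DrugRecord]:
    """Drugs with at least one target among ``genes``; catalog order kept.

    Matching joins on gene symbols: drug catalogs identify targets by
    symbol, not by the gene ids of the upstream datasets.
    """
    symbols = set(genes.symbols)
    return [d for d in catalog if any(t.symbol in symbols for t in d.targets)]


def filter_status(drugs: Sequence[DrugRecord],
                  allowed: Iterable[str] = DEFAULT_STATUS_WHITELIST
                  ) -> list[DrugRecord]:
    """Keep drugs whose global status is in the whitelist (case-insensitive)."""
    allowed_set = {_norm(a) for a in allowed}
    if not allowed_set:
        raise ValueError("status whitelist must be nonempty")
    return [d for d in drugs if d.global_status in allowed_set]


def filter_detail(drugs: Sequence[DrugRecord]) -> list[DrugRecord]:
    """Keep drugs whose development process is documented in detail."""
    return [d for d in drugs if d.has_trial_detail]


def filter_mechanism(drugs: Sequence[DrugRecord],
                     blacklist: Iterable[str] = DEFAULT_MECHANISM_BLACKLIST
                     ) -> list[DrugRecord]:
    """Drop drugs whose mechanism class is blacklisted."""
    black = {_norm(b) for b in blacklist}
    return [d for d in drugs if d.mechanism_class not in black]


def tabulate_classes(drugs: Sequence[DrugRecord]) -> dict[str, int]:
    """Drug count per mechanism class (sums to the number of drugs)."""
    return dict(sorted(Counter(d.mechanism_class for d in drugs).items()))


@dataclass
class FunnelReport:
    """Stage-by-stage survivor counts plus the final class tally."""

    stages: list[tuple[str, int]]
    class_tally: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = [c for _, c in self.stages]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError(f"funnel counts must be non-increasing: {counts}")
        if self.stages and self.class_tally and \
                sum(self.class_tally.values()) != counts[-1]:
            raise ValueError("class tally does not sum to the final stage count")

    @property
    def final_count(self) -> int:
        return self.stages[-1][1] if self.stages else 0

    def to_json(self) -> str:
        return json.dumps({"stages": [list(s) for s in self.stages],
                           "class_tally": self.class_tally},
                          indent=2, sort_keys=False)


def run_funnel(catalog: Sequence[DrugRecord], genes: GeneSet,
               allowed_statuses: Iterable[str] = DEFAULT_STATUS_WHITELIST,
               mechanism_blacklist: Iterable[str] = DEFAULT_MECHANISM_BLACKLIST,
               ) -> tuple[list[DrugRecord], FunnelReport]:
    """Full funnel: match -> status -> detail -> mechanism, with report."""
    matched = match_drugs(catalog, genes)
    by_status = filter_status(matched, allowed_statuses)
    by_detail = filter_detail(by_status)
    final = filter_mechanism(by_detail, mechanism_blacklist)
    report = FunnelReport(
        stages=[("matched", len(matched)), ("status", len(by_status)),
                ("detail", len(by_detail)), ("mechanism", len(final))],
        class_tally=tabulate_classes(final),
    )
    return final, report
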