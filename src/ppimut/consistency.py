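"""Evidence grouping and consistency classification of repeated annotations.

The same sequence change is often tested against the same interaction
partners in several independent experiments. Grouping those annotations
— with proteoform-sensitive partner identity, so a phosphorylated partner
is distinct from its unmodified form — gives the unit at which agreement
between experiments can be judged:

* ``consistent``    all stated effects point in one direction (mixing
  e.g. disrupting with decreasing still counts as consistent), or all
  report no effect;
* ``mild_conflict`` one direction mixed with no-effect reports;
* ``conflict``      directly antagonistic directions (a negative- and a
  positive-direction effect) are both present;
* ``single``        only one piece of evidence exists;
* ``unclassifiable`` every effect is of the undefined category, so no
  direction can be compared.

Undefined-direction effects never vote; antagonism dominates any amount
of accompanying no-effect evidence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

from .core import MutationFeature, effect_direction

__all__ = [
    "EvidenceGroup",
    "ConsistencyCall",
    "ConsistencyReport",
    "group_evidence",
    "classify_group",
    "consistency_report",
]


@dataclass
class EvidenceGroup:
    """All features sharing one (protein, sequence change, partner set) key."""

    key: tuple
    members: list[MutationFeature] = field(default_factory=list)

    @property
    def n_evidences(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ConsistencyCall:
    """Classification of one evidence group."""

    category: str  # single | consistent | mild_conflict | conflict | unclassifiable
    directions_seen: frozenset[str] = frozenset()


def group_key(feature: MutationFeature) -> tuple:
    """Grouping key: protein, ordered segment tuple, partner multiset.

    Partners are compared as (accession, proteoform tag) pairs, so two
    proteoforms of the same protein are different partners.
    """
    partners = tuple(
        sorted((p.protein_ac, p.proteoform_tag) for p in feature.partners)
    )
    return feature.change_key() + (partners,)


def group_evidence(features: Iterable[MutationFeature]) -> list[EvidenceGroup]:
    """Partition features into evidence groups (input order preserved)."""
    groups: dict[tuple, EvidenceGroup] = {}
    order: list[tuple] = []
    for feature in features:
        key = group_key(feature)
        if key not in groups:
            groups[key] = EvidenceGroup(key)
            order.append(key)
        groups[key].members.append(feature)
    return [groups[k] for k in order]


def classify_group(group: EvidenceGroup) -> ConsistencyCall:
    """Classify one evidence group per the direction-vote rules.

    The call is invariant under permutation or duplication of members:
    only the *set* of directions present matters.
    """
    directions = [effect_direction(m.effect) for m in group.members]
    seen = frozenset(directions)
    if group.n_evidences == 1:
        return ConsistencyCall("single", seen)
    voting = seen - {"unknown"}
    if not voting:
        return ConsistencyCall("unclassifiable", seen)
    if "negative" in voting and "positive" in voting:
        return ConsistencyCall("conflict", seen)
    if voting == {"neutral"}:
        return ConsistencyCall("consistent", seen)
    if "neutral" in voting:
        return ConsistencyCall("mild_conflict", seen)
    return ConsistencyCall("consistent", seen)


def _pct(count: int, total: int) -> float:
    if total == 0:
        return 0.0
    return float(
        (Decimal(100 * count) / Decimal(total)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


@dataclass
class ConsistencyReport:
    """Counts and percentages over multiply-tested (n >= 2) groups.

    Groups whose evidence is entirely of undefined direction are excluded
    from the denominator. Percentages are half-up, one decimal.
    """

    n_groups: int
    n_single: int
    n_multi: int
    counts: dict[str, int]
    percentages: dict[str, float]
    n_non_consistent: int
    pct_non_consistent: float
    pct_conflict: float
    conflict_keys: list[tuple]

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "grouping_key": "(protein_ac, sorted segment tuple, partner "
            "multiset with proteoform tags)",
            "n_groups": self.n_groups,
            "n_single": self.n_single,
            "n_multi_tested": self.n_multi,
            "counts": dict(self.counts),
            "percentages": dict(self.percentages),
            "n_non_consistent": self.n_non_consistent,
            "pct_non_consistent": self.pct_non_consistent,
            "pct_conflict": self.pct_conflict,
            "conflict_group_keys": [list(map(str, k)) for k in self.conflict_keys],
        }


def consistency_report(features: Iterable[MutationFeature]) -> ConsistencyReport:
    """Group features and summarize agreement over multiply-tested groups."""
    groups = group_evidence(features)
    calls = [(g, classify_group(g)) for g in groups]
    n_single = sum(1 for _, c in calls if c.category == "single")
    multi = [(g, c) for g, c in calls if c.category not in ("single", "unclassifiable")]
    counter = Counter(c.category for _, c in multi)
    n_multi = len(multi)
    counts = {
        "consistent": counter.get("consistent", 0),
        "mild_conflict": counter.get("mild_conflict", 0),
        "conflict": counter.get("conflict", 0),
    }
    percentages = {k: _pct(v, n_multi) for k, v in counts.items()}
    n_non = counts["mild_conflict"] + counts["conflict"]
    return ConsistencyReport(
        n_groups=len(groups),
        n_single=n_single,
        n_multi=n_multi,
        counts=counts,
        percentages=percentages,
        n_non_consistent=n_non,
        pct_non_consistent=_pct(n_non, n_multi),
        pct_conflict=_pct(counts["conflict"], n_multi),
        conflict_keys=[g.key for g, c in multi if c.category == "conflict"],
    )
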