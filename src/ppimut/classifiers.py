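"""Rule-based effect classifiers.

Phosphosite-relative substitution classes, alanine-scan detection,
affinity fold-change calls, the simplified cross-resource effect
vocabulary (loss / gain / no_effect / unknown), and interface-region
membership. All rules are pure functions of their inputs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .core import AffinityMeasurement, EffectCategory, effect_direction
from .varmap import PointChange

__all__ = [
    "PHOSPHO_ACCEPTORS",
    "PHOSPHO_DISRUPTING_TARGETS",
    "PHOSPHO_MIMETIC_TARGETS",
    "InterfaceRegion",
    "classify_phospho",
    "is_alanine_substitution",
    "classify_affinity_fold_change",
    "simplify_effect",
    "interface_membership",
    "read_phosphosite_table",
    "read_interface_table",
]

#: phosphorylatable residues.
PHOSPHO_ACCEPTORS = frozenset("STY")
#: replacements that remove the phosphosite (cannot be phosphorylated).
PHOSPHO_DISRUPTING_TARGETS = frozenset("AGVF")
#: replacements that mimic the phosphorylated state (negative charge).
PHOSPHO_MIMETIC_TARGETS = frozenset("ED")


def classify_phospho(
    point: PointChange, phosphosites: set[tuple[str, int]]
) -> str:
    """Classify a point substitution relative to annotated phosphosites.

    Returns one of ``phospho_disrupting`` (S/T/Y at an annotated site
    replaced by A/G/V/F), ``phospho_mimetic`` (replaced by E/D),
    ``other_at_phosphosite`` (any other replacement of S/T/Y at a site) or
    ``not_applicable`` (original not phosphorylatable, or position not an
    annotated site). The classes are exhaustive and mutually exclusive.
    """
    if point.original not in PHOSPHO_ACCEPTORS:
        return "not_applicable"
    if (point.protein_ac, point.position) not in phosphosites:
        return "not_applicable"
    if point.resulting in PHOSPHO_DISRUPTING_TARGETS:
        return "phospho_disrupting"
    if point.resulting in PHOSPHO_MIMETIC_TARGETS:
        return "phospho_mimetic"
    return "other_at_phosphosite"


def is_alanine_substitution(point: PointChange) -> bool:
    """True iff the replacement residue is alanine (and the original is not)."""
    return point.resulting == "A" and point.original != "A"


def classify_affinity_fold_change(
    measurement: AffinityMeasurement,
    loss_threshold: float = 1.5,
    gain_threshold: float = 0.5,
) -> str:
    """Call loss / gain / no_effect from a KD fold change.

    The ratio r = KD(mutant) / KD(wild type) is oriented so that a larger
    dissociation constant means weaker binding: r > ``loss_threshold``
    (default 1.5x) is a loss of binding, r < ``gain_threshold`` (default
    0.5x) a gain, anything between is no effect. Both thresholds are
    configurable.
    """
    if not (loss_threshold > 0 and gain_threshold > 0):
        raise ValueError("thresholds must be positive")
    ratio = measurement.kd_mutant / measurement.kd_wild_type
    if ratio > loss_threshold:
        return "loss"
    if ratio < gain_threshold:
        return "gain"
    return "no_effect"


def simplify_effect(effect: EffectCategory) -> str:
    """Collapse an effect category onto the loss/gain/no_effect/unknown scale."""
    return {
        "negative": "loss",
        "positive": "gain",
        "neutral": "no_effect",
        "unknown": "unknown",
    }[effect_direction(effect)]


@dataclass(frozen=True)
class InterfaceRegion:
    """A binding-associated sequence region, 1-based inclusive.

    ``source`` distinguishes structure-derived predictions from regions
    curated out of interaction records (``predicted`` | ``curated``).
    """

    protein_ac: str
    start: int
    end: int
    source: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad region {self.start}-{self.end}")

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


def interface_membership(
    points: PointChange | Iterable[PointChange],
    regions: Iterable[InterfaceRegion],
) -> dict[str, str]:
    """Inside/outside call per region source class.

    A (multi-position) change is inside a source class iff any of its
    positions lies within any region of that class on the same protein.
    Returns a dict over every source class present in ``regions`` (always
    including ``predicted`` and ``curated``), values ``inside``/``outside``.
    """
    if isinstance(points, PointChange):
        points = [points]
    points = list(points)
    result = {"predicted": "outside", "curated": "outside"}
    for region in regions:
        result.setdefault(region.source, "outside")
        if result[region.source] == "inside":
            continue
        for point in points:
            if point.protein_ac == region.protein_ac and region.covers(point.position):
                result[region.source] = "inside"
                break
    return result


def read_phosphosite_table(stream) -> set[tuple[str, int]]:
    """Read a phosphosite TSV (accession, position, residue) into the
    (accession, position) set the classifier consumes."""
    own = isinstance(stream, (str, Path))
    handle = open(stream, encoding="utf-8", newline="") if own else stream
    try:
        reader = csv.DictReader(handle, delimiter="\t")
        required = ("protein_ac", "position")
        missing = [c for c in required if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"phosphosite table missing column(s): {missing}")
        return {(row["protein_ac"].strip(), int(row["position"])) for row in reader}
    finally:
        if own:
            handle.close()


def read_interface_table(stream) -> list[InterfaceRegion]:
    """Read an interface-region TSV (accession, start, end, source)."""
    own = isinstance(stream, (str, Path))
    handle = open(stream, encoding="utf-8", newline="") if own else stream
    try:
        reader = csv.DictReader(handle, delimiter="\t")
        required = ("protein_ac", "start", "end", "source")
        missing = [c for c in required if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"interface table missing column(s): {missing}")
        return [
            InterfaceRegion(
                row["protein_ac"].strip(),
                int(row["start"]),
                int(row["end"]),
                row["source"].strip(),
            )
            for row in reader
        ]
    finally:
        if own:
            handle.close()
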