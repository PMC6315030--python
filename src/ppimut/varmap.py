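"""Map an external variant catalogue onto mutation annotations.

Matching follows three tiers. A feature spanning several positions is
first split into individual point substitutions; it is a ``full`` match
only when *every* position has a catalogue variant with the identical
alternate residue. Single-position features whose position is covered but
whose alternate residue differs are ``positional``; multi-position
features with any coverage short of full are ``partial`` (this bucket
covers both "some residue changes" and "some positions" matched — the
``detail`` field keeps the sub-distinction). Features with no covered
position are ``none``.

Insertions and deletions cannot be expressed as point substitutions and
are reported unmapped by construction.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

from .core import ChangeSegment, MutationFeature, VariantRecord

__all__ = [
    "PointChange",
    "SplitResult",
    "MappingCall",
    "MappingSummary",
    "VariantCatalogue",
    "split_to_point_changes",
    "map_annotation",
    "mapping_summary",
    "read_variant_table",
    "write_variant_table",
]


class PointChange(NamedTuple):
    """A single-position substitution."""

    protein_ac: str
    position: int
    original: str
    resulting: str


@dataclass
class SplitResult:
    """Point substitutions from one feature plus any unsplittable segments."""

    points: list[PointChange]
    skipped: list[ChangeSegment] = field(default_factory=list)


def split_to_point_changes(feature: MutationFeature) -> SplitResult:
    """Split a feature into individual point substitutions.

    A contiguous multi-residue substitution yields one triple per
    position. Insertion and deletion segments cannot be split and are
    returned in ``skipped``. A substitution whose original and resulting
    strings differ in length has no positionwise reading and raises
    ``ValueError``.
    """
    points: list[PointChange] = []
    skipped: list[ChangeSegment] = []
    for seg in feature.segments:
        if seg.kind != "substitution":
            skipped.append(seg)
            continue
        if len(seg.original) != len(seg.resulting):
            raise ValueError(
                f"feature {feature.feature_ac}: segment {seg.start}-{seg.end} "
                f"original/resulting lengths differ "
                f"({len(seg.original)} vs {len(seg.resulting)})"
            )
        for i, pos in enumerate(seg.positions):
            points.append(
                PointChange(feature.protein_ac, pos, seg.original[i], seg.resulting[i])
            )
    return SplitResult(points, skipped)


class VariantCatalogue:
    """Variant records indexed by (accession, position).

    Accession strings are matched exactly; an isoform-suffixed accession
    ("P12345-2") only matches variants carrying the same suffix.
    """

    def __init__(self, records: Iterable[VariantRecord] = ()) -> None:
        self._index: dict[tuple[str, int], list[VariantRecord]] = defaultdict(list)
        self._n = 0
        for record in records:
            self.add(record)

    def add(self, record: VariantRecord) -> None:
        self._index[(record.protein_ac, record.position)].append(record)
        self._n = self._n + 1

    def at(self, protein_ac: str, position: int) -> list[VariantRecord]:
        return self._index.get((protein_ac, position), [])

    def __len__(self) -> int:
        return self._n

    def __iter__(self):
        for records in self._index.values():
            yield from records


@dataclass
class MappingCall:
    """Mapping outcome for one annotation.

    ``category`` is ``full``, ``partial``, ``positional`` or ``none``;
    categories are mutually exclusive. ``detail`` preserves the partial
    sub-distinction (``residue-mismatch`` when every position is covered
    but some alternates differ, ``position-subset`` when some positions are
    uncovered) and carries warnings such as reference-residue demotions.
    ``disease_linked`` is true when any matched variant is disease-linked.
    """

    category: str
    matched_variants: tuple[VariantRecord, ...] = ()
    disease_linked: bool = False
    detail: str = ""


def map_annotation(
    feature: MutationFeature, catalogue: VariantCatalogue
) -> MappingCall:
    """Classify one feature against the catalogue (full/partial/positional/none).

    A catalogue variant whose reference residue is stated and disagrees
    with the feature's original residue cannot support a full match: the
    would-be full match is demoted to a positional one and noted in
    ``detail``.
    """
    split = split_to_point_changes(feature)
    if not split.points:
        return MappingCall("none", detail="indel: no point substitutions")

    matched: list[VariantRecord] = []
    n_full = 0
    n_covered = 0
    demoted = False
    for point in split.points:
        here = catalogue.at(point.protein_ac, point.position)
        if not here:
            continue
        n_covered += 1
        matched.extend(here)
        exact = [v for v in here if v.alternate == point.resulting]
        supported = [v for v in exact if not v.reference or v.reference == point.original]
        if supported:
            n_full += 1
        elif exact:
            demoted = True

    n_points = len(split.points)
    disease = any(v.disease_linked for v in matched)
    detail = "reference-residue-mismatch; " if demoted else ""
    if n_covered == 0:
        return MappingCall("none")
    if n_full == n_points and not split.skipped:
        return MappingCall("full", tuple(matched), disease)
    if n_points == 1 and not split.skipped:
        return MappingCall("positional", tuple(matched), disease, detail.strip("; "))
    sub = "residue-mismatch" if n_covered == n_points else "position-subset"
    return MappingCall("partial", tuple(matched), disease, detail + sub)


def _pct_int(count: int, total: int) -> int:
    if total == 0:
        return 0
    return int(
        (Decimal(100 * count) / Decimal(total)).quantize(
            Decimal("1"), rounding=ROUND_HALF_UP
        )
    )


@dataclass
class MappingSummary:
    """Mapping counts at annotation and distinct-sequence-change granularity.

    ``cumulative`` counts full + partial + positional. Percentages are
    rounded to the nearest integer (half-up).
    """

    n_annotations: int
    n_changes: int
    n_proteins: int
    annotation_counts: dict[str, int]
    change_counts: dict[str, int]
    pct_annotations_full: int
    pct_annotations_cumulative: int
    pct_annotations_pos_partial: int
    pct_changes_full: int
    pct_changes_cumulative: int
    pct_changes_pos_partial: int

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "n_annotations": self.n_annotations,
            "n_sequence_changes": self.n_changes,
            "n_proteins": self.n_proteins,
            "annotation_counts": dict(self.annotation_counts),
            "change_counts": dict(self.change_counts),
            "pct_annotations_full": self.pct_annotations_full,
            "pct_annotations_cumulative": self.pct_annotations_cumulative,
            "pct_annotations_pos_partial": self.pct_annotations_pos_partial,
            "pct_changes_full": self.pct_changes_full,
            "pct_changes_cumulative": self.pct_changes_cumulative,
            "pct_changes_pos_partial": self.pct_changes_pos_partial,
        }


def mapping_summary(
    features: Iterable[MutationFeature], catalogue: VariantCatalogue
) -> MappingSummary:
    """Map every annotation and summarize at both granularities.

    A distinct sequence change is a distinct (protein accession, ordered
    segment tuple); all annotations of one change necessarily share a
    mapping category, which is therefore also the change's category.
    """
    features = list(features)
    ann_counts = {"full": 0, "partial": 0, "positional": 0, "none": 0}
    change_category: dict[tuple, str] = {}
    proteins = set()
    for feature in features:
        call = map_annotation(feature, catalogue)
        ann_counts[call.category] += 1
        change_category[feature.change_key()] = call.category
        proteins.add(feature.protein_ac)

    chg_counts = {"full": 0, "partial": 0, "positional": 0, "none": 0}
    for category in change_category.values():
        chg_counts[category] += 1

    n_ann = len(features)
    n_chg = len(change_category)
    ann_cum = n_ann - ann_counts["none"]
    chg_cum = n_chg - chg_counts["none"]
    ann_pp = ann_counts["partial"] + ann_counts["positional"]
    chg_pp = chg_counts["partial"] + chg_counts["positional"]
    return MappingSummary(
        n_annotations=n_ann,
        n_changes=n_chg,
        n_proteins=len(proteins),
        annotation_counts=ann_counts,
        change_counts=chg_counts,
        pct_annotations_full=_pct_int(ann_counts["full"], n_ann),
        pct_annotations_cumulative=_pct_int(ann_cum, n_ann),
        pct_annotations_pos_partial=_pct_int(ann_pp, n_ann),
        pct_changes_full=_pct_int(chg_counts["full"], n_chg),
        pct_changes_cumulative=_pct_int(chg_cum, n_chg),
        pct_changes_pos_partial=_pct_int(chg_pp, n_chg),
    )


_VARIANT_COLUMNS = (
    "protein_ac",
    "position",
    "reference",
    "alternate",
    "disease_flag",
    "external_id",
    "source",
)


def read_variant_table(stream) -> list[VariantRecord]:
    """Read a variant catalogue TSV (accession, position, ref, alt,
    disease_flag 0/1, external_id, source)."""
    own = isinstance(stream, (str, Path))
    handle = open(stream, encoding="utf-8", newline="") if own else stream
    try:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = [c for c in _VARIANT_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"variant table missing column(s): {missing}")
        records = []
        for row in reader:
            records.append(
                VariantRecord(
                    protein_ac=row["protein_ac"].strip(),
                    position=int(row["position"]),
                    reference=row["reference"].strip(),
                    alternate=row["alternate"].strip(),
                    disease_linked=row["disease_flag"].strip() == "1",
                    external_id=row["external_id"].strip(),
                    source=row["source"].strip(),
                )
            )
        return records
    finally:
        if own:
            handle.close()


def write_variant_table(records: Iterable[VariantRecord], stream) -> int:
    """Write a variant catalogue TSV; returns rows written."""
    own = isinstance(stream, (str, Path))
    handle = open(stream, "w", encoding="utf-8", newline="") if own else stream
    try:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_VARIANT_COLUMNS)
        n = 0
        for r in records:
            writer.writerow(
                [
                    r.protein_ac,
                    r.position,
                    r.reference,
                    r.alternate,
                    "1" if r.disease_linked else "0",
                    r.external_id,
                    r.source,
                ]
            )
            n += 1
        return n
    finally:
        if own:
            handle.close()
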