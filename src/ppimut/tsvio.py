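"""Read, write and validate the tab-delimited mutations flat file.

Dialect (one row per contiguous changed section; multi-segment features
span several rows sharing one ``feature_ac``), columns in order::

    feature_ac  feature_label  feature_range  original_seq  resulting_seq
    feature_type  feature_annotation  protein_ac  protein_symbol
    protein_taxid  interaction_id  partner_acs  detection_method
    pubmed_id  source_db

* dialect version ``ppimut-mutations-tsv/1`` (header is checked by name,
  so column reordering by other tools is tolerated)
* coordinates 1-based inclusive; ranges written ``725-725`` (ASCII
  hyphen), en-dash accepted on read
* ``-`` denotes an empty original/resulting sequence (insertion/deletion)
* ``feature_type`` is ``<term name>(<MI id>)``, e.g.
  ``mutation disrupting interaction(MI:0573)``
* ``partner_acs`` is ``;``-separated, each entry ``accession`` or
  ``accession|proteoform-tag``
* encoding UTF-8
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import hgvs
from .core import (
    CATEGORY_DISPLAY,
    DEFAULT_VOCABULARY,
    ChangeSegment,
    EffectCategory,
    EffectVocabulary,
    MutationFeature,
    ParticipantRef,
    ProteinRecord,
    VocabularyError,
)

__all__ = [
    "DIALECT_VERSION",
    "COLUMNS",
    "TableReadError",
    "ValidationIssue",
    "read_mutations_table",
    "write_mutations_table",
    "validate_dataset",
    "read_fasta",
    "write_fasta",
]

DIALECT_VERSION = "ppimut-mutations-tsv/1"

COLUMNS = (
    "feature_ac",
    "feature_label",
    "feature_range",
    "original_seq",
    "resulting_seq",
    "feature_type",
    "feature_annotation",
    "protein_ac",
    "protein_symbol",
    "protein_taxid",
    "interaction_id",
    "partner_acs",
    "detection_method",
    "pubmed_id",
    "source_db",
)

#: columns that must agree across all rows of one feature accession.
_SHARED_COLUMNS = tuple(c for c in COLUMNS if c not in
                        ("feature_range", "original_seq", "resulting_seq"))

_RANGE_RE = re.compile(r"^(\d+)\s*[-–—−]\s*(\d+)$")
_TYPE_RE = re.compile(r"^(.*?)\s*\((MI:\d+)\)\s*$")


class TableReadError(ValueError):
    """Structurally invalid mutations table."""


@dataclass(frozen=True)
class ValidationIssue:
    """One finding of :func:`validate_dataset`.

    ``feature_ac`` is the affected feature accession, or ``"<file>"`` for
    file-level findings. ``severity`` is ``error`` or ``warning``; ``code``
    is a short machine-readable string.
    """

    feature_ac: str
    severity: str
    code: str
    message: str


def _open(stream, mode: str = "r"):
    if isinstance(stream, (str, Path)):
        return open(stream, mode, encoding="utf-8", newline=""), True
    return stream, False


def _parse_range(text: str, row_no: int) -> tuple[int, int]:
    m = _RANGE_RE.match(text.strip())
    if not m:
        raise TableReadError(f"row {row_no}: non-numeric range {text!r}")
    start, end = int(m.group(1)), int(m.group(2))
    if end < start:
        raise TableReadError(f"row {row_no}: range end {end} < start {start}")
    return start, end


def _parse_partners(cell: str) -> tuple[ParticipantRef, ...]:
    refs = []
    for entry in cell.split(";"):
        entry = entry.strip()
        if not entry:
            continue
        ac, _, tag = entry.partition("|")
        refs.append(ParticipantRef(ac, tag))
    return tuple(refs)


def _format_partners(partners: Iterable[ParticipantRef]) -> str:
    return ";".join(
        f"{p.protein_ac}|{p.proteoform_tag}" if p.proteoform_tag else p.protein_ac
        for p in partners
    )


def _parse_effect(
    cell: str, vocabulary: EffectVocabulary
) -> tuple[EffectCategory, str]:
    """Return (effect, unknown_term) for a ``feature_type`` cell."""
    m = _TYPE_RE.match(cell)
    name, mi_id = (m.group(1), m.group(2)) if m else (cell.strip(), "")
    try:
        return vocabulary.resolve(name, mi_id), ""
    except VocabularyError:
        return EffectCategory("undefined", mi_id=mi_id), cell.strip()


def _format_effect(feature: MutationFeature, vocabulary: EffectVocabulary) -> str:
    if feature.unknown_effect_term:
        return feature.unknown_effect_term
    effect = feature.effect
    name = None
    if effect.mi_id:
        name = vocabulary.term_name(effect.mi_id)
    if name is None:
        name = CATEGORY_DISPLAY[effect.name]
    return f"{name}({effect.mi_id})" if effect.mi_id else name


def read_mutations_table(
    stream, vocabulary: EffectVocabulary = DEFAULT_VOCABULARY
) -> list[MutationFeature]:
    """Read a mutations flat file into :class:`MutationFeature` objects.

    ``stream`` may be a path or an open text handle. Rows sharing a
    ``feature_ac`` are merged into one multi-segment feature; their shared
    metadata columns must agree, otherwise a :class:`TableReadError` lists
    the offending row numbers.
    """
    handle, own = _open(stream)
    try:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise TableReadError("empty stream: missing header row") from None
        index = {name.strip(): i for i, name in enumerate(header)}
        missing = [c for c in COLUMNS if c not in index]
        if missing:
            raise TableReadError(f"missing mandatory column(s): {missing}")

        order: list[str] = []
        rows_by_ac: dict[str, list[tuple[int, dict[str, str]]]] = {}
        for row_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < len(header):
                row = row + [""] * (len(header) - len(row))
            cells = {c: row[index[c]].strip() for c in COLUMNS}
            ac = cells["feature_ac"]
            if not ac:
                raise TableReadError(f"row {row_no}: empty feature_ac")
            if ac not in rows_by_ac:
                order.append(ac)
                rows_by_ac[ac] = []
            rows_by_ac[ac].append((row_no, cells))

        features: list[MutationFeature] = []
        for ac in order:
            rows = rows_by_ac[ac]
            first_no, first = rows[0]
            for col in _SHARED_COLUMNS:
                values = {cells[col] for _, cells in rows}
                if len(values) > 1:
                    nos = [no for no, _ in rows]
                    raise TableReadError(
                        f"feature {ac}: rows {nos} disagree on column "
                        f"{col!r}: {sorted(values)}"
                    )
            segments = []
            for row_no, cells in rows:
                start, end = _parse_range(cells["feature_range"], row_no)
                original = "" if cells["original_seq"] in ("-", "") else cells["original_seq"]
                resulting = "" if cells["resulting_seq"] in ("-", "") else cells["resulting_seq"]
                flanking = ""
                if not original:  # recover insertion flanks from the label
                    parsed = hgvs.parse_label(cells["feature_label"], strict=False)
                    for seg in parsed.segments:
                        if seg.kind == "insertion" and (seg.start, seg.end) == (start, end):
                            flanking = seg.flanking
                try:
                    segments.append(
                        ChangeSegment(start, end, original, resulting, flanking)
                    )
                except ValueError as exc:
                    raise TableReadError(f"row {row_no}: {exc}") from None
            effect, unknown_term = _parse_effect(first["feature_type"], vocabulary)
            features.append(
                MutationFeature(
                    feature_ac=ac,
                    label=first["feature_label"],
                    segments=tuple(segments),
                    effect=effect,
                    protein_ac=first["protein_ac"],
                    protein_organism=first["protein_taxid"],
                    protein_symbol=first["protein_symbol"],
                    annotations=first["feature_annotation"],
                    interaction_id=first["interaction_id"],
                    partners=_parse_partners(first["partner_acs"]),
                    publication=first["pubmed_id"],
                    source_db=first["source_db"],
                    detection_method=first["detection_method"],
                    unknown_effect_term=unknown_term,
                )
            )
        return features
    finally:
        if own:
            handle.close()


def write_mutations_table(
    features: Iterable[MutationFeature],
    stream,
    vocabulary: EffectVocabulary = DEFAULT_VOCABULARY,
) -> int:
    """Write features to a mutations flat file; returns rows written.

    Multi-segment features emit one row per contiguous segment, all sharing
    the feature accession and label, so the row count equals the total
    segment count.
    """
    handle, own = _open(stream, "w")
    try:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(COLUMNS)
        n = 0
        for feature in features:
            effect_cell = _format_effect(feature, vocabulary)
            partners_cell = _format_partners(feature.partners)
            for seg in feature.segments:
                writer.writerow(
                    [
                        feature.feature_ac,
                        feature.label,
                        f"{seg.start}-{seg.end}",
                        seg.original or "-",
                        seg.resulting or "-",
                        effect_cell,
                        feature.annotations,
                        feature.protein_ac,
                        feature.protein_symbol,
                        feature.protein_organism,
                        feature.interaction_id,
                        partners_cell,
                        feature.detection_method,
                        feature.publication,
                        feature.source_db,
                    ]
                )
                n += 1
        return n
    finally:
        if own:
            handle.close()


def validate_dataset(
    features: Iterable[MutationFeature],
    proteome: Mapping[str, ProteinRecord],
    vocabulary: EffectVocabulary = DEFAULT_VOCABULARY,
) -> list[ValidationIssue]:
    """Check features against a proteome and their own labels.

    Findings (never exceptions): per feature, range within protein length,
    stored original residues equal to the protein sequence at the stated
    coordinates, label/column concordance, unknown effect terms. Features
    on absent accessions yield a ``protein-unavailable`` warning.
    """
    issues: list[ValidationIssue] = []
    for feature in features:
        ac = feature.feature_ac
        if feature.unknown_effect_term:
            issues.append(
                ValidationIssue(
                    ac,
                    "error",
                    "unknown-effect-term",
                    f"effect term {feature.unknown_effect_term!r} is outside "
                    "the vocabulary",
                )
            )
        for problem in hgvs.validate_label_consistency(feature):
            issues.append(ValidationIssue(ac, "error", "label-mismatch", problem))
        protein = proteome.get(feature.protein_ac)
        if protein is None:
            issues.append(
                ValidationIssue(
                    ac,
                    "warning",
                    "protein-unavailable",
                    f"protein {feature.protein_ac} absent from the proteome",
                )
            )
            continue
        for seg in feature.segments:
            if seg.end > len(protein):
                issues.append(
                    ValidationIssue(
                        ac,
                        "error",
                        "range-out-of-bounds",
                        f"segment {seg.start}-{seg.end} exceeds sequence "
                        f"length {len(protein)} of {protein.accession}",
                    )
                )
                continue
            if seg.original:
                observed = protein.sequence[seg.start - 1 : seg.end]
                if observed != seg.original:
                    issues.append(
                        ValidationIssue(
                            ac,
                            "error",
                            "sequence-mismatch",
                            f"segment {seg.start}-{seg.end}: stored original "
                            f"{seg.original!r} but sequence has {observed!r}",
                        )
                    )
    return issues


def read_fasta(stream) -> dict[str, ProteinRecord]:
    """Read a FASTA proteome into accession-keyed protein records."""
    handle, own = _open(stream)
    try:
        proteome = {}
        for record in SeqIO.parse(handle, "fasta"):
            proteome[record.id] = ProteinRecord(record.id, str(record.seq).upper())
        return proteome
    finally:
        if own:
            handle.close()


def write_fasta(proteome: Mapping[str, ProteinRecord], stream) -> None:
    """Write an accession-keyed proteome as FASTA (sorted by accession)."""
    handle, own = _open(stream, "w")
    try:
        records = [
            SeqRecord(Seq(p.sequence), id=p.accession, description="")
            for _, p in sorted(proteome.items())
        ]
        SeqIO.write(records, handle, "fasta")
    finally:
        if own:
            handle.close()
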