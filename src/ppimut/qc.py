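"""Quality control of feature coordinates across protein sequence releases.

When a referenced protein sequence changes between releases, annotated
feature coordinates may silently point at the wrong residues. The update
procedure here re-anchors each feature by exact search: the original
residues of every segment, extended by a flanking context window, are
looked up verbatim in the new sequence. A unique hit for every segment
with one common offset shifts the feature; anything ambiguous flags it
for curator review rather than guessing.

Flag reasons form a small taxonomy: ``no-match``, ``ambiguous-match``,
``inconsistent-offsets``, ``protein-missing-old``, ``protein-removed``,
``invalid-feature``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from . import hgvs
from .core import ChangeSegment, MutationFeature, ProteinRecord

__all__ = [
    "DEFAULT_CONTEXT",
    "RemapError",
    "RemapResult",
    "UpdateReport",
    "check_feature",
    "remap_feature",
    "run_update",
]

#: default flanking context, residues on each side (truncated at termini).
DEFAULT_CONTEXT = 10


class RemapError(ValueError):
    """Precondition failure: feature does not validate against the old sequence."""


@dataclass
class RemapResult:
    """Outcome of remapping one feature onto a new sequence release.

    ``status`` is ``unchanged``, ``shifted`` or ``flagged``. ``offset`` is
    the common signed shift (0 unless shifted); ``new_segments`` carry the
    relocated coordinates (empty when flagged); ``reason`` explains a flag.
    """

    status: str
    offset: int = 0
    new_segments: tuple[ChangeSegment, ...] = ()
    reason: str = ""


@dataclass
class UpdateReport:
    """Aggregate outcome of a proteome update run."""

    counts: dict[str, int]
    results: dict[str, RemapResult]
    updated_features: list[MutationFeature] = field(default_factory=list)


def _check_segments(segments: Iterable[ChangeSegment], sequence: str) -> str:
    status = "valid"
    for seg in segments:
        if seg.end > len(sequence):
            return "out_of_bounds"
        if seg.original and sequence[seg.start - 1 : seg.end] != seg.original:
            status = "mismatch"
    return status


def check_feature(feature: MutationFeature, protein: ProteinRecord) -> str:
    """Classify a feature against a sequence: ``valid``, ``mismatch`` or
    ``out_of_bounds``.

    Valid means every segment lies within the sequence and its original
    residues equal the sequence at the stated 1-based coordinates.
    Out-of-bounds takes precedence over mismatch.
    """
    return _check_segments(feature.segments, protein.sequence)


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (overlapping) 0-based occurrence indices of ``needle``."""
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def remap_feature(
    feature: MutationFeature,
    old_seq: str,
    new_seq: str,
    context: int = DEFAULT_CONTEXT,
) -> RemapResult:
    """Re-anchor a feature's coordinates from ``old_seq`` onto ``new_seq``.

    Each segment's original residues plus ``context`` flanking residues on
    either side (truncated at the termini) are searched for exactly in the
    new sequence. Every segment must hit exactly once and all segments must
    agree on a single offset; otherwise the feature is flagged.

    Raises :class:`RemapError` if the feature does not validate against
    ``old_seq``.
    """
    status = _check_segments(feature.segments, old_seq)
    if status != "valid":
        raise RemapError(
            f"feature {feature.feature_ac} is {status} against the old sequence"
        )
    if new_seq == old_seq:
        return RemapResult("unchanged", 0, tuple(feature.segments))

    offsets: list[int] = []
    for seg in feature.segments:
        lo = max(0, seg.start - 1 - context)
        hi = min(len(old_seq), seg.end + context)
        window = old_seq[lo:hi]
        hits = _find_all(new_seq, window)
        if not hits:
            return RemapResult(
                "flagged",
                reason=f"no-match: context of segment {seg.start}-{seg.end} "
                "absent from the new sequence",
            )
        if len(hits) > 1:
            return RemapResult(
                "flagged",
                reason=f"ambiguous-match: context of segment "
                f"{seg.start}-{seg.end} occurs {len(hits)} times in the new "
                "sequence",
            )
        offsets.append(hits[0] - lo)
    if len(set(offsets)) > 1:
        return RemapResult(
            "flagged",
            reason=f"inconsistent-offsets: per-segment offsets {offsets} "
            "disagree (possible internal rearrangement)",
        )

    offset = offsets[0]
    new_segments = tuple(
        replace(seg, start=seg.start + offset, end=seg.end + offset)
        for seg in feature.segments
    )
    if _check_segments(new_segments, new_seq) != "valid":
        # cannot happen for an exact unique context hit; defensive
        return RemapResult(
            "flagged", reason="post-check-failure: shifted coordinates do not "
            "re-validate"
        )
    return RemapResult("shifted", offset, new_segments)


def run_update(
    features: Iterable[MutationFeature],
    old_proteome: Mapping[str, ProteinRecord],
    new_proteome: Mapping[str, ProteinRecord],
    context: int = DEFAULT_CONTEXT,
) -> UpdateReport:
    """Remap every feature from one proteome release to the next.

    Every feature lands in exactly one status; flagged features are
    excluded from ``updated_features`` (left out of the data set until a
    curator revisits them). Shifted features get relocated segments and a
    re-generated short label.
    """
    counts = {"unchanged": 0, "shifted": 0, "flagged": 0}
    results: dict[str, RemapResult] = {}
    updated: list[MutationFeature] = []
    for feature in features:
        old = old_proteome.get(feature.protein_ac)
        new = new_proteome.get(feature.protein_ac)
        if old is None:
            result = RemapResult(
                "flagged",
                reason=f"protein-missing-old: {feature.protein_ac} absent "
                "from the old proteome",
            )
        elif new is None:
            result = RemapResult(
                "flagged",
                reason=f"protein-removed: {feature.protein_ac} absent from "
                "the new proteome",
            )
        else:
            try:
                result = remap_feature(feature, old.sequence, new.sequence, context)
            except RemapError as exc:
                result = RemapResult("flagged", reason=f"invalid-feature: {exc}")
        counts[result.status] += 1
        results[feature.feature_ac] = result
        if result.status == "unchanged":
            updated.append(feature)
        elif result.status == "shifted":
            shifted = replace(
                feature,
                segments=result.new_segments,
                label=hgvs.format_label(result.new_segments),
            )
            updated.append(shifted)
    return UpdateReport(counts=counts, results=results, updated_features=updated)
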