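"""Parse and emit HGVS-style protein-change short labels.

Feature short labels follow the protein-level HGVS recommendations, e.g.
``p.Arg725Glu``. The grammar supported here is the subset used by the
mutations flat file:

* single substitutions       ``p.Arg725Glu``
* contiguous multi-residue   ``p.Cys_Ser215-216Ala_Ala``
* discontiguous multi        ``p.[Asn31His;Ala60Val]``
* simple deletions           ``p.Arg725del``
* simple insertions          ``p.Ala12_Gly13insSer``

Positions are 1-based; residue names are three-letter on the wire and
one-letter in :class:`~ppimut.core.ChangeSegment`. Strict parsing rejects
malformed labels with a character offset; lenient parsing repairs the
common legacy defects (stray whitespace, lowercase residue names, en-dash
ranges) and reports everything else as warnings instead of raising.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Data.IUPACData import (
    protein_letters_1to3_extended,
    protein_letters_3to1_extended,
)

from .core import ChangeSegment, MutationFeature

__all__ = [
    "LabelParseError",
    "LabelParseResult",
    "parse_label",
    "format_label",
    "validate_label_consistency",
]

# three-letter -> one-letter, title-case keys (includes Sec/U and B/Z/X codes)
THREE_TO_ONE: dict[str, str] = dict(protein_letters_3to1_extended)
ONE_TO_THREE: dict[str, str] = dict(protein_letters_1to3_extended)

_EN_DASHES = "–—−"  # en dash, em dash, minus sign


class LabelParseError(ValueError):
    """Malformed protein-change label; ``offset`` is the 0-based character
    position in the input where parsing failed."""

    def __init__(self, message: str, offset: int = 0) -> None:
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


@dataclass
class LabelParseResult:
    """Outcome of parsing one short label."""

    segments: tuple[ChangeSegment, ...]
    variant_form: str  # single | multi_bracket | contiguous_multi
    warnings: list[str] = field(default_factory=list)


_RES = r"[A-Z][a-z]{2}"
_SINGLE_SUB = re.compile(rf"^({_RES})(\d+)({_RES})$")
_CONTIG_SUB = re.compile(
    rf"^((?:{_RES})(?:_{_RES})*)(\d+)-(\d+)((?:{_RES})(?:_{_RES})*)$"
)
_DELETION = re.compile(rf"^({_RES})(\d+)del$")
_INSERTION = re.compile(rf"^({_RES})(\d+)_({_RES})(\d+)ins((?:{_RES})+)$")


def _make_segment(offset: int, *args, **kwargs) -> ChangeSegment:
    try:
        return ChangeSegment(*args, **kwargs)
    except ValueError as exc:
        raise LabelParseError(str(exc), offset) from None


def _to_one(name: str, offset: int) -> str:
    try:
        return THREE_TO_ONE[name]
    except KeyError:
        raise LabelParseError(f"unknown residue name {name!r}", offset) from None


def _names_to_one(joined: str, offset: int) -> str:
    """Convert ``Cys_Ser`` or ``CysSer`` style runs to one-letter codes."""
    out = []
    pos = offset
    for name in joined.replace("_", " ").split():
        out.append(_to_one(name, pos))
        pos += len(name) + 1
    return "".join(out)


def _parse_simple(body: str, offset: int) -> ChangeSegment:
    """Parse one unbracketed change description (no ``p.`` prefix)."""
    m = _SINGLE_SUB.match(body)
    if m:
        orig, pos, res = m.group(1), int(m.group(2)), m.group(3)
        return _make_segment(
            offset, pos, pos, _to_one(orig, offset), _to_one(res, offset + m.start(3))
        )
    m = _CONTIG_SUB.match(body)
    if m:
        start, end = int(m.group(2)), int(m.group(3))
        if end < start:
            raise LabelParseError(f"range end {end} < start {start}", offset + m.start(3))
        orig = _names_to_one(m.group(1), offset)
        res = _names_to_one(m.group(4), offset + m.start(4))
        if len(orig) != end - start + 1:
            raise LabelParseError(
                f"{len(orig)} original residues for range {start}-{end}", offset
            )
        return _make_segment(offset, start, end, orig, res)
    m = _DELETION.match(body)
    if m:
        pos = int(m.group(2))
        return _make_segment(offset, pos, pos, _to_one(m.group(1), offset), "")
    m = _INSERTION.match(body)
    if m:
        left, lpos = m.group(1), int(m.group(2))
        right, rpos = m.group(3), int(m.group(4))
        if rpos != lpos + 1:
            raise LabelParseError(
                f"insertion flanks {lpos} and {rpos} are not adjacent",
                offset + m.start(4),
            )
        seq = "".join(
            _to_one(name, offset + m.start(5) + 3 * i)
            for i, name in enumerate(re.findall(_RES, m.group(5)))
        )
        flank = _to_one(left, offset) + _to_one(right, offset + m.start(3))
        return _make_segment(offset, lpos, rpos, "", seq, flanking=flank)
    # pinpoint the first structurally wrong character for the error message
    probe = re.match(rf"^(?:{_RES})(?:_{_RES})*", body)
    bad = probe.end() if probe else 0
    raise LabelParseError(f"cannot parse change description {body!r}", offset + bad)


def _strict_parse(label: str) -> LabelParseResult:
    if not label.startswith("p."):
        raise LabelParseError("label must start with 'p.'", 0)
    body = label[2:]
    if body.startswith("["):
        if not body.endswith("]"):
            raise LabelParseError("unterminated '['", len(label) - 1)
        inner = body[1:-1]
        parts = inner.split(";")
        if len(parts) < 2:
            raise LabelParseError("bracketed label needs >= 2 changes", 2)
        segments = []
        offset = 3  # position of the first char inside the bracket
        for part in parts:
            segments.append(_parse_simple(part, offset))
            offset += len(part) + 1
        segments.sort(key=lambda s: (s.start, s.end))
        return LabelParseResult(tuple(segments), "multi_bracket")
    segment = _parse_simple(body, 2)
    form = "contiguous_multi" if segment.end > segment.start and segment.kind == "substitution" else "single"
    return LabelParseResult((segment,), form)


def _repair(label: str) -> tuple[str, list[str]]:
    """Apply lenient repairs; return (repaired label, warnings)."""
    warnings: list[str] = []
    repaired = label
    if re.search(r"\s", repaired):
        repaired = re.sub(r"\s+", "", repaired)
        warnings.append("removed stray whitespace")
    if any(d in repaired for d in _EN_DASHES):
        for d in _EN_DASHES:
            repaired = repaired.replace(d, "-")
        warnings.append("normalized en-dash to hyphen in range")

    def fix_case(m: re.Match) -> str:
        run = m.group(0)
        if run[0].isupper() and run[1:].islower() and len(run) == 3:
            return run  # already canonical
        lower = run.lower()
        if lower == "del":
            return "del"
        if lower == "ins":
            return "ins"
        if lower.startswith("ins"):
            rest = lower[3:]
            chunks = [rest[i : i + 3].capitalize() for i in range(0, len(rest), 3)]
            return "ins" + "".join(chunks)
        if len(run) % 3 == 0:
            return "".join(
                lower[i : i + 3].capitalize() for i in range(0, len(run), 3)
            )
        return run

    body = repaired[2:] if repaired.startswith("p.") else repaired
    fixed_body = re.sub(r"[A-Za-z]{3,}", fix_case, body)
    if fixed_body != body:
        repaired = (repaired[:2] if repaired.startswith("p.") else "") + fixed_body
        warnings.append("normalized residue name capitalization")
    return repaired, warnings


def parse_label(label: str, strict: bool = True) -> LabelParseResult:
    """Parse a protein-change short label into change segments.

    Parameters
    ----------
    label
        HGVS-style protein label, e.g. ``"p.Arg725Glu"``.
    strict
        When true (default) malformed labels raise :class:`LabelParseError`
        with a character offset. When false, legacy defects are repaired
        where possible and every deviation is reported in
        ``result.warnings``; unparseable labels yield an empty segment
        tuple instead of raising.
    """
    if strict:
        return _strict_parse(label)
    try:
        return _strict_parse(label)
    except LabelParseError:
        pass
    repaired, warnings = _repair(label)
    try:
        result = _strict_parse(repaired)
    except LabelParseError as exc:
        return LabelParseResult((), "single", warnings + [f"unparseable: {exc}"])
    result.warnings = warnings or [f"non-canonical label {label!r}"]
    return result


def _to_three(code: str) -> str:
    try:
        return ONE_TO_THREE[code]
    except KeyError:
        raise ValueError(f"unknown one-letter residue code {code!r}") from None


def _format_simple(segment: ChangeSegment) -> str:
    if segment.kind == "insertion":
        if len(segment.flanking) != 2:
            raise ValueError(
                "insertion segment needs its two flanking residues to be "
                "formatted as a label"
            )
        left, right = segment.flanking
        seq = "".join(_to_three(c) for c in segment.resulting)
        return (
            f"{_to_three(left)}{segment.start}_{_to_three(right)}{segment.end}ins{seq}"
        )
    if segment.kind == "deletion":
        if segment.end != segment.start:
            raise ValueError("multi-residue deletions are outside the label grammar")
        return f"{_to_three(segment.original)}{segment.start}del"
    if segment.end == segment.start:
        return f"{_to_three(segment.original)}{segment.start}{_to_three(segment.resulting)}"
    orig = "_".join(_to_three(c) for c in segment.original)
    res = "_".join(_to_three(c) for c in segment.resulting)
    return f"{orig}{segment.start}-{segment.end}{res}"


def format_label(segments) -> str:
    """Emit the canonical short label for a list of change segments.

    Single substitution -> ``p.Xaa<pos>Yaa``; contiguous multi-residue ->
    underscore/range form; multiple discontiguous segments -> bracketed
    semicolon form. ``format_label(parse_label(x).segments) == x`` for
    canonical labels.
    """
    segments = sorted(segments, key=lambda s: (s.start, s.end))
    if not segments:
        raise ValueError("cannot format an empty segment list")
    if len(segments) == 1:
        return "p." + _format_simple(segments[0])
    return "p.[" + ";".join(_format_simple(s) for s in segments) + "]"


def validate_label_consistency(feature: MutationFeature) -> list[str]:
    """Report disagreements between a feature's label and its stored columns.

    Returns human-readable issue strings; an empty list means the label and
    the range/original/resulting fields agree. Conflicts are flagged, never
    silently resolved.
    """
    issues: list[str] = []
    result = parse_label(feature.label, strict=False)
    if not result.segments:
        issues.append(f"label {feature.label!r} is unparseable: {result.warnings}")
        return issues
    parsed = sorted(result.segments, key=lambda s: (s.start, s.end))
    stored = list(feature.sorted_segments)
    if len(parsed) != len(stored):
        issues.append(
            f"label describes {len(parsed)} segment(s) but {len(stored)} stored"
        )
        return issues
    for p, s in zip(parsed, stored):
        where = f"segment {s.start}-{s.end}"
        if (p.start, p.end) != (s.start, s.end):
            issues.append(
                f"{where}: label range {p.start}-{p.end} differs from stored "
                f"range {s.start}-{s.end}"
                + (
                    " (range lengths differ)"
                    if p.end - p.start != s.end - s.start
                    else ""
                )
            )
            continue
        if p.original != s.original:
            issues.append(
                f"{where}: label original {p.original!r} differs from stored "
                f"{s.original!r}"
            )
        if p.resulting != s.resulting:
            issues.append(
                f"{where}: label resulting {p.resulting!r} differs from stored "
                f"{s.resulting!r}"
            )
    return issues
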