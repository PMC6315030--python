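"""Label grammar: published examples, round-trip properties, lenient
repairs, label/column concordance."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import TABLE1_LABELS
from ppimut.core import ChangeSegment, EffectCategory, MutationFeature
from ppimut.hgvs import (
    LabelParseError,
    format_label,
    parse_label,
    validate_label_consistency,
)


@pytest.mark.parametrize(
    "label,expected,form",
    [
        ("p.Arg725Glu", [(725, 725, "R", "E")], "single"),
        ("p.Cys_Ser215-216Ala_Ala", [(215, 216, "CS", "AA")], "contiguous_multi"),
        ("p.[Asn31His;Ala60Val]", [(31, 31, "N", "H"), (60, 60, "A", "V")],
         "multi_bracket"),
        ("p.Thr2Ala", [(2, 2, "T", "A")], "single"),
        ("p.Ile114Gly", [(114, 114, "I", "G")], "single"),
        ("p.Arg725del", [(725, 725, "R", "")], "single"),
        ("p.Ala12_Gly13insSer", [(12, 13, "", "S")], "single"),
    ],
)
def test_parse_published_and_indel_labels(label, expected, form):
    result = parse_label(label)
    got = [(s.start, s.end, s.original, s.resulting) for s in result.segments]
    assert got == expected
    assert result.variant_form == form
    assert result.warnings == []


@pytest.mark.parametrize(
    "label,offset_hint",
    [
        ("p.Xyz12Ala", "Xyz"),          # unknown residue name
        ("p.ArgGlu", "position"),        # no position
        ("p.Cys_Ser216-215Ala_Ala", "215"),  # end < start
        ("Arg725Glu", "p."),             # missing prefix
    ],
)
def test_strict_mode_rejects_malformed_labels(label, offset_hint):
    with pytest.raises(LabelParseError) as err:
        parse_label(label)
    assert err.value.offset >= 0


def test_format_single_and_multi_segment_labels():
    assert format_label([ChangeSegment(2, 2, "T", "A")]) == "p.Thr2Ala"
    assert format_label([ChangeSegment(114, 114, "I", "G")]) == "p.Ile114Gly"
    assert (
        format_label([ChangeSegment(60, 60, "A", "V"), ChangeSegment(31, 31, "N", "H")])
        == "p.[Asn31His;Ala60Val]"
    )  # emitted sorted by position
    with pytest.raises(ValueError):
        format_label([])


@pytest.mark.parametrize("label", TABLE1_LABELS)
def test_round_trip_on_published_labels(label):
    assert format_label(parse_label(label).segments) == label


_RES1 = st.sampled_from(list("ACDEFGHIKLMNPQRSTVWY"))


@st.composite
def _segment_lists(draw):
    """Sorted, non-overlapping substitution/deletion/insertion segments."""
    n = draw(st.integers(1, 4))
    segments, cursor = [], 1
    for _ in range(n):
        start = cursor + draw(st.integers(1, 50))
        kind = draw(st.sampled_from(["sub", "multi", "del", "ins"]))
        if kind == "sub":
            seg = ChangeSegment(start, start, draw(_RES1), draw(_RES1))
        elif kind == "multi":
            length = draw(st.integers(2, 3))
            orig = "".join(draw(st.lists(_RES1, min_size=length, max_size=length)))
            res = "".join(draw(st.lists(_RES1, min_size=1, max_size=3)))
            seg = ChangeSegment(start, start + length - 1, orig, res)
        elif kind == "del":
            seg = ChangeSegment(start, start, draw(_RES1), "")
        else:
            ins = "".join(draw(st.lists(_RES1, min_size=1, max_size=3)))
            seg = ChangeSegment(start, start + 1, "", ins,
                                flanking=draw(_RES1) + draw(_RES1))
        segments.append(seg)
        cursor = seg.end + 1
    return segments


@settings(max_examples=200, deadline=None, derandomize=True)
@given(_segment_lists())
def test_round_trip_segments_to_label_and_back(segments):
    label = format_label(segments)
    parsed = parse_label(label)
    assert list(parsed.segments) == segments
    assert format_label(parsed.segments) == label
    assert all(s.original == s.original.upper() for s in parsed.segments)


@pytest.mark.parametrize(
    "messy,clean",
    [
        (" p.Arg725Glu ", "p.Arg725Glu"),
        ("p.arg725glu", "p.Arg725Glu"),
        ("p.Cys_Ser215–216Ala_Ala", "p.Cys_Ser215-216Ala_Ala"),
        ("p.cys_ser215-216ala_ala", "p.Cys_Ser215-216Ala_Ala"),
    ],
)
def test_lenient_mode_repairs_legacy_defects(messy, clean):
    result = parse_label(messy, strict=False)
    assert result.warnings, "a repaired label must carry warnings"
    assert format_label(result.segments) == clean


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.text(min_size=0, max_size=30))
def test_lenient_mode_never_raises_and_warns_iff_strict_raises(text):
    result = parse_label(text, strict=False)
    try:
        parse_label(text, strict=True)
        strict_ok = True
    except LabelParseError:
        strict_ok = False
    assert bool(result.warnings) == (not strict_ok)


def _feature(label, segments):
    return MutationFeature(
        feature_ac="EBI-T1",
        label=label,
        segments=tuple(segments),
        effect=EffectCategory("undefined"),
        protein_ac="P1",
    )


def test_label_column_concordance():
    assert validate_label_consistency(
        _feature("p.Arg725Glu", [ChangeSegment(725, 725, "R", "E")])
    ) == []
    # label Asn (N) against stored original D: flagged, not resolved
    issues = validate_label_consistency(
        _feature("p.Asn31His", [ChangeSegment(31, 31, "D", "H")])
    )
    assert len(issues) == 1 and "'N'" in issues[0] and "'D'" in issues[0]
    # range length disagreement
    issues = validate_label_consistency(
        _feature("p.Thr2Ala", [ChangeSegment(2, 3, "TS", "AA")])
    )
    assert len(issues) == 1 and "range" in issues[0]
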