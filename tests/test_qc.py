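"""Coordinate QC: validity checks, context-search remapping, update runs,
and equivalence with a brute-force placement oracle."""

import numpy as np
import pytest

from ppimut.core import (
    ChangeSegment,
    EffectCategory,
    MutationFeature,
    ProteinRecord,
)
from ppimut.qc import RemapError, check_feature, remap_feature, run_update


def _feature(segments, protein_ac="P1", ac="EBI-QT1"):
    segments = tuple(segments)
    return MutationFeature(
        feature_ac=ac,
        label="p.Ala1Val",  # label content irrelevant to qc
        segments=segments,
        effect=EffectCategory("disrupting", "MI:0573"),
        protein_ac=protein_ac,
    )


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


def test_check_feature_statuses():
    seq = "A" * 724 + "R" + "A" * 30
    feature = _feature([ChangeSegment(725, 725, "R", "E")])
    assert check_feature(feature, ProteinRecord("P1", seq)) == "valid"
    assert check_feature(feature, ProteinRecord("P1", "A" * 700)) == "out_of_bounds"
    bad = "A" * 724 + "K" + "A" * 30
    assert check_feature(feature, ProteinRecord("P1", bad)) == "mismatch"


def test_remap_identity_and_shift_and_flag():
    rng = np.random.default_rng(42)
    old = _random_seq(rng, 300)
    pos = 150
    feature = _feature([ChangeSegment(pos, pos, old[pos - 1], "A")])

    result = remap_feature(feature, old, old)
    assert result.status == "unchanged" and result.offset == 0
    assert result.new_segments == feature.segments

    new = "GS" + old  # 2-residue N-terminal extension
    result = remap_feature(feature, old, new)
    assert result.status == "shifted" and result.offset == 2
    seg = result.new_segments[0]
    assert new[seg.start - 1 : seg.end] == seg.original

    scrambled = old[:100] + _random_seq(rng, 100) + old[200:]
    result = remap_feature(feature, old, scrambled)
    assert result.status == "flagged" and result.reason.startswith("no-match")


def test_remap_flags_ambiguous_context():
    unit = "ACDEFGHIKLMNPQRSTVWY" * 2  # 40-mer
    old = unit + "WWWWW"
    feature = _feature([ChangeSegment(5, 5, old[4], "A")])
    duplicated = unit + unit + "WWWWW"
    result = remap_feature(feature, old, duplicated, context=10)
    assert result.status == "flagged"
    assert result.reason.startswith("ambiguous-match")


def test_remap_requires_valid_feature_against_old_sequence():
    with pytest.raises(RemapError):
        remap_feature(_feature([ChangeSegment(5, 5, "W", "A")]), "AAAAAAAAAA", "AAAA")


def test_remap_flags_inconsistent_per_segment_offsets():
    rng = np.random.default_rng(7)
    old = _random_seq(rng, 200)
    feature = _feature(
        [
            ChangeSegment(30, 30, old[29], "A"),
            ChangeSegment(150, 150, old[149], "A"),
        ]
    )
    # insert residues between the two segments: offsets 0 and +4 disagree
    new = old[:90] + "GSGS" + old[90:]
    result = remap_feature(feature, old, new)
    assert result.status == "flagged"
    assert result.reason.startswith("inconsistent-offsets")


def _oracle_offsets(old, new, seg, context):
    """Brute force: every placement of the context window in the new sequence."""
    lo = max(0, seg.start - 1 - context)
    hi = min(len(old), seg.end + context)
    window = old[lo:hi]
    return [
        i - lo
        for i in range(len(new) - len(window) + 1)
        if new[i : i + len(window)] == window
    ]


@pytest.mark.parametrize("seed", range(8))
def test_remap_agrees_with_brute_force_oracle(seed):
    """On sequences <= 500 aa, context search equals exhaustive placement."""
    rng = np.random.default_rng(seed)
    length = int(rng.integers(60, 500))
    old = _random_seq(rng, length)
    pos = int(rng.integers(20, length - 20))
    feature = _feature([ChangeSegment(pos, pos, old[pos - 1], "A")])
    edit = seed % 4
    if edit == 0:
        new = old
    elif edit == 1:
        new = _random_seq(rng, int(rng.integers(1, 6))) + old
    elif edit == 2:
        cut = int(rng.integers(1, 15))
        new = old[cut:]
    else:
        new = old[: max(0, pos - 40)] + _random_seq(rng, 30) + old[pos + 40 :]
    result = remap_feature(feature, old, new)
    offsets = _oracle_offsets(old, new, feature.segments[0], context=10)
    if new == old:
        assert result.status == "unchanged"
    elif len(offsets) == 1:
        assert result.status == "shifted" and result.offset == offsets[0]
    else:
        assert result.status == "flagged"


def test_run_update_is_identity_when_proteomes_match(small_fixture):
    report = run_update(small_fixture.features, small_fixture.proteome,
                        small_fixture.proteome)
    assert report.counts == {
        "unchanged": len(small_fixture.features), "shifted": 0, "flagged": 0
    }
    assert report.updated_features == small_fixture.features


def test_run_update_recovers_injected_shifts_and_scrambles(small_fixture):
    fx = small_fixture
    report = run_update(fx.features, fx.proteome, fx.new_proteome)
    assert sum(report.counts.values()) == len(fx.features)
    for ac, expected in fx.truth.qc.items():
        result = report.results[ac]
        assert result.status == expected["status"]
        if expected["status"] == "shifted":
            assert result.offset == expected["offset"]
    flagged = {ac for ac, r in report.results.items() if r.status == "flagged"}
    updated_acs = {f.feature_ac for f in report.updated_features}
    assert flagged.isdisjoint(updated_acs)
    # soundness: every shifted feature re-validates against the new release
    for feature in report.updated_features:
        assert check_feature(feature, fx.new_proteome[feature.protein_ac]) == "valid"
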