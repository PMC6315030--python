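"""Variant-to-annotation matching: splitting, category rules, summaries,
and equivalence with a brute-force pair scan."""

import numpy as np
import pytest

from ppimut.core import (
    ChangeSegment,
    EffectCategory,
    MutationFeature,
    VariantRecord,
)
from ppimut.varmap import (
    VariantCatalogue,
    map_annotation,
    mapping_summary,
    split_to_point_changes,
)


def _feature(segments, protein="P1", ac="EBI-M1"):
    return MutationFeature(
        feature_ac=ac,
        label="p.Ala1Val",
        segments=tuple(segments),
        effect=EffectCategory("disrupting"),
        protein_ac=protein,
    )


def test_split_single_and_contiguous_substitutions():
    single = _feature([ChangeSegment(725, 725, "R", "E")])
    assert [tuple(p) for p in split_to_point_changes(single).points] == [
        ("P1", 725, "R", "E")
    ]
    contig = _feature([ChangeSegment(215, 216, "CS", "AA")])
    assert [tuple(p) for p in split_to_point_changes(contig).points] == [
        ("P1", 215, "C", "A"),
        ("P1", 216, "S", "A"),
    ]


def test_split_reports_indels_and_rejects_length_mismatch():
    indel = _feature([ChangeSegment(12, 13, "", "ST", flanking="AG")])
    result = split_to_point_changes(indel)
    assert result.points == [] and len(result.skipped) == 1
    with pytest.raises(ValueError, match="lengths differ"):
        split_to_point_changes(_feature([ChangeSegment(215, 216, "CS", "A")]))


def _catalogue(*records):
    return VariantCatalogue(records)


def test_map_annotation_category_rules():
    single = _feature([ChangeSegment(100, 100, "A", "V")])
    assert map_annotation(single, _catalogue()).category == "none"
    assert (
        map_annotation(single, _catalogue(VariantRecord("P1", 100, "A", "V"))).category
        == "full"
    )
    assert (
        map_annotation(single, _catalogue(VariantRecord("P1", 100, "A", "G"))).category
        == "positional"
    )
    two = _feature([ChangeSegment(100, 100, "A", "V"), ChangeSegment(200, 200, "S", "T")])
    call = map_annotation(two, _catalogue(VariantRecord("P1", 100, "A", "V")))
    assert call.category == "partial" and "position-subset" in call.detail
    call = map_annotation(
        two,
        _catalogue(VariantRecord("P1", 100, "A", "V"), VariantRecord("P1", 200, "S", "G")),
    )
    assert call.category == "partial" and "residue-mismatch" in call.detail
    call = map_annotation(
        two,
        _catalogue(VariantRecord("P1", 100, "A", "V"), VariantRecord("P1", 200, "S", "T")),
    )
    assert call.category == "full"


def test_reference_residue_disagreement_demotes_full_to_positional():
    single = _feature([ChangeSegment(100, 100, "A", "V")])
    call = map_annotation(single, _catalogue(VariantRecord("P1", 100, "C", "V")))
    assert call.category == "positional"
    assert "reference-residue-mismatch" in call.detail


def test_disease_flag_passes_through():
    single = _feature([ChangeSegment(100, 100, "A", "V")])
    call = map_annotation(
        single, _catalogue(VariantRecord("P1", 100, "A", "V", disease_linked=True))
    )
    assert call.disease_linked


def test_isoform_accessions_match_exactly():
    iso = _feature([ChangeSegment(100, 100, "A", "V")], protein="P1-2")
    assert map_annotation(iso, _catalogue(VariantRecord("P1", 100, "A", "V"))).category == "none"


def _brute_force_category(feature, variants):
    """Independent oracle: direct scan over all (variant, point) pairs."""
    split = split_to_point_changes(feature)
    points = split.points
    if not points:
        return "none"
    full = covered = 0
    for point in points:
        here = [
            v for v in variants
            if v.protein_ac == point.protein_ac and v.position == point.position
        ]
        if here:
            covered += 1
        if any(
            v.alternate == point.resulting
            and (not v.reference or v.reference == point.original)
            for v in here
        ):
            full += 1
    if covered == 0:
        return "none"
    if full == len(points) and not split.skipped:
        return "full"
    if len(points) == 1 and not split.skipped:
        return "positional"
    return "partial"


@pytest.mark.parametrize("seed", range(5))
def test_indexed_mapping_equals_brute_force_scan(seed):
    """Random instances up to 10^3 records agree with the pair-scan oracle."""
    rng = np.random.default_rng(seed)
    residues = list("ACDEFGHIKLMNPQRSTVWY")
    proteins = [f"P{i}" for i in range(8)]
    variants = []
    for _ in range(int(rng.integers(200, 1000))):
        ref, alt = rng.choice(residues, size=2, replace=False)
        variants.append(
            VariantRecord(
                str(rng.choice(proteins)), int(rng.integers(1, 60)),
                str(ref), str(alt),
            )
        )
    features = []
    for i in range(150):
        protein = str(rng.choice(proteins))
        n_pos = int(rng.integers(1, 3))
        positions = sorted(rng.choice(np.arange(1, 60), size=n_pos, replace=False))
        segments = []
        for pos in positions:
            orig, res = rng.choice(residues, size=2, replace=False)
            segments.append(ChangeSegment(int(pos), int(pos), str(orig), str(res)))
        features.append(_feature(segments, protein=protein, ac=f"EBI-R{i}"))
    catalogue = VariantCatalogue(variants)
    for feature in features:
        assert (
            map_annotation(feature, catalogue).category
            == _brute_force_category(feature, variants)
        )


def test_mapping_summary_recovers_injected_structure(small_fixture):
    fx = small_fixture
    features = [f for f in fx.features if f.feature_ac in fx.truth.mapping_annotation]
    summary = mapping_summary(features, VariantCatalogue(fx.variants))
    truth_ann = {}
    for category in fx.truth.mapping_annotation.values():
        truth_ann[category] = truth_ann.get(category, 0) + 1
    truth_chg = {}
    for category in fx.truth.mapping_change.values():
        truth_chg[category] = truth_chg.get(category, 0) + 1
    assert summary.annotation_counts == {
        k: truth_ann.get(k, 0) for k in ("full", "partial", "positional", "none")
    }
    assert summary.change_counts == {
        k: truth_chg.get(k, 0) for k in ("full", "partial", "positional", "none")
    }
    sc = fx.spec.variants
    assert summary.n_annotations == sc.n_annotations
    assert summary.n_changes == sc.n_changes
    assert summary.n_proteins == sc.n_proteins
    assert summary.pct_annotations_cumulative >= summary.pct_annotations_full
    assert summary.pct_changes_cumulative >= summary.pct_changes_full


def test_mirror_catalogue_gives_full_everywhere(small_fixture):
    fx = small_fixture
    features = [
        f for f in fx.features if f.feature_ac in fx.truth.mapping_annotation
    ]
    mirror = []
    seen = set()
    for feature in features:
        for point in split_to_point_changes(feature).points:
            key = (point.protein_ac, point.position, point.resulting)
            if key not in seen:
                seen.add(key)
                mirror.append(
                    VariantRecord(point.protein_ac, point.position,
                                  point.original, point.resulting)
                )
    summary = mapping_summary(features, VariantCatalogue(mirror))
    assert summary.pct_annotations_full == 100
    assert summary.pct_changes_full == 100


def test_summary_monotone_when_catalogue_grows(small_fixture):
    fx = small_fixture
    features = [
        f for f in fx.features if f.feature_ac in fx.truth.mapping_annotation
    ][:200]
    base = mapping_summary(features, VariantCatalogue(fx.variants[:20]))
    bigger = mapping_summary(features, VariantCatalogue(fx.variants))
    assert bigger.pct_annotations_full >= base.pct_annotations_full
    assert bigger.pct_annotations_cumulative >= base.pct_annotations_cumulative
    assert bigger.pct_changes_cumulative >= base.pct_changes_cumulative
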