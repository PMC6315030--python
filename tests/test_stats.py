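"""Descriptive statistics: effect shares, replacement matrices,
per-publication and per-organism summaries."""

import numpy as np
import pytest

from ppimut.core import ChangeSegment, EffectCategory, MutationFeature
from ppimut.stats import (
    EmptyDatasetError,
    effect_distribution,
    per_organism_summary,
    per_publication_counts,
    replacement_matrix,
)

# per-category annotation counts as printed for the published data set
PRINTED_COUNTS = {
    "disrupting": 10_976,
    "decreasing": 8_553,
    "increasing": 2_256,
    "causing": 188,
    "no_effect": 3_057,
    "undefined": 2_838,
}


def _feature(effect="disrupting", ac="EBI-1", publication="PMID:1",
             organism="9606", protein="P1", segments=None, interaction="I1"):
    return MutationFeature(
        feature_ac=ac,
        label="p.Ser10Ala",
        segments=tuple(segments or [ChangeSegment(10, 10, "S", "A")]),
        effect=EffectCategory(effect),
        protein_ac=protein,
        protein_organism=organism,
        publication=publication,
        interaction_id=interaction,
    )


def _printed_dataset():
    features = []
    i = 0
    for name, count in PRINTED_COUNTS.items():
        for _ in range(count):
            features.append(_feature(name, ac=f"EBI-{i}"))
            i += 1
    return features


def test_effect_distribution_reproduces_printed_shares():
    dist = effect_distribution(_printed_dataset())
    assert dist.total == 27_868
    assert dist.counts == PRINTED_COUNTS
    assert dist.percentages["decreasing"] == 30.7
    assert dist.percentages["increasing"] == 8.1
    assert dist.percentages["no_effect"] == 11.0
    assert dist.percentages["causing"] == 0.7
    assert dist.percentages["undefined"] == 10.2
    # half-up rounding computes 39.4 for the largest category (10976/27868);
    # this is a documented deviation from the printed 39.3
    assert dist.percentages["disrupting"] == 39.4
    assert sum(dist.percentages.values()) == pytest.approx(100, abs=0.1)


def test_effect_distribution_small_and_empty_inputs():
    dist = effect_distribution([_feature("disrupting"), _feature("no_effect")])
    assert dist.percentages["disrupting"] == 50.0
    assert dist.percentages["no_effect"] == 50.0
    with pytest.raises(EmptyDatasetError):
        effect_distribution([])


def test_replacement_matrix_counts_and_normalizations():
    result = replacement_matrix([_feature()])
    assert result.counts.at["S", "A"] == 1 and result.total == 1
    normalized = replacement_matrix([_feature()], normalize_by="original")
    assert normalized.normalized.at["S", "A"] == 1.0

    features = [
        _feature(segments=[ChangeSegment(5, 6, "RK", "AA")], ac="EBI-a"),
        _feature(segments=[ChangeSegment(9, 9, "R", "A")], ac="EBI-b"),
        _feature(segments=[ChangeSegment(3, 3, "R", "")], ac="EBI-c"),  # deletion
    ]
    result = replacement_matrix(features)
    assert result.counts.at["R", "A"] == 2
    assert result.counts.at["K", "A"] == 1
    assert result.total == 3 and result.n_indels == 1

    by_row = replacement_matrix(features, normalize_by="original")
    row_sums = by_row.normalized.sum(axis=1)
    assert row_sums.loc["R"] == pytest.approx(1.0, abs=1e-9)

    with pytest.raises(ValueError, match="unknown normalization"):
        replacement_matrix(features, normalize_by="bogus")


def test_effect_scope_equals_unnormalized_scaled_on_single_effect_dataset():
    features = [
        _feature(segments=[ChangeSegment(5, 5, "R", "A")], ac="EBI-a"),
        _feature(segments=[ChangeSegment(7, 7, "K", "G")], ac="EBI-b"),
        _feature(segments=[ChangeSegment(9, 9, "R", "A")], ac="EBI-c"),
    ]
    by_effect = replacement_matrix(features, normalize_by="effect").by_effect
    assert list(by_effect) == ["disrupting"]
    plain = replacement_matrix(features).counts
    assert np.allclose(by_effect["disrupting"].to_numpy(),
                       plain.to_numpy() / plain.to_numpy().sum())


def test_replacement_matrix_recovers_injected_counts(small_fixture):
    fx = small_fixture
    from ppimut.varmap import split_to_point_changes

    expected = {}
    for feature in fx.features:
        for point in split_to_point_changes(feature).points:
            key = (point.original, point.resulting)
            expected[key] = expected.get(key, 0) + 1
    result = replacement_matrix(fx.features)
    assert result.total == sum(expected.values())
    for (orig, res), count in expected.items():
        assert result.counts.at[orig, res] == count


def test_per_publication_threshold_shares():
    features = (
        [_feature(publication="PMID:a", ac=f"EBI-a{i}") for i in range(1)]
        + [_feature(publication="PMID:b", ac=f"EBI-b{i}") for i in range(2)]
        + [_feature(publication="PMID:c", ac=f"EBI-c{i}") for i in range(200)]
    )
    summary = per_publication_counts(features, threshold=100)
    assert summary.histogram == {"PMID:a": 1, "PMID:b": 2, "PMID:c": 200}
    assert summary.pct_publications_under == 66.7  # 2 of 3
    assert summary.pct_annotations_under == 1.5  # 3 of 203
    single = per_publication_counts([_feature()], threshold=100)
    assert single.pct_publications_under == 100.0
    empty = per_publication_counts([], threshold=100)
    assert empty.histogram == {} and empty.pct_publications_under == 0.0


def test_per_organism_summary_counts_and_distinct_totals(small_fixture):
    fx = small_fixture
    org_features = [f for f in fx.features if f.protein_ac.startswith("ORG")]
    table = per_organism_summary(org_features).set_index("organism")
    for taxid, expected in fx.truth.organism.items():
        row = table.loc[taxid]
        assert row["annotations"] == expected["annotations"]
        assert row["sequence_changes"] == expected["sequence_changes"]
        assert row["proteins"] == expected["proteins"]
        assert row["interactions"] == expected["interactions"]
        assert row["publications"] == expected["publications"]
    totals = table.loc["Totals"]
    assert totals["annotations"] == sum(
        e["annotations"] for e in fx.truth.organism.values()
    )


def test_totals_row_uses_distinct_union_not_row_sum():
    shared = [
        _feature(organism="9606", protein="SHARED", publication="PMID:x",
                 interaction="I-x", ac="EBI-h"),
        _feature(organism="10090", protein="SHARED", publication="PMID:x",
                 interaction="I-x", ac="EBI-m"),
    ]
    table = per_organism_summary(shared).set_index("organism")
    assert table.loc["Totals", "proteins"] == 1
    assert table.loc["Totals", "publications"] == 1
    assert table.loc["Totals", "annotations"] == 2


def test_one_feature_dataset_has_all_ones():
    table = per_organism_summary([_feature()]).set_index("organism")
    row = table.loc["9606"]
    assert (
        row["annotations"], row["sequence_changes"], row["proteins"],
        row["interactions"], row["publications"],
    ) == (1, 1, 1, 1, 1)


def test_summaries_invariant_under_row_order(small_fixture):
    features = list(small_fixture.features)
    reversed_features = list(reversed(features))
    a = effect_distribution(features)
    b = effect_distribution(reversed_features)
    assert a.counts == b.counts and a.percentages == b.percentages
    assert (
        replacement_matrix(features).counts.equals(
            replacement_matrix(reversed_features).counts
        )
    )
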