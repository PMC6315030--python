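"""Descriptive statistics over a mutations dataset.

The unit called "annotation" throughout is one :class:`MutationFeature`
(a multi-row, multi-segment feature counts once). Percentages are rounded
half-up — one decimal for effect shares, nearest integer for mapping
shares — through a single centralized helper, because published rounding
conventions are not always internally consistent and a deliberate,
documented choice beats an incidental one.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd

from .core import CATEGORY_NAMES, MutationFeature
from .varmap import split_to_point_changes

__all__ = [
    "EmptyDatasetError",
    "EffectDistribution",
    "ReplacementMatrix",
    "PublicationSummary",
    "effect_distribution",
    "replacement_matrix",
    "per_publication_counts",
    "per_organism_summary",
    "round_half_up",
]

STANDARD_RESIDUES = tuple("ACDEFGHIKLMNPQRSTVWY")


class EmptyDatasetError(ValueError):
    """Raised when a summary is requested over an empty dataset."""


def round_half_up(value, ndigits: int = 1) -> float:
    """Decimal half-up rounding (5 rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def _share(count: int, total: int, ndigits: int = 1) -> float:
    return float(
        (Decimal(100 * count) / Decimal(total)).quantize(
            Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP
        )
    )


@dataclass
class EffectDistribution:
    """Annotation counts and shares per effect category."""

    counts: dict[str, int]
    percentages: dict[str, float]
    total: int

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "total": self.total,
            "counts": dict(self.counts),
            "percentages": dict(self.percentages),
        }


def effect_distribution(features: Iterable[MutationFeature]) -> EffectDistribution:
    """Count annotations per effect category with half-up one-decimal shares.

    Raises :class:`EmptyDatasetError` on an empty dataset (there is no
    meaningful distribution to report).
    """
    counter = Counter(f.effect.name for f in features)
    total = sum(counter.values())
    if total == 0:
        raise EmptyDatasetError("no annotations: empty effect distribution")
    counts = {name: counter.get(name, 0) for name in CATEGORY_NAMES}
    percentages = {name: _share(c, total) for name, c in counts.items()}
    return EffectDistribution(counts, percentages, total)


@dataclass
class ReplacementMatrix:
    """Amino-acid replacement counts over split point substitutions.

    ``counts`` is a (original x resulting) integer DataFrame over the 20
    standard residues (rows/columns extended when non-standard codes
    occur). ``normalized`` divides by the scope total (matrix, row or
    column scope); with effect scope, ``by_effect`` holds one normalized
    matrix per effect category instead. ``n_indels`` counts the segments
    excluded because they are insertions or deletions.
    """

    counts: pd.DataFrame
    normalize_by: str = "none"
    normalized: pd.DataFrame | None = None
    by_effect: dict[str, pd.DataFrame] | None = None
    n_indels: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def _empty_matrix(extra: Iterable[str] = ()) -> pd.DataFrame:
    letters = list(STANDARD_RESIDUES) + sorted(set(extra) - set(STANDARD_RESIDUES))
    return pd.DataFrame(0, index=letters, columns=letters, dtype=int)


def _count_matrix(pairs: Iterable[tuple[str, str]]) -> pd.DataFrame:
    pairs = list(pairs)
    seen = {c for p in pairs for c in p}
    matrix = _empty_matrix(seen)
    for orig, res in pairs:
        matrix.at[orig, res] += 1
    return matrix


def replacement_matrix(
    features: Iterable[MutationFeature], normalize_by: str = "none"
) -> ReplacementMatrix:
    """Tally (original, resulting) residue pairs over point substitutions.

    ``normalize_by``: ``none`` (raw counts), ``original`` (each row sums
    to 1), ``resulting`` (each column sums to 1) or ``effect`` (one
    matrix per effect category, each normalized by that category's total).
    Indel segments are excluded and counted in ``n_indels``.
    """
    if normalize_by not in ("none", "original", "resulting", "effect"):
        raise ValueError(f"unknown normalization scope {normalize_by!r}")
    pairs: list[tuple[str, str]] = []
    pairs_by_effect: dict[str, list[tuple[str, str]]] = {}
    n_indels = 0
    for feature in features:
        split = split_to_point_changes(feature)
        n_indels += len(split.skipped)
        for point in split.points:
            pairs.append((point.original, point.resulting))
            pairs_by_effect.setdefault(feature.effect.name, []).append(
                (point.original, point.resulting)
            )
    counts = _count_matrix(pairs)
    result = ReplacementMatrix(counts, normalize_by, n_indels=n_indels)
    if normalize_by == "effect":
        result.by_effect = {}
        for name, effect_pairs in pairs_by_effect.items():
            m = _count_matrix(effect_pairs)
            result.by_effect[name] = m / len(effect_pairs)
        return result
    if normalize_by == "none":
        return result
    total = counts.sum(axis=1 if normalize_by == "original" else 0)
    normalized = counts.div(total.where(total != 0, 1),
                            axis=0 if normalize_by == "original" else 1)
    result.normalized = normalized.astype(float)
    return result


@dataclass
class PublicationSummary:
    """Annotations-per-publication histogram and under-threshold shares."""

    histogram: dict[str, int]
    threshold: int
    n_publications: int
    n_annotations: int
    n_publications_under: int
    n_annotations_under: int
    pct_publications_under: float
    pct_annotations_under: float

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "threshold": self.threshold,
            "n_publications": self.n_publications,
            "n_annotations": self.n_annotations,
            "n_publications_under": self.n_publications_under,
            "n_annotations_under": self.n_annotations_under,
            "pct_publications_under": self.pct_publications_under,
            "pct_annotations_under": self.pct_annotations_under,
            "histogram": dict(self.histogram),
        }


def per_publication_counts(
    features: Iterable[MutationFeature], threshold: int = 100
) -> PublicationSummary:
    """Histogram of annotations per publication and the share of
    publications (and of annotations) below ``threshold`` annotations.

    An empty dataset yields an empty histogram with zero shares.
    """
    histogram = Counter(f.publication for f in features)
    n_pub = len(histogram)
    n_ann = sum(histogram.values())
    under = {p: c for p, c in histogram.items() if c < threshold}
    n_pub_under = len(under)
    n_ann_under = sum(under.values())
    return PublicationSummary(
        histogram=dict(histogram),
        threshold=threshold,
        n_publications=n_pub,
        n_annotations=n_ann,
        n_publications_under=n_pub_under,
        n_annotations_under=n_ann_under,
        pct_publications_under=_share(n_pub_under, n_pub) if n_pub else 0.0,
        pct_annotations_under=_share(n_ann_under, n_ann) if n_ann else 0.0,
    )


def per_organism_summary(features: Iterable[MutationFeature]) -> pd.DataFrame:
    """Per-organism table: annotations, distinct sequence changes, distinct
    proteins, distinct interactions, distinct publications.

    The final ``Totals`` row counts distinct unions over all organisms (an
    identifier shared across organisms counts once), so totals can be
    smaller than the column sums.
    """
    rows: dict[str, dict[str, set | int]] = {}
    all_sets = {
        "sequence_changes": set(),
        "proteins": set(),
        "interactions": set(),
        "publications": set(),
    }
    n_total = 0
    for feature in features:
        org = feature.protein_organism or "unknown"
        entry = rows.setdefault(
            org,
            {
                "annotations": 0,
                "sequence_changes": set(),
                "proteins": set(),
                "interactions": set(),
                "publications": set(),
            },
        )
        entry["annotations"] += 1
        n_total += 1
        keys = {
            "sequence_changes": feature.change_key(),
            "proteins": feature.protein_ac,
            "interactions": feature.interaction_id,
            "publications": feature.publication,
        }
        for col, key in keys.items():
            entry[col].add(key)
            all_sets[col].add(key)

    records = []
    for org in sorted(rows, key=lambda o: -rows[o]["annotations"]):
        entry = rows[org]
        records.append(
            {
                "organism": org,
                "annotations": entry["annotations"],
                "sequence_changes": len(entry["sequence_changes"]),
                "proteins": len(entry["proteins"]),
                "interactions": len(entry["interactions"]),
                "publications": len(entry["publications"]),
            }
        )
    records.append(
        {
            "organism": "Totals",
            "annotations": n_total,
            **{col: len(values) for col, values in all_sets.items()},
        }
    )
    return pd.DataFrame.from_records(records)
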