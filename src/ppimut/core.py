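"""Core domain types for mutation annotations on molecular interactions.

Coordinates are 1-based and inclusive throughout the package (UniProt
feature convention). A *mutation feature* describes one engineered or
natural sequence change on an interaction participant, made of one or
more contiguous changed segments, together with the controlled-vocabulary
effect the change had on the interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "Direction",
    "EffectCategory",
    "EffectVocabulary",
    "DEFAULT_VOCABULARY",
    "VocabularyError",
    "ChangeSegment",
    "ParticipantRef",
    "MutationFeature",
    "ProteinRecord",
    "VariantRecord",
    "AffinityMeasurement",
    "effect_direction",
]

#: residues accepted in protein sequences: the 20 standard letters plus
#: selenocysteine (U), unknown (X) and the B/Z ambiguity codes.
SEQUENCE_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XUBZ")

#: the six effect categories used for reporting.
CATEGORY_NAMES = (
    "disrupting",
    "decreasing",
    "increasing",
    "causing",
    "no_effect",
    "undefined",
)

#: direction semantics of each category; total by construction.
CATEGORY_DIRECTIONS: Mapping[str, str] = {
    "disrupting": "negative",
    "decreasing": "negative",
    "increasing": "positive",
    "causing": "positive",
    "no_effect": "neutral",
    "undefined": "unknown",
}


class Direction:
    """Direction labels for effect categories (plain string constants)."""

    NEGATIVE = "negative"
    POSITIVE = "positive"
    NEUTRAL = "neutral"
    UNKNOWN = "unknown"


class VocabularyError(ValueError):
    """An effect term name or MI identifier outside the known vocabulary."""


@dataclass(frozen=True)
class EffectCategory:
    """A controlled-vocabulary effect term collapsed onto a reporting category.

    Parameters
    ----------
    name
        One of ``disrupting, decreasing, increasing, causing, no_effect,
        undefined``.
    mi_id
        The PSI-MI accession of the original term when known
        (e.g. ``"MI:0573"``); empty string otherwise.
    """

    name: str
    mi_id: str = ""

    def __post_init__(self) -> None:
        if self.name not in CATEGORY_DIRECTIONS:
            raise VocabularyError(
                f"unknown effect category {self.name!r}; expected one of "
                f"{sorted(CATEGORY_DIRECTIONS)}"
            )

    @property
    def direction(self) -> str:
        """Direction semantic: negative, positive, neutral or unknown."""
        return CATEGORY_DIRECTIONS[self.name]


def effect_direction(effect: EffectCategory) -> str:
    """Return the direction label of an effect category.

    Raises :class:`VocabularyError` for a category name outside the closed
    vocabulary (possible when an ``EffectCategory`` was built unsafely).
    """
    name = effect.name
    if name not in CATEGORY_DIRECTIONS:
        raise VocabularyError(f"unknown effect category {name!r}")
    return CATEGORY_DIRECTIONS[name]


class EffectVocabulary:
    """Mapping from PSI-MI mutation-branch terms to reporting categories.

    The packaged default covers the mutation branch of the PSI-MI controlled
    vocabulary, collapsing the rate/strength children onto their parent
    category (e.g. "mutation decreasing rate" -> decreasing). The map is
    user-extensible through :meth:`register`.
    """

    #: (mi_id, term name, category) triples for the packaged default.
    _DEFAULT_TERMS = (
        ("MI:0118", "mutation", "undefined"),
        ("MI:0119", "mutation decreasing interaction", "decreasing"),
        ("MI:1133", "mutation decreasing interaction strength", "decreasing"),
        ("MI:1130", "mutation decreasing interaction rate", "decreasing"),
        ("MI:0573", "mutation disrupting interaction", "disrupting"),
        ("MI:1128", "mutation disrupting interaction strength", "disrupting"),
        ("MI:1129", "mutation disrupting interaction rate", "disrupting"),
        ("MI:0382", "mutation increasing interaction", "increasing"),
        ("MI:1132", "mutation increasing interaction strength", "increasing"),
        ("MI:1131", "mutation increasing interaction rate", "increasing"),
        ("MI:2227", "mutation causing an interaction", "causing"),
        ("MI:2226", "mutation with no effect", "no_effect"),
    )

    # common short names appearing in flat-file "Feature type" cells
    _SHORT_NAMES = {
        "mutation": "undefined",
        "mutation decreasing": "decreasing",
        "mutation decreasing rate": "decreasing",
        "mutation decreasing strength": "decreasing",
        "mutation disrupting": "disrupting",
        "mutation disrupting rate": "disrupting",
        "mutation disrupting strength": "disrupting",
        "mutation increasing": "increasing",
        "mutation increasing rate": "increasing",
        "mutation increasing strength": "increasing",
        "mutation causing": "causing",
        "mutation causing an interaction": "causing",
        "mutation with no effect": "no_effect",
        "no effect": "no_effect",
    }

    def __init__(self) -> None:
        self._by_mi: dict[str, str] = {}
        self._by_name: dict[str, str] = {}
        self._term_by_mi: dict[str, str] = {}
        for mi_id, term, category in self._DEFAULT_TERMS:
            self.register(mi_id=mi_id, term_name=term, category=category)
            self._term_by_mi[mi_id] = term
        for term, category in self._SHORT_NAMES.items():
            self._by_name[term] = category
        for category in CATEGORY_NAMES:
            self._by_name[category] = category

    def register(self, *, term_name: str, category: str, mi_id: str = "") -> None:
        """Add (or override) a term -> category mapping."""
        if category not in CATEGORY_DIRECTIONS:
            raise VocabularyError(f"unknown target category {category!r}")
        if mi_id:
            self._by_mi[mi_id] = category
        self._by_name[term_name.strip().lower()] = category

    def resolve(self, term_name: str = "", mi_id: str = "") -> EffectCategory:
        """Resolve a term name and/or MI id into an :class:`EffectCategory`.

        The MI id takes precedence when both are given and known.
        """
        if mi_id and mi_id in self._by_mi:
            return EffectCategory(self._by_mi[mi_id], mi_id=mi_id)
        key = term_name.strip().lower()
        if key in self._by_name:
            return EffectCategory(self._by_name[key], mi_id=mi_id)
        raise VocabularyError(
            f"unknown effect term {term_name!r} (MI id {mi_id or 'absent'!r})"
        )

    def known(self, term_name: str = "", mi_id: str = "") -> bool:
        if mi_id and mi_id in self._by_mi:
            return True
        return term_name.strip().lower() in self._by_name

    def term_name(self, mi_id: str) -> str | None:
        """Canonical PSI-MI term name for an MI id, if packaged."""
        return self._term_by_mi.get(mi_id)


#: shared default vocabulary instance.
DEFAULT_VOCABULARY = EffectVocabulary()

#: representative MI accession per reporting category (the parent term).
REPRESENTATIVE_MI: Mapping[str, str] = {
    "disrupting": "MI:0573",
    "decreasing": "MI:0119",
    "increasing": "MI:0382",
    "causing": "MI:2227",
    "no_effect": "MI:2226",
    "undefined": "MI:0118",
}

#: display name per reporting category, used when writing the flat file for
#: a feature whose MI id is absent or outside the packaged vocabulary.
CATEGORY_DISPLAY: Mapping[str, str] = {
    "disrupting": "mutation disrupting",
    "decreasing": "mutation decreasing",
    "increasing": "mutation increasing",
    "causing": "mutation causing",
    "no_effect": "mutation with no effect",
    "undefined": "mutation",
}


@dataclass(frozen=True, order=True)
class ChangeSegment:
    """One contiguous changed section of protein sequence.

    ``start``/``end`` are 1-based inclusive positions. ``original`` is the
    wild-type residue string at those positions (empty for a pure
    insertion); ``resulting`` is the replacement (empty for a pure
    deletion). ``flanking`` holds the two residues bracketing a pure
    insertion (so insertion labels can be re-emitted); empty otherwise.
    """

    start: int
    end: int
    original: str
    resulting: str
    flanking: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")
        if self.original and len(self.original) != self.end - self.start + 1:
            raise ValueError(
                f"original {self.original!r} has length {len(self.original)} "
                f"but range {self.start}-{self.end} spans "
                f"{self.end - self.start + 1} residues"
            )
        if not self.original and not self.resulting:
            raise ValueError("segment with empty original and resulting")

    @property
    def kind(self) -> str:
        """``substitution``, ``insertion`` or ``deletion``."""
        if not self.original:
            return "insertion"
        if not self.resulting:
            return "deletion"
        return "substitution"

    @property
    def positions(self) -> range:
        """The affected 1-based positions (inclusive)."""
        return range(self.start, self.end + 1)


@dataclass(frozen=True, order=True)
class ParticipantRef:
    """Reference to an interaction participant, proteoform-sensitive.

    Two refs compare equal only when both the accession and the proteoform
    tag (isoform/PTM state, e.g. ``"phosphorylated"``) agree — a
    phosphorylated protein is a different partner from its unmodified form.
    """

    protein_ac: str
    proteoform_tag: str = ""


@dataclass
class MutationFeature:
    """One annotated sequence-change feature on an interaction participant."""

    feature_ac: str
    label: str
    segments: tuple[ChangeSegment, ...]
    effect: EffectCategory
    protein_ac: str
    protein_organism: str = ""
    protein_symbol: str = ""
    annotations: str = ""
    interaction_id: str = ""
    partners: tuple[ParticipantRef, ...] = ()
    publication: str = ""
    source_db: str = ""
    detection_method: str = ""
    #: set only when a flat file carried an effect term outside the
    #: vocabulary; preserved verbatim so writing is faithful and the
    #: validator can flag it.
    unknown_effect_term: str = ""

    def __post_init__(self) -> None:
        self.segments = tuple(self.segments)
        self.partners = tuple(self.partners)
        if not self.segments:
            raise ValueError(f"feature {self.feature_ac}: no segments")

    @property
    def sorted_segments(self) -> tuple[ChangeSegment, ...]:
        return tuple(sorted(self.segments, key=lambda s: (s.start, s.end)))

    def change_key(self) -> tuple:
        """(protein, ordered segment tuple) identifying the sequence change."""
        return (
            self.protein_ac,
            tuple((s.start, s.end, s.original, s.resulting) for s in self.sorted_segments),
        )


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence under a given release."""

    accession: str
    sequence: str
    version_tag: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"{self.accession}: residues outside the one-letter alphabet: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        return self.sequence[position - 1]


@dataclass(frozen=True)
class VariantRecord:
    """A catalogue variant at one protein position."""

    protein_ac: str
    position: int
    reference: str
    alternate: str
    disease_linked: bool = False
    external_id: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.reference == self.alternate:
            raise ValueError(
                f"{self.protein_ac}:{self.position} reference equals alternate "
                f"({self.reference!r})"
            )


@dataclass(frozen=True)
class AffinityMeasurement:
    """Wild-type and mutant equilibrium dissociation constants (molar)."""

    kd_wild_type: float
    kd_mutant: float

    def __post_init__(self) -> None:
        if not (self.kd_wild_type > 0 and self.kd_mutant > 0):
            raise ValueError("KD values must be strictly positive")
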