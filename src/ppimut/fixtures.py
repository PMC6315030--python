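"""Seeded synthetic fixtures with retrievable ground truth.

Every pipeline stage in this package can be exercised offline: the
generator emits a proteome (FASTA), a mutations table, a variant
catalogue, phosphosite and interface tables, and — for the update
pipeline — a second proteome release with injected shifts and scrambles.
Each injected scenario records its ground truth per feature/group so the
analysis modules can be checked for exact recovery.

Scenario counts are realized *exactly* (a consistency scenario asking for
19 antagonistic groups produces exactly 19), which is what makes worked
examples with printed counts reproducible. Background sequences are drawn
uniformly over the 20-residue alphabet; annotation multiplicities per
sequence change follow a truncated-geometric weighting adjusted to hit
exact totals, mirroring the observation that most changes are tested only
once. Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from . import hgvs
from .classifiers import (
    PHOSPHO_ACCEPTORS,
    PHOSPHO_DISRUPTING_TARGETS,
    PHOSPHO_MIMETIC_TARGETS,
    InterfaceRegion,
)
from .core import (
    REPRESENTATIVE_MI,
    ChangeSegment,
    EffectCategory,
    MutationFeature,
    ParticipantRef,
    ProteinRecord,
)
from .tsvio import write_fasta, write_mutations_table
from .varmap import write_variant_table
from .core import VariantRecord

__all__ = [
    "FeasibilityError",
    "ConsistencyScenario",
    "VariantScenario",
    "PhosphoScenario",
    "InterfaceScenario",
    "OrganismComposition",
    "QCScenario",
    "FixtureSpec",
    "GroundTruth",
    "Fixture",
    "generate",
    "corrupt",
    "DEFAULT_EFFECT_COUNTS",
]

_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: per-category annotation counts of the published data set (the default
#: dataset composition the plain effect fixture emulates).
DEFAULT_EFFECT_COUNTS: Mapping[str, int] = {
    "disrupting": 10_976,
    "decreasing": 8_553,
    "increasing": 2_256,
    "causing": 188,
    "no_effect": 3_057,
    "undefined": 2_838,
}

_NEGATIVE = ("disrupting", "decreasing")
_POSITIVE = ("increasing", "causing")


class FeasibilityError(ValueError):
    """The requested scenario counts are mutually infeasible."""


@dataclass
class ConsistencyScenario:
    """Multiply-tested evidence groups with injected agreement classes.

    ``n_multi_groups`` groups get 2+ evidences each; ``n_conflict`` of
    them mix antagonistic directions, ``n_mild`` mix one direction with
    no-effect, the rest agree in direction. ``n_single_groups`` extra
    once-tested changes can be added.
    """

    n_multi_groups: int = 200
    n_mild: int = 4
    n_conflict: int = 2
    n_single_groups: int = 0
    members_min: int = 2
    members_max: int = 3

    def validate(self) -> None:
        if self.n_mild + self.n_conflict > self.n_multi_groups:
            raise FeasibilityError(
                "n_mild + n_conflict exceeds n_multi_groups "
                f"({self.n_mild}+{self.n_conflict} > {self.n_multi_groups})"
            )
        if self.members_min < 2 or self.members_max < self.members_min:
            raise FeasibilityError("need members_max >= members_min >= 2")


@dataclass
class VariantScenario:
    """Annotation/catalogue overlap with injected match structure.

    ``n_full_*`` annotations/changes are fully matched (every position,
    identical alternate residue); ``n_pos_partial_*`` are matched
    positionally (single-position change, different alternate) or
    partially (two-position change, one position matched); the remainder
    stay unmatched.
    """

    n_annotations: int = 500
    n_changes: int = 250
    n_proteins: int = 60
    n_full_annotations: int = 140
    n_full_changes: int = 30
    n_pos_partial_annotations: int = 80
    n_pos_partial_changes: int = 40
    disease_fraction: float = 0.2

    def validate(self) -> None:
        n_none_changes = self.n_changes - self.n_full_changes - self.n_pos_partial_changes
        n_none_ann = (
            self.n_annotations
            - self.n_full_annotations
            - self.n_pos_partial_annotations
        )
        checks = [
            (self.n_proteins >= 1, "need at least one protein"),
            (self.n_changes >= self.n_proteins,
             "n_changes must cover every protein (>= n_proteins)"),
            (n_none_changes >= 0, "full + pos/partial changes exceed n_changes"),
            (n_none_ann >= 0, "full + pos/partial annotations exceed n_annotations"),
            (self.n_full_annotations >= self.n_full_changes,
             "n_full_annotations not distributable over n_full_changes (>=1 each)"),
            (self.n_pos_partial_annotations >= self.n_pos_partial_changes,
             "n_pos_partial_annotations not distributable over n_pos_partial_changes"),
            (n_none_ann >= n_none_changes,
             "unmatched annotations not distributable over unmatched changes"),
            ((self.n_full_changes == 0) <= (self.n_full_annotations == 0),
             "full annotations require full changes"),
            ((self.n_pos_partial_changes == 0)
             <= (self.n_pos_partial_annotations == 0),
             "pos/partial annotations require pos/partial changes"),
        ]
        for ok, message in checks:
            if not ok:
                raise FeasibilityError(message)


@dataclass
class PhosphoScenario:
    """Point substitutions with injected phosphosite-relative classes."""

    n_disrupting: int = 20
    n_mimetic: int = 10
    n_other_at_site: int = 5
    n_not_applicable: int = 15
    n_decoy_sites: int = 5


@dataclass
class InterfaceScenario:
    """Features with injected interface membership per region source."""

    n_inside_curated: int = 15
    n_inside_predicted: int = 15
    n_outside: int = 20


@dataclass
class OrganismComposition:
    """Exact per-organism identifier counts (Table-2-style row)."""

    taxid: str
    n_annotations: int
    n_changes: int
    n_proteins: int
    n_interactions: int
    n_publications: int

    def validate(self) -> None:
        ok = (
            1 <= self.n_proteins <= self.n_changes <= self.n_annotations
            and 1 <= self.n_interactions <= self.n_annotations
            and 1 <= self.n_publications <= self.n_annotations
        )
        if not ok:
            raise FeasibilityError(
                f"organism {self.taxid}: need proteins <= changes <= "
                "annotations and interactions/publications <= annotations"
            )


@dataclass
class QCScenario:
    """Second proteome release with injected coordinate shifts/scrambles."""

    n_unchanged: int = 10
    n_shifted: int = 5
    n_flagged: int = 3
    shift_offset: int = 2
    context: int = 10

    def validate(self) -> None:
        if self.shift_offset < 1:
            raise FeasibilityError("shift_offset must be >= 1")


@dataclass
class FixtureSpec:
    """Seeded generation parameters; every scenario is optional."""

    seed: int = 0
    protein_length: tuple[int, int] = (250, 400)
    taxid: str = "9606"
    effect_counts: dict[str, int] | None = None
    consistency: ConsistencyScenario | None = None
    variants: VariantScenario | None = None
    phospho: PhosphoScenario | None = None
    interface: InterfaceScenario | None = None
    organisms: list[OrganismComposition] | None = None
    qc: QCScenario | None = None

    def validate(self) -> None:
        lo, hi = self.protein_length
        if not (30 <= lo <= hi):
            raise FeasibilityError("protein_length must satisfy 30 <= lo <= hi")
        if self.effect_counts:
            unknown = set(self.effect_counts) - set(REPRESENTATIVE_MI)
            if unknown:
                raise FeasibilityError(f"unknown effect categories {sorted(unknown)}")
            if any(v < 0 for v in self.effect_counts.values()):
                raise FeasibilityError("negative effect count")
        for scenario in (self.consistency, self.variants, self.qc):
            if scenario is not None:
                scenario.validate()
        for org in self.organisms or []:
            org.validate()

    @classmethod
    def from_dict(cls, data: Mapping) -> "FixtureSpec":
        data = dict(data)
        converters = {
            "consistency": ConsistencyScenario,
            "variants": VariantScenario,
            "phospho": PhosphoScenario,
            "interface": InterfaceScenario,
            "qc": QCScenario,
        }
        for key, converter in converters.items():
            if data.get(key) is not None and not isinstance(data[key], converter):
                data[key] = converter(**data[key])
        if data.get("organisms"):
            data["organisms"] = [
                o if isinstance(o, OrganismComposition) else OrganismComposition(**o)
                for o in data["organisms"]
            ]
        if "protein_length" in data:
            data["protein_length"] = tuple(data["protein_length"])
        return cls(**data)


@dataclass
class GroundTruth:
    """Per-record labels of every injected property."""

    effect: dict[str, str] = field(default_factory=dict)
    consistency: dict[str, str] = field(default_factory=dict)
    consistency_members: dict[str, list[str]] = field(default_factory=dict)
    mapping_annotation: dict[str, str] = field(default_factory=dict)
    mapping_change: dict[str, str] = field(default_factory=dict)
    phospho: dict[str, str] = field(default_factory=dict)
    interface: dict[str, dict[str, str]] = field(default_factory=dict)
    qc: dict[str, dict] = field(default_factory=dict)
    organism: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Fixture:
    """Generated data bundle plus its ground truth."""

    spec: FixtureSpec
    proteome: dict[str, ProteinRecord]
    features: list[MutationFeature]
    variants: list[VariantRecord]
    phosphosites: list[tuple[str, int, str]]
    interfaces: list[InterfaceRegion]
    new_proteome: dict[str, ProteinRecord] | None
    truth: GroundTruth

    @property
    def phosphosite_set(self) -> set[tuple[str, int]]:
        return {(ac, pos) for ac, pos, _ in self.phosphosites}

    def write(self, outdir) -> dict[str, str]:
        """Write all tables under ``outdir``; returns name -> path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        paths["proteome"] = str(outdir / "proteome.fasta")
        write_fasta(self.proteome, paths["proteome"])
        paths["mutations"] = str(outdir / "mutations.tsv")
        write_mutations_table(self.features, paths["mutations"])
        paths["variants"] = str(outdir / "variants.tsv")
        write_variant_table(self.variants, paths["variants"])

        paths["phosphosites"] = str(outdir / "phosphosites.tsv")
        with open(paths["phosphosites"], "w", encoding="utf-8") as handle:
            handle.write("protein_ac\tposition\tresidue\n")
            for ac, pos, residue in sorted(self.phosphosites):
                handle.write(f"{ac}\t{pos}\t{residue}\n")

        paths["interfaces"] = str(outdir / "interfaces.tsv")
        with open(paths["interfaces"], "w", encoding="utf-8") as handle:
            handle.write("protein_ac\tstart\tend\tsource\n")
            for region in sorted(self.interfaces, key=lambda r: (r.protein_ac, r.start)):
                handle.write(
                    f"{region.protein_ac}\t{region.start}\t{region.end}\t{region.source}\n"
                )

        if self.new_proteome is not None:
            paths["new_proteome"] = str(outdir / "proteome_new.fasta")
            write_fasta(self.new_proteome, paths["new_proteome"])

        paths["truth"] = str(outdir / "ground_truth.json")
        with open(paths["truth"], "w", encoding="utf-8") as handle:
            json.dump(self.truth.to_dict(), handle, indent=1, sort_keys=True)
            handle.write("\n")
        return paths


class _SequencePool:
    """Registers proteins and pins residues; realizes sequences at the end."""

    def __init__(self, rng: np.random.Generator, length_range: tuple[int, int]):
        self.rng = rng
        self.length_range = length_range
        self.lengths: dict[str, int] = {}
        self.taxids: dict[str, str] = {}
        self.pins: dict[str, dict[int, str]] = {}
        self.used: dict[str, set[int]] = {}
        self._counters: dict[str, int] = {}

    def new_protein(self, prefix: str, taxid: str, length: int | None = None) -> str:
        n = self._counters.get(prefix, 0) + 1
        self._counters[prefix] = n
        ac = f"{prefix}{n:05d}"
        lo, hi = self.length_range
        self.lengths[ac] = int(length if length is not None else self.rng.integers(lo, hi + 1))
        self.taxids[ac] = taxid
        self.pins[ac] = {}
        self.used[ac] = set()
        return ac

    def draw_residue(self, exclude: str = "") -> str:
        pool = [r for r in _RESIDUES if r not in exclude]
        return str(self.rng.choice(pool))

    def pin(self, ac: str, pos: int, residue: str | None = None) -> str:
        pins = self.pins[ac]
        if pos in pins:
            if residue is not None and pins[pos] != residue:
                raise FeasibilityError(
                    f"{ac} position {pos} already pinned to {pins[pos]}"
                )
            return pins[pos]
        pins[pos] = residue if residue is not None else self.draw_residue()
        return pins[pos]

    def free_position(self, ac: str, lo: int = 2, hi: int | None = None,
                      run: int = 1) -> int:
        """Reserve ``run`` consecutive unused positions; returns the first."""
        hi = hi if hi is not None else self.lengths[ac] - 1
        hi = min(hi, self.lengths[ac] - run)
        used = self.used[ac]
        for _ in range(10_000):
            pos = int(self.rng.integers(lo, hi + 1))
            span = range(pos, pos + run)
            if all(p not in used for p in span):
                used.update(span)
                return pos
        raise FeasibilityError(f"{ac}: no free run of {run} positions left")

    def realize(self) -> dict[str, ProteinRecord]:
        proteome = {}
        for ac in self.lengths:
            length = self.lengths[ac]
            seq = self.rng.choice(_RESIDUES, size=length)
            for pos, residue in self.pins[ac].items():
                seq[pos - 1] = residue
            proteome[ac] = ProteinRecord(ac, "".join(seq))
        return proteome


class _FeatureFactory:
    def __init__(self, pool: _SequencePool, rng: np.random.Generator):
        self.pool = pool
        self.rng = rng
        self.n = 0

    def _next_ac(self) -> str:
        self.n += 1
        return f"EBI-S{self.n:07d}"

    def substitution(
        self,
        protein_ac: str,
        positions: Iterable[int],
        effect_name: str,
        partners: tuple[ParticipantRef, ...],
        publication: str,
        interaction_id: str,
        resulting: dict[int, str] | None = None,
        originals: dict[int, str] | None = None,
        source_db: str = "synthdb",
        detection_method: str = "two hybrid(MI:0018)",
    ) -> MutationFeature:
        segments = []
        for pos in sorted(positions):
            orig = self.pool.pin(
                protein_ac, pos, (originals or {}).get(pos)
            )
            res = (resulting or {}).get(pos) or self.pool.draw_residue(exclude=orig)
            segments.append(ChangeSegment(pos, pos, orig, res))
        segments = tuple(segments)
        return MutationFeature(
            feature_ac=self._next_ac(),
            label=hgvs.format_label(segments),
            segments=segments,
            effect=EffectCategory(effect_name, REPRESENTATIVE_MI[effect_name]),
            protein_ac=protein_ac,
            protein_organism=self.pool.taxids[protein_ac],
            protein_symbol=protein_ac.replace("-", "_"),
            partners=partners,
            publication=publication,
            interaction_id=interaction_id,
            source_db=source_db,
            detection_method=detection_method,
        )


def _allocate_extras(
    rng: np.random.Generator, n_items: int, n_extras: int
) -> np.ndarray:
    """Distribute ``n_extras`` over ``n_items`` with geometric weights.

    Returns per-item extra counts (base multiplicity 1 is added by the
    caller); exact total guaranteed.
    """
    if n_items == 0:
        return np.zeros(0, dtype=int)
    if n_extras == 0:
        return np.zeros(n_items, dtype=int)
    weights = rng.geometric(0.5, size=n_items).astype(float)
    return rng.multinomial(n_extras, weights / weights.sum())


def _gen_effect(spec, pool, factory, truth, features):
    counts = spec.effect_counts
    total = sum(counts.values())
    if total == 0:
        return
    # keep per-protein position load well under the shortest sequence
    n_proteins = max(1, total // 100)
    acs = [pool.new_protein("EFF-P", spec.taxid) for _ in range(n_proteins)]
    n_pubs = max(1, total // 40)
    i = 0
    for name in sorted(counts):
        for _ in range(counts[name]):
            ac = acs[i % n_proteins]
            pos = pool.free_position(ac)
            feature = factory.substitution(
                ac,
                [pos],
                name,
                partners=(ParticipantRef(f"EFF-PART{i % 97:03d}"),),
                publication=f"PMID:9{i % n_pubs:06d}",
                interaction_id=f"EBI-I{i:07d}",
            )
            features.append(feature)
            truth.effect[feature.feature_ac] = name
            i += 1


def _member_count(rng, sc) -> int:
    return int(rng.integers(sc.members_min, sc.members_max + 1))


def _gen_consistency(sc, taxid, pool, factory, truth, features, rng):
    n_groups = sc.n_multi_groups + sc.n_single_groups
    classes = (
        ["conflict"] * sc.n_conflict
        + ["mild_conflict"] * sc.n_mild
        + ["consistent"] * (sc.n_multi_groups - sc.n_conflict - sc.n_mild)
        + ["single"] * sc.n_single_groups
    )
    acs = [
        pool.new_protein("CON-P", taxid)
        for _ in range(max(1, n_groups // 40))
    ]
    for g, klass in enumerate(classes):
        protein = acs[g % len(acs)]
        pos = pool.free_position(protein)
        partners = (ParticipantRef(f"CON-PART{g:05d}"),)
        orig = pool.pin(protein, pos)
        res = pool.draw_residue(exclude=orig)
        if klass == "single":
            effect_names = [str(rng.choice(_NEGATIVE))]
        elif klass == "conflict":
            n = _member_count(rng, sc)
            effect_names = [str(rng.choice(_NEGATIVE)), str(rng.choice(_POSITIVE))]
            extra_pool = _NEGATIVE + _POSITIVE + ("no_effect",)
            effect_names += [str(rng.choice(extra_pool)) for _ in range(n - 2)]
        elif klass == "mild_conflict":
            n = _member_count(rng, sc)
            direction = _NEGATIVE if rng.random() < 0.8 else _POSITIVE
            n_neutral = int(rng.integers(1, n))
            effect_names = [str(rng.choice(direction)) for _ in range(n - n_neutral)]
            effect_names += ["no_effect"] * n_neutral
        else:  # consistent, same direction (categories may mix)
            n = _member_count(rng, sc)
            direction = _NEGATIVE if rng.random() < 0.8 else _POSITIVE
            effect_names = [str(rng.choice(direction)) for _ in range(n)]
        group_id = f"CG{g:06d}"
        member_acs = []
        for m, name in enumerate(effect_names):
            feature = factory.substitution(
                protein,
                [pos],
                name,
                partners=partners,
                publication=f"PMID:8{g % 500:04d}{m}",
                interaction_id=f"EBI-C{g:06d}{m}",
                resulting={pos: res},
            )
            features.append(feature)
            member_acs.append(feature.feature_ac)
        truth.consistency[group_id] = klass
        truth.consistency_members[group_id] = member_acs


def _change_id(protein_ac: str, positions: list[int]) -> str:
    return protein_ac + ":" + ",".join(map(str, positions))


def _gen_variants(sc, taxid, pool, factory, truth, features, variants, rng):
    acs = [pool.new_protein("VAR-P", taxid) for _ in range(sc.n_proteins)]
    n_none_changes = sc.n_changes - sc.n_full_changes - sc.n_pos_partial_changes
    # change -> protein: every protein covered, remainder random
    owners = [acs[i % len(acs)] for i in range(sc.n_changes)]
    categories = (
        ["full"] * sc.n_full_changes
        + ["pos_partial"] * sc.n_pos_partial_changes
        + ["none"] * n_none_changes
    )
    per_bucket_extras = {
        "full": _allocate_extras(
            rng, sc.n_full_changes, sc.n_full_annotations - sc.n_full_changes
        ),
        "pos_partial": _allocate_extras(
            rng,
            sc.n_pos_partial_changes,
            sc.n_pos_partial_annotations - sc.n_pos_partial_changes,
        ),
        "none": _allocate_extras(
            rng,
            n_none_changes,
            (sc.n_annotations - sc.n_full_annotations - sc.n_pos_partial_annotations)
            - n_none_changes,
        ),
    }
    bucket_index = {"full": 0, "pos_partial": 0, "none": 0}
    effect_pool = _NEGATIVE + _POSITIVE + ("no_effect", "undefined")
    for c, (protein, bucket) in enumerate(zip(owners, categories)):
        idx = bucket_index[bucket]
        bucket_index[bucket] += 1
        sub_positional = bucket == "pos_partial" and idx % 2 == 0
        if bucket == "pos_partial" and not sub_positional:
            positions = sorted(
                [pool.free_position(protein), pool.free_position(protein)]
            )
        else:
            positions = [pool.free_position(protein)]
        originals = {p: pool.pin(protein, p) for p in positions}
        resulting = {
            p: pool.draw_residue(exclude=originals[p]) for p in positions
        }
        if bucket == "full":
            category = "full"
            for p in positions:
                variants.append(
                    VariantRecord(
                        protein, p, originals[p], resulting[p],
                        disease_linked=bool(rng.random() < sc.disease_fraction),
                        external_id=f"rs9{c:06d}",
                        source="synthetic-catalogue",
                    )
                )
        elif bucket == "pos_partial" and sub_positional:
            category = "positional"
            p = positions[0]
            other = pool.draw_residue(exclude=originals[p] + resulting[p])
            variants.append(
                VariantRecord(
                    protein, p, originals[p], other,
                    disease_linked=bool(rng.random() < sc.disease_fraction),
                    external_id=f"rs8{c:06d}",
                    source="synthetic-catalogue",
                )
            )
        elif bucket == "pos_partial":
            category = "partial"
            p = positions[0]  # only the first position is matched
            variants.append(
                VariantRecord(
                    protein, p, originals[p], resulting[p],
                    disease_linked=bool(rng.random() < sc.disease_fraction),
                    external_id=f"rs7{c:06d}",
                    source="synthetic-catalogue",
                )
            )
        else:
            category = "none"
        n_annotations = 1 + int(per_bucket_extras[bucket][idx])
        truth.mapping_change[_change_id(protein, positions)] = category
        for a in range(n_annotations):
            feature = factory.substitution(
                protein,
                positions,
                str(rng.choice(effect_pool)),
                partners=(ParticipantRef(f"VAR-PART{c % 211:03d}"),),
                publication=f"PMID:7{c % 800:04d}{a % 3}",
                interaction_id=f"EBI-V{c:06d}{a}",
                resulting=resulting,
                originals=originals,
            )
            features.append(feature)
            truth.mapping_annotation[feature.feature_ac] = category


def _gen_phospho(sc, taxid, pool, factory, truth, features, sites, rng):
    n_total = sc.n_disrupting + sc.n_mimetic + sc.n_other_at_site + sc.n_not_applicable
    acs = [pool.new_protein("PHO-P", taxid) for _ in range(max(1, n_total // 50))]
    other_targets = [
        r for r in _RESIDUES
        if r not in PHOSPHO_DISRUPTING_TARGETS | PHOSPHO_MIMETIC_TARGETS
    ]
    plan = (
        [("phospho_disrupting", True)] * sc.n_disrupting
        + [("phospho_mimetic", True)] * sc.n_mimetic
        + [("other_at_phosphosite", True)] * sc.n_other_at_site
        + [("not_applicable", False)] * sc.n_not_applicable
    )
    for i, (klass, at_site) in enumerate(plan):
        ac = acs[i % len(acs)]
        pos = pool.free_position(ac)
        if klass == "not_applicable" and i % 2 == 0:
            # a phosphorylatable residue at a position with no annotated site
            orig = str(rng.choice(sorted(PHOSPHO_ACCEPTORS)))
            res = pool.draw_residue(exclude=orig)
        elif klass == "not_applicable":
            orig = pool.draw_residue(exclude="STY")
            res = pool.draw_residue(exclude=orig)
        else:
            orig = str(rng.choice(sorted(PHOSPHO_ACCEPTORS)))
            if klass == "phospho_disrupting":
                res = str(rng.choice(sorted(PHOSPHO_DISRUPTING_TARGETS)))
            elif klass == "phospho_mimetic":
                res = str(rng.choice(sorted(PHOSPHO_MIMETIC_TARGETS)))
            else:
                res = str(rng.choice([r for r in other_targets if r != orig]))
        pool.pin(ac, pos, orig)
        if at_site:
            sites.append((ac, pos, orig))
        feature = factory.substitution(
            ac,
            [pos],
            "decreasing",
            partners=(ParticipantRef(f"PHO-PART{i % 37:02d}"),),
            publication=f"PMID:6{i % 300:04d}",
            interaction_id=f"EBI-PH{i:05d}",
            resulting={pos: res},
            originals={pos: orig},
        )
        features.append(feature)
        truth.phospho[feature.feature_ac] = klass
    for d in range(sc.n_decoy_sites):
        ac = acs[d % len(acs)]
        pos = pool.free_position(ac)
        residue = str(rng.choice(sorted(PHOSPHO_ACCEPTORS)))
        pool.pin(ac, pos, residue)
        sites.append((ac, pos, residue))


def _gen_interface(sc, taxid, pool, factory, truth, features, regions, rng):
    n_total = sc.n_inside_curated + sc.n_inside_predicted + sc.n_outside
    acs = []
    for _ in range(max(1, n_total // 40)):
        ac = pool.new_protein("IFC-P", taxid, length=320)
        acs.append(ac)
        regions.append(InterfaceRegion(ac, 40, 110, "curated"))
        regions.append(InterfaceRegion(ac, 180, 240, "predicted"))
    plan = (
        [("inside", "outside")] * sc.n_inside_curated
        + [("outside", "inside")] * sc.n_inside_predicted
        + [("outside", "outside")] * sc.n_outside
    )
    windows = {
        ("inside", "outside"): (40, 110),
        ("outside", "inside"): (180, 240),
        ("outside", "outside"): (120, 175),
    }
    for i, membership in enumerate(plan):
        ac = acs[i % len(acs)]
        lo, hi = windows[membership]
        pos = pool.free_position(ac, lo=lo, hi=hi)
        feature = factory.substitution(
            ac,
            [pos],
            "disrupting",
            partners=(ParticipantRef(f"IFC-PART{i % 29:02d}"),),
            publication=f"PMID:5{i % 200:04d}",
            interaction_id=f"EBI-IF{i:05d}",
        )
        features.append(feature)
        truth.interface[feature.feature_ac] = {
            "curated": membership[0],
            "predicted": membership[1],
        }


def _gen_organisms(compositions, pool, factory, truth, features, rng):
    effect_pool = _NEGATIVE + _POSITIVE + ("no_effect", "undefined")
    for org in compositions:
        acs = [pool.new_protein(f"ORG{org.taxid}-P", org.taxid)
               for _ in range(org.n_proteins)]
        owners = [acs[i % len(acs)] for i in range(org.n_changes)]
        extras = _allocate_extras(
            rng, org.n_changes, org.n_annotations - org.n_changes
        )
        interactions = [f"EBI-O{org.taxid}-{i:05d}" for i in range(org.n_interactions)]
        publications = [f"PMID:4{org.taxid}{p:04d}" for p in range(org.n_publications)]
        a = 0
        for c, protein in enumerate(owners):
            pos = pool.free_position(protein)
            res = None
            for _ in range(1 + int(extras[c])):
                # cycle identifiers so the first pass covers them all exactly
                interaction = interactions[a % len(interactions)] if a < len(
                    interactions
                ) else str(rng.choice(interactions))
                publication = publications[a % len(publications)] if a < len(
                    publications
                ) else str(rng.choice(publications))
                orig = pool.pin(protein, pos)
                if res is None:
                    res = pool.draw_residue(exclude=orig)
                feature = factory.substitution(
                    protein,
                    [pos],
                    str(rng.choice(effect_pool)),
                    partners=(ParticipantRef(f"ORG{org.taxid}-PART0"),),
                    publication=publication,
                    interaction_id=interaction,
                    resulting={pos: res},
                )
                features.append(feature)
                a += 1
        truth.organism[org.taxid] = {
            "annotations": org.n_annotations,
            "sequence_changes": org.n_changes,
            "proteins": org.n_proteins,
            "interactions": org.n_interactions,
            "publications": org.n_publications,
        }


def _gen_qc_features(sc, taxid, pool, factory, truth, features, rng):
    """Create one feature per QC protein; returns plan for the new release."""
    plan = []
    statuses = (
        ["unchanged"] * sc.n_unchanged
        + ["shifted"] * sc.n_shifted
        + ["flagged"] * sc.n_flagged
    )
    for status in statuses:
        ac = pool.new_protein("QC-P", taxid)
        margin = sc.context + sc.shift_offset + 5
        pos = pool.free_position(ac, lo=margin, hi=pool.lengths[ac] - margin)
        feature = factory.substitution(
            ac,
            [pos],
            "disrupting",
            partners=(ParticipantRef("QC-PART00"),),
            publication="PMID:300000",
            interaction_id=f"EBI-Q{len(plan):05d}",
        )
        features.append(feature)
        plan.append((feature.feature_ac, ac, pos, status))
    return plan


def _build_new_proteome(plan, sc, proteome, truth, rng):
    new_proteome = dict(proteome)
    for feature_ac, ac, pos, status in plan:
        old = proteome[ac].sequence
        lo = max(0, pos - 1 - sc.context)
        hi = min(len(old), pos + sc.context)
        window = old[lo:hi]
        if status == "unchanged":
            truth.qc[feature_ac] = {"status": "unchanged", "offset": 0}
            continue
        if status == "shifted":
            prefix = "".join(str(rng.choice(_RESIDUES)) for _ in range(sc.shift_offset))
            new_seq = prefix + old
            if new_seq.count(window) != 1:
                raise FeasibilityError(
                    f"{ac}: context window not unique after shift injection"
                )
            new_proteome[ac] = ProteinRecord(ac, new_seq, version_tag="new")
            truth.qc[feature_ac] = {"status": "shifted", "offset": sc.shift_offset}
            continue
        # flagged: scramble the feature's context region in the new release
        for _ in range(20):
            scramble = "".join(
                str(rng.choice(_RESIDUES)) for _ in range(hi - lo)
            )
            new_seq = old[:lo] + scramble + old[hi:]
            if window not in new_seq:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise FeasibilityError(f"{ac}: could not remove context window")
        new_proteome[ac] = ProteinRecord(ac, new_seq, version_tag="new")
        truth.qc[feature_ac] = {"status": "flagged", "offset": None}
    return new_proteome


def generate(spec: FixtureSpec) -> Fixture:
    """Generate a fixture bundle per ``spec``; deterministic under the seed.

    Raises :class:`FeasibilityError` when the requested counts are
    mutually infeasible, naming the violated constraint.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pool = _SequencePool(rng, spec.protein_length)
    factory = _FeatureFactory(pool, rng)
    truth = GroundTruth()
    features: list[MutationFeature] = []
    variants: list[VariantRecord] = []
    sites: list[tuple[str, int, str]] = []
    regions: list[InterfaceRegion] = []

    if spec.effect_counts:
        _gen_effect(spec, pool, factory, truth, features)
    if spec.consistency:
        _gen_consistency(spec.consistency, spec.taxid, pool, factory, truth,
                         features, rng)
    if spec.variants:
        _gen_variants(spec.variants, spec.taxid, pool, factory, truth,
                      features, variants, rng)
    if spec.phospho:
        _gen_phospho(spec.phospho, spec.taxid, pool, factory, truth, features,
                     sites, rng)
    if spec.interface:
        _gen_interface(spec.interface, spec.taxid, pool, factory, truth,
                       features, regions, rng)
    if spec.organisms:
        _gen_organisms(spec.organisms, pool, factory, truth, features, rng)
    qc_plan = []
    if spec.qc:
        qc_plan = _gen_qc_features(spec.qc, spec.taxid, pool, factory, truth,
                                   features, rng)

    proteome = pool.realize()
    new_proteome = None
    if spec.qc:
        new_proteome = _build_new_proteome(qc_plan, spec.qc, proteome, truth, rng)

    for feature in features:
        truth.effect.setdefault(feature.feature_ac, feature.effect.name)

    return Fixture(
        spec=spec,
        proteome=proteome,
        features=features,
        variants=variants,
        phosphosites=sites,
        interfaces=regions,
        new_proteome=new_proteome,
        truth=truth,
    )


CORRUPTION_MODES = ("label-typo", "off-by-one", "residue-mismatch")


def corrupt(
    features: Iterable[MutationFeature],
    modes: Iterable[str],
    rate: float,
    seed: int,
) -> tuple[list[MutationFeature], list[tuple[str, str]]]:
    """Inject typographical corruption into a copy of the features.

    ``modes`` is a subset of ``label-typo`` (label disagrees with the
    stored columns), ``off-by-one`` (range shifted by one) and
    ``residue-mismatch`` (stored original residue altered). Each feature
    is corrupted with probability ``rate``; the corruption log lists
    (feature_ac, mode) pairs, and :func:`ppimut.tsvio.validate_dataset`
    flags every logged feature. ``rate=0`` is the identity.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    modes = sorted(set(modes))
    unknown = set(modes) - set(CORRUPTION_MODES)
    if unknown:
        raise ValueError(f"unknown corruption mode(s): {sorted(unknown)}")
    if not modes:
        raise ValueError("no corruption modes given")
    rng = np.random.default_rng(seed)
    out: list[MutationFeature] = []
    log: list[tuple[str, str]] = []
    residues = list("ACDEFGHIKLMNPQRSTVWY")
    for feature in features:
        feature = copy.deepcopy(feature)
        if rate > 0 and rng.random() < rate:
            mode = str(rng.choice(modes))
            seg = feature.segments[0]
            if mode == "label-typo":
                wrong = str(rng.choice([r for r in residues if r != seg.resulting[:1] and r != seg.original[:1]]))
                typo_seg = ChangeSegment(
                    seg.start, seg.end, seg.original, wrong * len(seg.resulting)
                )
                feature.label = hgvs.format_label(
                    (typo_seg,) + feature.segments[1:]
                )
            elif mode == "off-by-one":
                shifted = ChangeSegment(
                    seg.start + 1, seg.end + 1, seg.original, seg.resulting
                )
                feature.segments = (shifted,) + feature.segments[1:]
            else:  # residue-mismatch
                wrong = str(rng.choice([r for r in residues if r != seg.original[:1]]))
                bad = ChangeSegment(
                    seg.start, seg.end, wrong * len(seg.original), seg.resulting
                )
                feature.segments = (bad,) + feature.segments[1:]
            log.append((feature.feature_ac, mode))
        out.append(feature)
    return out, log
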