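# Methods notes

This note records the procedures the package implements, the defaults it
chooses where the conventions of the field leave room, and what its
synthetic fixtures do and do not demonstrate.

## Data model

A *mutation feature* is one annotated sequence change on an interaction
participant: an ordered list of contiguous changed segments (1-based,
inclusive coordinates on the UniProtKB sequence; `original` residues,
`resulting` residues), an effect term, and provenance (protein accession
with isoform suffix kept verbatim, organism, interaction evidence id,
partner list, publication, source database, detection method). In the
flat file each segment is one row; rows of one feature share the feature
accession and short label.

The effect vocabulary collapses the PSI-MI mutation branch onto six
reporting categories — disrupting, decreasing, increasing, causing,
no_effect, undefined — because those are the categories at which such
datasets are summarized; the rate/strength child terms (e.g. `mutation
decreasing rate (MI:1130)`) fold onto their parents. The packaged map
covers MI:0118/0119/0382/0573/1128–1133/2226/2227 and is user-extensible
(`EffectVocabulary.register`), since live datasets may carry additional
children. Each category has exactly one direction: negative (disrupting,
decreasing), positive (increasing, causing), neutral (no_effect), unknown
(undefined).

Partner identity is proteoform-sensitive: `(accession, proteoform tag)`
pairs, so a phosphorylated partner never equals its unmodified form.

## Label grammar

The supported HGVS-protein subset is the one the flat files actually use:
single substitutions, contiguous multi-residue substitutions
(underscore + range form), discontiguous multi-variants (bracketed,
semicolon-separated), single-residue deletions (`p.Xaa123del`) and simple
insertions (`p.Xaa123_Yaa124insSeq`). Substitutions dominate such
datasets by two orders of magnitude, so frameshifts, extensions,
duplications and multi-residue deletions are out of grammar and rejected
explicitly. Residue names use the three-letter↔one-letter tables from
Biopython (selenocysteine and ambiguity codes included); unknown names
are errors, never silently skipped.

Strict parsing raises with a character offset. Lenient parsing repairs
exactly three legacy defects — stray whitespace, lowercase residue names,
en-dash in ranges — and reports anything else as warnings on a
best-effort result; it never raises, and its warning list is non-empty
precisely when strict parsing would have failed. Insertion segments keep
their two flanking residues (an extension field on the segment) so labels
round-trip without access to the protein sequence.

A label/column concordance check compares label-derived segments with the
stored range/original/resulting columns and reports disagreements as
issues; known upstream conflicts (a label naming Asn where the original
column stores D) are flagged, never silently resolved in either
direction.

## Flat-file dialect

Dialect `ppimut-mutations-tsv/1`: 15 named, tab-separated columns
(feature_ac, feature_label, feature_range, original_seq, resulting_seq,
feature_type, feature_annotation, protein_ac, protein_symbol,
protein_taxid, interaction_id, partner_acs, detection_method, pubmed_id,
source_db), UTF-8, ASCII hyphen in ranges on write (en-dash tolerated on
read), `-` for an empty original/resulting. This is a documented dialect
of the published table structure, versioned so a later reconciliation
with the full production column set is possible; it does not claim
byte-compatibility with any particular FTP snapshot. The header is
matched by name, so reordered columns read fine. Reading merges rows by
feature accession and refuses to merge rows whose shared metadata
disagrees (listing the row numbers); writing emits one row per segment,
so rows written = total segments. Write∘read and read∘write are
identities on valid inputs, modulo whitespace normalization.

Validation is issue-based, never exception-based: per feature it checks
range against sequence length, stored original residues against the
sequence, label/column concordance, and vocabulary membership of the
effect term; features on absent proteins get a warning, not an error.

## Coordinate QC across releases

When the referenced sequence changes, each segment's original residues
plus a flanking context window are searched verbatim in the new sequence.
Defaults and policies:

* **Context flank: 10 residues** each side, truncated at termini,
  configurable. No published window size exists for this step; 10 gives
  a ≥ 21-residue probe, long enough that a chance repeat in a proteome is
  negligible while staying robust to edits more than 10 residues away.
* **Unique hit or flag.** Zero hits, multiple hits, or per-segment
  offsets that disagree (internal rearrangement) flag the feature for
  curator review; the updater never guesses. Flag reasons form a small
  fixed taxonomy (`no-match`, `ambiguous-match`, `inconsistent-offsets`,
  `protein-missing-old`, `protein-removed`, `invalid-feature`) — the
  production systems this emulates do not publish a flag taxonomy, so
  this one is the package's own, documented here.
* Multi-segment features must agree on a single common offset.
* Shifted features re-validate by construction (the hit is an exact
  match); the updater also regenerates their short labels. Flagged
  features are excluded from the updated table, mirroring the practice of
  leaving unfixable records out of a release until revisited.

An update run over identical proteomes is the identity. For sequences up
to a few hundred residues the context search is provably equivalent to
exhaustive enumeration of all placements of the window (tested against a
brute-force oracle).

## Evidence consistency

Grouping key: (protein accession, segment tuple sorted by start, partner
multiset with proteoform tags). Classification over the directions
present, with these resolutions where the verbal definitions leave gaps:

* Undefined-direction effects never vote; a group whose evidence is all
  undefined is excluded from the multiply-tested denominator (there is no
  stated effect to compare).
* A group that mixes both antagonistic directions *and* no-effect
  evidence is a conflict: antagonism dominates.
* All-no-effect groups are consistent.
* "Most in one direction plus no-effect" is implemented as: all
  directional members share one sign; a 50/50 split between one direction
  and neutral still qualifies as mild conflict.

The report states its grouping key so that either the per-group or the
per-(group, method) counting convention can be reproduced downstream;
this package counts groups.

## Variant mapping

Multi-position changes are split into point substitutions before
matching. Tiers: full (every position covered with identical alternate),
positional (single-position change, position covered, different
alternate), partial (multi-position change with any coverage short of
full — both the "some positions" and the "some residue changes" cases,
distinguished in a `detail` flag), none. Single-position features are
never partial; multi-position features are never positional. A catalogue
variant whose stated reference residue contradicts the feature's original
residue cannot support a full match (demoted to positional, noted in
`detail`) — a defensive-curation stance. Disease linkage is a
pass-through boolean from the catalogue. Accession strings match exactly;
an isoform-suffixed annotation is not matched against canonical-sequence
variants, and this choice is deliberate (silently collapsing isoforms
can map a change onto the wrong sequence frame).

Summaries report full and cumulative (full+partial+positional) counts at
two granularities — per annotation and per distinct (protein, segment
tuple) sequence change — with percentages rounded half-up to the nearest
integer.

## Effect rules

* Phosphosite classes are a pure function of (original, resulting,
  site membership): S/T/Y→A/G/V/F disrupting, S/T/Y→E/D mimetic, other
  replacements of S/T/Y at a site `other_at_phosphosite`, everything else
  `not_applicable`. Sites come from an explicit table (accession,
  position, residue), never inferred from sequence.
* Affinity calls use r = KD(mutant)/KD(wild type) with defaults
  (r > 1.5 → loss, r < 0.5 → gain, else no effect). The underlying
  "fold changes over and under 50%" phrasing admits more than one
  reading (e.g. a symmetric |Δ| > 50% on a normalized scale); the
  asymmetric ratio pair is this package's documented default, and both
  thresholds and the orientation are configuration, not assertion.
* Interface membership is inclusive-boundary interval containment per
  region source class (predicted vs curated); a multi-position change is
  inside if any position is.

## Rounding

Percentages are rounded half-up (one decimal for effect and consistency
shares, nearest integer for mapping shares) through one centralized
helper. Published tables are not always reproducible under any single
rounding convention — the effect-share table this design emulates prints
one category (10,976/27,868) as 39.3 where half-up computes 39.4, while
its other five shares match half-up exactly — so the package documents
half-up, reproduces the five matching shares, and treats the remaining
one as a known deviation rather than special-casing it.

## Synthetic fixtures

The generator emulates the *record structure* of a curated mutations
dataset — multi-row multi-position features, per-publication and
per-organism groupings, repeated evidence for one change, catalogue
overlap tiers, phosphosite and interface overlap, release-to-release
sequence changes — with exact injected counts and per-record ground
truth. Design choices:

* Background sequences are uniform over the 20 standard residues;
  mutated positions are pinned so the stated original residues always
  match the emitted FASTA (a freshly generated bundle validates with zero
  errors). Residue-frequency realism is irrelevant to rule-based
  pipelines and is deliberately not modelled.
* Annotation multiplicities per sequence change are drawn with truncated
  geometric weights and adjusted to exact totals, reflecting that most
  changes are tested once while a few are tested many times.
* Default protein lengths 250–400 residues; the default effect-fixture
  composition is the published per-category annotation counts
  (27,868 annotations across six categories), generated in ~2 s.
* Shift injection prepends a short random segment (default offset +2);
  scramble injection rewrites the feature's context region. Both verify
  their own detectability at generation time and fail fast otherwise.
* Infeasible scenario specs (e.g. more full-matched changes than
  full-matched annotations) raise a feasibility error naming the violated
  constraint before anything is generated.

The corruption operator injects label typos, off-by-one ranges and
residue mismatches at a given rate with its own seed and returns a log;
the dataset validator flags exactly the logged features (tested as a set
equality).

What passing on these fixtures shows: the rules, parsers, and summaries
are implemented exactly and recover injected structure at published
scale. What it does not show: robustness to the messiness of real
third-party files (inconsistent column dialects, mixed encodings,
non-standard effect terms beyond the packaged vocabulary), realistic
amino-acid or disease co-annotation statistics, or literature-bias
structure. Real-data claims require the real flat file, which this
package can read but does not ship.

## Problem sizes

The test suite and the acceptance script run at the published scales
where printed counts exist — 7,212 evidence groups (~17k features) and
16,765 annotations over 8,820 changes in 1,990 proteins — each generated
and analysed in a few seconds; property tests use hundreds of randomized
instances with sequences ≤ 500 residues and catalogues ≤ 10³ records,
sizes at which brute-force oracles are exact and fast.

## Known limitations

* No DNA/RNA-level HGVS, no frameshift/extension/duplication notation.
* No alignment-based remapping: a sequence edit inside the context window
  flags the feature rather than re-aligning it (curator-safety bias).
* No PSI-MI XML/MITAB parsing; the flat-file dialect is the interface.
* Significance testing, structure-based interface prediction, allele
  frequencies and disease-ontology rollups are out of scope; the package
  emits the groupings and contingency counts such analyses would consume.
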