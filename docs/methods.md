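# Methods

## Overview

`dockmine` implements a text-mining protocol for protein–protein docking:
retrieve abstracts about an interactor pair, extract residue mentions,
keep the mentions that correspond to surface residues of the target
structure, optionally filter abstracts with a bag-of-words SVM, and use
the surviving residues as weighted constraints to rescore rigid-body
docking matches.  This note records the model choices, parameters,
numerical details and limitations.

## Query construction

Names are URL-encoded with the RFC 3986 reserved set (space → `%20`).  For
every hyphen in a name the full cartesian product of {keep, remove,
replace-by-space} is generated and deduplicated; superset generation is
deliberate — extra variants can only add recall, and the canonical
six-variant example is always contained in the output.  Names shorter than
3 symbols are unusable (empty output is the signal, not an error); names of
exactly 3 symbols are AND-combined with the keyword "protein".  Cleaved
proteins follow three scenarios keyed on exact matching of the
structure-entry name (equality of case-folded, whitespace-collapsed
strings — an edit-distance-0 criterion): match to the recommended name
takes all chain names; match to exactly one chain name takes that chain;
otherwise the recommended plus the structure-entry name.  Generic-word
names (e.g. "act") are AND-combined with a configurable MeSH-term
disjunction; no MeSH vocabulary is hard-coded.  Gene names, organism
names, E.C. numbers and CD-antigen tags are excluded by design.

## Corpus handling

The canonical offline format is a documented fixture JSON (array of
objects: `pmid`, `title`, `body`, `pub_date` ISO date or null,
`retrieved_by` tags, optional `svm_label`); MEDLINE/PubMed
`PubmedArticleSet` XML is supported read-only.  Retrieval tags are `AND`,
`OR-1`, `OR-2`; a record tagged `AND` mentions both proteins and therefore
always carries both OR tags (enforced at construction).  An abstract
matching both OR halves keeps both tags.  Date filtering is at day
resolution; a record with an unknown date fails any active window
(conservative — it cannot be shown to precede the structure paper).
Filtering is order-preserving and idempotent.  The live E-utilities
adapter is disabled by default and raises an explicit "offline" error
rather than returning a silently empty corpus; no test or script requires
the network.

## Mention extraction

Residue numbers are a non-zero digit followed by any digits (no leading
zeros, no zero).  Three-letter codes match in exactly three case styles
(`Ala`, `ala`, `ALA`) with separators none / single space / hyphen, or the
number parenthesized without interior spaces; full names match in Title
and lower case (with both `Aspartate`/`Aspartic acid` and
`Glutamate`/`Glutamic acid` spellings).  Word boundaries are required on
both sides of every match so accession-embedded tokens (`XGLY2003`) never
fire.  Mutation shorthands — one-letter `S4A` and three-letter `Ser4Ala` /
`Ser-4Ala` — are only active when the text contains one of the mutagenesis
keywords (mutation, mutagenesis, mutagen, mutant, substitution) as a whole
word, and they emit both the original and the substituted residue.
One-letter mentions outside mutation context are excluded: deciding
whether "T4" names a residue requires sentence-level parsing, which is out
of scope.  Mentions are deduplicated per abstract by (residue, number).

## Surface, interface, and the identification filter

SASA is computed by Shrake–Rupley sphere sampling: probe radius 1.4 Å,
960 quasi-uniform points per atom (golden-spiral lattice), element vdW
radii C 1.70 / N 1.55 / O 1.52 / S 1.80 Å (default 1.70).  Relative
exposure divides per-residue SASA by the theoretical maximum ASA of the
residue type (Tien et al. 2013 table); residues at ≥ 25 % are surface.
The surface of each interactor is computed on that interactor in
isolation (its unbound state) — computing it on the assembled complex
would bury exactly the residues the method is looking for.  Interface
residues are defined independently on the bound complex: any heavy atom
within 6 Å (inclusive) of any heavy atom of the partner.  The two sets
are deliberately uncoupled: a residue can be interface yet buried.

Identification: a mention survives iff residue name and number match a
surface residue — against both interactors for AND-retrieved corpora,
against only the mentioned interactor (its OR tag) for OR corpora.
Insertion-coded residues never match a plain-integer mention.  When
reference-sequence numbering differs from the structure's, a global
alignment maps positions; mapping refuses below 90 % identity over
aligned columns (configurable).  Structures are read from PDB ATOM
records (first model; hydrogens, waters and heteroatoms dropped;
highest-occupancy alternate location kept).

## Abstract labelling and the SVM filter

With `n_int` interface and `n_non` non-interface identified residues, an
abstract is positive when `n_int − n_non > 4` or (`n_non = 0` and
`n_int > 0`), negative when `n_non − n_int > 4` or (`n_non > 0` and
`n_int = 0`), otherwise unused; abstracts with no residues at all are
unused.  The labelled pool is split per class 80/20 (floor) into training
and validation, seeded and deterministic.

Tokens are lower-cased words; a standard English stop-word list ships with
the package (configurable), and callers supply protein and amino-acid
names as extra stop terms since those words were part of the queries.
Stemming is the Porter (1980) algorithm implemented in-package, preceded
by a configurable prefix map that collapses spelling families Porter
separates (`inclu-` for include/inclusion, `muta-` for
mutant/mutation/mutagenesis/…).  Feature vectors are raw per-abstract stem
counts (token-wise); per-class normalized counts are means over training
abstracts.  Feature selection keeps stems with `|f_pos − f_neg| > 0.02`
and `f_pos + f_neg > 0.2`, ranked by the contrast δ(m) descending (ties
alphabetical); truncating to the largest-|δ| stems yields the automated
feature-set family.  Six manually curated stem sets (60 → 10 stems) and
the 143-stem automated set ship as packaged data.

The classifier is a support-vector machine (scikit-learn SVC) with linear,
polynomial `(α x·y + c)^d` (defaults α = 1, c = 0; d = 1 is the linear
case) or RBF `exp(−γ|x−y|²)` kernels; the signed decision value is the
score, and scores within a margin (default half-width 0.05; 0 disables)
leave the abstract unclassified and excluded from metric evaluation.
Precision, recall and accuracy are the usual ratios; the Matthews
correlation uses the standard signed numerator `TP·TN − FP·FN`.  A metric
with a zero denominator is reported as undefined (None), never as 0.

## Evaluation

Per complex, `P_TM` is the fraction of interface residues among all
identified residues, summed over abstracts; undefined when nothing was
identified.  Dataset metrics count complexes: coverage = L_tot/n,
success = L_int/n, accuracy = L_int/L_tot, printed to one decimal,
half-up.  Histograms of `P_TM` are normalized by the number of complexes
with a defined value.  The change in `P_TM` after SVM filtering is
reported per complex, flagging separately the case where the filter
removed every abstract.

## Constraints and rescoring

Residue confidence is `f(R) = min(10, Σ aᵢ)` over distinct abstracts,
`aᵢ = 2` for AND-retrieved, 1 for OR-only.  The cap balances low- against
high-confidence constraints and damps over-represented residues; raw AND
counts are kept alongside the capped value because the top-5 selection
prefers more AND contributions among residues tied at the cut, with
remaining ties removed at random under a seed.  Reference constraints are
the top three cross-interface residue pairs by ascending Cα–Cα distance
(exact ties broken lexicographically by chain id then residue number),
each residue at the maximal confidence 10.

Matches are rigid transforms of the unbound ligand.  A match's score is
the summed confidence of constraint residues at the *model's* interface,
operationalized with the same 6 Å heavy-atom rule used for real
interfaces; the match list is re-sorted by score descending with a stable
sort, so equal scores (including the no-constraints case, all zeros)
preserve scan order.  i-RMSD is the Cα RMSD over the bound-reference
ligand-interface residues between the docked unbound ligand and the
unbound ligand superimposed on the bound complex (two least-squares
fits: bound receptor → unbound receptor carries the reference into the
docking frame); residues missing from the unbound ligand are skipped and
the matched count reported.  Success criteria: strict — some model with
i-RMSD ≤ 5 Å in the top 10; relaxed — ≤ 8 Å in the top 100 (bounds
inclusive).

## Synthetic fixtures

The corpus generator emulates the class structure of the labelled
abstract pool: positive abstracts draw inflected words whose stems are
PPI-relevant (binding, interface, contact, …), negative abstracts draw
clinical/genetics vocabulary (patients, polymorphism, expression, …),
with a separation parameter (default 1.0 = fully disjoint profiles,
word budget ~12 profile words per abstract from Poisson draws) and ~30 %
of abstracts tagged AND.  Residue mentions are planted in the exact
surface forms of the extraction grammar, with the mutagenesis keyword
planted alongside mutation shorthands; the ground-truth table records
every expected (residue, number) pair.  The toy complex is a pair of
rectangular grid "proteins" (5×3×2 receptor, 3×2×2 ligand residues,
5 Å spacing, 5 atoms per residue) with the ligand 4 Å above the receptor
face, giving a designed contact patch; unbound structures are rigid
random rotations/translations with 0.05 Å coordinate jitter; the pose
list holds one near-native match (fit of the unbound ligand onto its
bound position) and 20–30 decoys displaced 30–60 Å.  Everything is
deterministic under the spec seed.

What the fixtures do *not* emulate: real English prose and its ambiguity
(templated sentences only), realistic protein geometry and packing,
corpus-scale class imbalance, and the noise structure of real retrieval.
Passing tests therefore demonstrate correctness of the mechanics —
grammar recall, geometric filters, arithmetic, ranking — not the
corpus-dependent performance figures of a live literature run, which are
out of scope here.

## Problem sizes and determinism

The test suite and the acceptance script run on toy structures of ~40
residues and corpora of ~100–240 abstracts; these sizes make every oracle
comparison (grid-sampling SASA, all-pairs interface scan, direct RMSD)
exact and fast while exercising identical code paths to larger inputs.
All randomness (splits, tie-breaking, fixtures) flows from explicit seeds;
derived seeds stay below 2³¹.

## Known limitations

* One-letter residue mentions outside mutation context are not mined.
* Mixed-case residue tokens (`aLa5`) do not match, by design.
* The SASA reference areas and sampling density are configuration, not
  dogma; any consistent SASA with the 25 % relative threshold preserves
  the method.
* mmCIF input, NMR multi-model handling, and the rigid-body docking scan
  itself (match generation) are out of scope; pose lists come from
  upstream tools or the fixture generator.
* Re-deriving the published 143-stem automated feature list requires the
  original corpus; the packaged copy is reference data.
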