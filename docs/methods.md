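# Methods

This note records the models, conventions and design choices behind
`contamsort`, in the order the pipeline runs.

## Composite databases

A `SequenceDatabase` is an ordered, accession-unique list of protein
records, each tagged with a species (`human`, `bovine`, `utility`) and the
source database it came from. Composites are built by concatenation
without deduplication, so entry counts are exactly additive and the
provenance list records every part. Accession collisions across merged
parts (impossible for disjoint UniProt species sets, possible for user
data) are resolved by default by suffixing the source label onto the later
accession; a strict mode raises instead. FASTA is written with
60-character wrapping and `accession description` headers; UniProt
`db|ACC|NAME` headers are recognised on input, with the accession taken
from the middle field. Sequences must be uppercase over the 20 standard
residues; B/J/X/Z/U are tolerated with a warning and terminal `*` stop
characters are stripped, reflecting what real UniProt releases contain.

The packaged 20-entry utility database (proteases added during sample
preparation and enolase mass standards) contains synthetic placeholder
sequences — the categories matter for the pipeline (utility matches must
be censused separately, never as human or bovine identifications), not the
exact sequences, which vary by laboratory.

## Digestion and the peptide index

Tryptic digestion cleaves C-terminal to K or R, suppressed when the next
residue is proline; the suppression is configurable because some search
engines use the unsuppressed rule. Only fully-tryptic peptides are
generated (both termini enzymatic or protein ends), with up to
`max_missed_cleavages` internal cleavable bonds (default 2, matching the
usual search setting) and length within 6–50 residues by default — the
observable range for an ion-trap instrument; bounds of (1, ∞) recover the
exhaustive digest. The implementation is checked in the test suite against
a brute-force oracle that enumerates every substring with valid tryptic
termini, and against an independent digestion implementation (pyteomics)
under the same rule.

The `PeptideIndex` maps each peptide sequence to the set of
`(accession, species)` parents across all digested databases. A peptide is
*shared* (orthologous) when its parents span human and bovine; since CID
fragmentation cannot distinguish isoleucine from leucine, an optional
`equate_il` flag folds I onto L before indexing so specificity conclusions
can be checked under both conventions (off by default: sequence databases
distinguish the residues, and most search engines report them as written).
Modifications are ignored for indexing — species specificity is a property
of the bare sequence.

## PSM filtering

A PSM is retained iff `q <= 0.01`, its XCorr reaches the charge-dependent
threshold (+1: 1.5, +2: 2, +3: 2.25, +4: 2.5, +5: 2.75, +6: 3, +7: 3.2,
above +7: 3.4) and it is the top-ranked match for its spectrum. q and PEP
are compared without epsilon slack. Protein-level criteria apply after
grouping: at least one unique peptide and a protein score of at least 10.
When the input table carries no vendor protein score, the sum of the
group's retained PSM XCorr values is used as a documented proxy; the two
are not asserted equivalent.

## Protein grouping

Grouping is parsimonious: proteins with identical observed-peptide sets
merge into one group, and the reported groups form a minimum-cardinality
set cover of the observed peptides. The cover is found exactly per
connected component of the peptide–protein graph (components up to 14
candidate groups, which covers realistic instances after merging; larger
components fall back to greedy selection). Ties between equally small
covers are broken by the lexicographically smallest tuple of leader
accessions; a group's leader is its lexicographically smallest member.
Each peptide is then assigned to exactly one selected group — the one with
the most peptide evidence, ties again lexicographic — so PSM counts
partition cleanly.

## Target-decoy q-values

For synthetic end-to-end runs (production searches bring their own
q-values) q is estimated by decoy counting on XCorr:
`FDR(t) = #decoys(score >= t) / #targets(score >= t)`, and a PSM's q-value
is the minimum FDR over thresholds at or below its score, which makes q
monotone non-increasing in score. Ties in score are processed as one
block; with zero targets above a threshold the ratio uses a denominator of
one; FDR is capped at 1. Absent decoys are an error, not a silent default.

## Cross-database comparison

Two searches of the same spectra are joined on `(spectrum file, scan)` —
charge is excluded from the key so a re-search that calls a different
charge still joins. When several PSMs share a spectrum after filtering
(e.g. different charge states) the lowest-PEP one represents the spectrum;
two PSMs with identical (file, scan, charge) are an error. The comparison
statistic is `delta = (-log10 PEP_B) - (-log10 PEP_A)` with PEP floored at
1e-10 to avoid infinities (log base and floor are conventions of this
package; the delta threshold of 0.7 is the standard one for this
analysis). Regions: `grey` for |delta| below the threshold, `red` for
delta at or above it, `green` for delta at or below its negative (the
boundary value is assigned to the colored region so the regions partition
exactly), `blue` for spectra matched only in B, and `a_only_unmatched` for
spectra matched only in A — the latter region has no conventional name but
is emitted rather than dropped so the partition covers every spectrum.

## Species census

Each PSM is classed as `orthologous` if its peptide is shared between the
species (regardless of which protein the search engine reported — the
peptide cannot testify either way), `utility` if only utility sequences
produce it, and otherwise by its assigned protein: bovine assignments
split into `major_fbs` / `minor_fbs` / `other_bovine` by contaminant-list
membership, everything else is `human`. Classes partition the PSM set by
construction. Protein-group censuses class each group by its leader;
groups whose members span species are reported separately as `ambiguous`.

## SILAC audit

Heavy labels are matched by modification name and residue (Arg10 on R,
+10.01 Da; Lys8 on K, +8.01 Da; Pro6 on P, +6.01 Da, covering metabolic
Arg→Pro conversion), with delta masses stored to two decimals as printed
in search-engine exports; masses are not recomputed. A label on a
non-matching residue is treated as a corrupt table. Each R/K/P residue is
flagged independently (missed-cleavage peptides contribute several), and a
peptide is *labeled* when it carries at least one label.

Protein label classification follows the three-way rule — labeled (all
supporting peptides labeled), partially labeled (mixed), non-labeled
(none) — at two peptide-unit levels, both reported: *observation* level
aggregates PSMs by (sequence, charge) and counts a peptide seen both
labeled and unlabeled as two observations; *peptide* level collapses to
the bare sequence, labeled iff any supporting PSM is. When per-PSM species
classes are available, PSMs of orthologous peptides are excluded from a
group's label evidence: a species-shared peptide cannot testify about one
species' labeling, and without the exclusion a genuine contaminant group
could appear "partially labeled" purely through the labeled human ortholog
of a shared peptide. Groups supported only by shared peptides fall back to
the full evidence.

## The synthetic generator

The generator emulates the *structure* of a contaminated secretome
experiment, not its physics. Defaults are the study conditions:

| parameter | default | rationale |
|---|---|---|
| `contaminant_psm_fraction` | 0.07 | middle of the 5–10% serum carry-over expected from residual-FBS quantification |
| `major_fbs_count` | 30 | size of the dominant-contaminant list |
| `n_fbs_proteins` | 40 | FBS list size; Zipf (1/rank) abundances put ~93% of contaminant PSMs on the top 30 |
| `label_efficiency` | 0.97 | SILAC incorporation above the >95% level expected after ~8 passages |
| `pro_conversion_rate` | 0.03 | low Arg→Pro conversion |
| `orthology_fraction` | 0.25 | fraction of bovine proteins cloned from human sources |
| `incorrect_psm_rate` | 0.05 | per-database rate of misassigned spectra |
| XCorr correct / incorrect | N(3.5, 0.5) / N(1.5, 0.4) | separated score distributions |
| PEP | logistic in XCorr, slope 3, midpoint 2.3 | monotone score→error-probability link |
| per-database XCorr jitter | sd 0.05 | re-searches of a spectrum agree to well under the 0.7 delta threshold |

Protein sequences are i.i.d. over the 20 residues with K/R boosted to ~11%
combined so tryptic peptide lengths are realistic. Orthologous bovine
proteins are built by cloning a human protein, keeping exactly one of its
zero-missed-cleavage tryptic peptides and substituting every residue
outside it through a map that swaps K↔R, fixes P and cycles the remaining
letters — the cleavage pattern is preserved exactly, so the clone shares
precisely the preserved peptide (up to vanishing-probability random
collisions) and everything else is bovine-unique. This gives the generator
exact shared-peptide bookkeeping, verified against the index in the tests.

Per database (human-only, human+FBS, human+bovine) a spectrum yields a
correct PSM only when the database contains a parent of its true peptide;
otherwise, and additionally at `incorrect_psm_rate`, it yields a low-score
incorrect match drawn from the database's peptide universe. This
reproduces the two signature mechanisms: bovine-unique contaminant spectra
are *absent* from the human-only search (blue region) or *misassigned* to
human sequences that a composite search then beats (red region). Decoys
(one per spectrum, scored from the incorrect distribution) feed the
q-value estimator. SILAC annotations are driven by the spectrum's true
origin: cell-derived spectra get per-residue labels at the configured
efficiency, serum-derived spectra never do — which also reproduces the
"labeled bovine protein" artifact when an incorrect bovine match lands on
a cell-derived spectrum in the oversized human+bovine database.

What the generator does **not** emulate: spectra, m/z, retention time,
intensity-dependent scoring, homologous-but-inexact peptides, shared
peptides *within* a species, and protein abundance structure beyond the
FBS Zipf weights. Passing tests therefore demonstrate the correctness of
the bookkeeping, classification and estimation machinery under controlled
conditions, not the behaviour of any particular instrument or search
engine on real data.

## Problem sizes

The test suite and the acceptance script run at desk scale by choice:
database arithmetic at full proteome scale (113k placeholder entries),
digest–oracle equivalence on 200 random proteins of up to 60 residues,
structural invariants on 20 seeds of 1,000 spectra, and a 5,000-spectrum
end-to-end experiment for fraction/SILAC recovery (binomial 99% CI at
n ≈ 5,000 is about ±0.9 percentage points around 7%). Determinism is
absolute for a fixed seed: all randomness flows through seeded NumPy
generators with fixed stream splits per stage.

## Known limitations

* The protein score proxy (sum of PSM XCorr) is not the vendor metric;
  protein-level filtering on real exports should use the exported score.
* Exact minimal-cover grouping is exponential in component size and falls
  back to greedy above 14 candidate groups per component; greedy can
  overcount groups on adversarial instances.
* The q-value estimator is deliberately plain target-decoy counting — no
  semi-supervised rescoring — and is meant as plumbing for synthetic data.
* Orthologous-peptide handling treats I/L as distinct unless `equate_il`
  is set; conclusions about species specificity can differ between the
  two conventions and should be checked under both.
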