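# Methods

## Coordinates and reference

All internal coordinates are 0-based half-open on the CDS nucleotide
sequence; residues are 1-based everywhere a user sees them.  A CDS is
rejected unless it is ACGT-only, a multiple of 3 long, and free of internal
stop codons; `protein_length` excludes the terminal stop.

## sgRNA enumeration

Every 23-nt window on either strand whose last three bases match NGG or NAG
yields one guide.  The blunt Cas9 cut falls between spacer positions 17 and
18 (3 bp 5′ of the PAM); `cut_site` stores the plus-strand CDS coordinate of
the first base 3′ of the cut, so mirroring the CDS mirrors cut sites exactly
(`cut′ = L − cut`).  Guides are designed against the CDS only; windows
spanning into UTRs, off-target scoring and efficiency prediction are out of
scope.  Duplicate spacers are kept at each position and flagged.

## Effect calling

Per aligned fragment: soft clips are ignored; M/=/X blocks are diffed
base-by-base with maximal mismatch runs merged into one substitution
variant; I/D ops become insertion/deletion variants.  Reads whose net indel
length is not a multiple of 3 are frameshifts and are removed before any
quantification.  For the rest, the reference window around all variants is
extended to codon boundaries, both windows are translated, and the longest
common prefix, then suffix, is trimmed at residue level.  Prefix-first
trimming makes the call canonical in repeat runs (the event reports at the
rightmost equivalent position); when an indel diff ends flush with the
window with no anchoring suffix residue, the window is extended rightward
codon-by-codon until anchored.  A fragment that cannot cover the anchored
window is *uncallable* and excluded from both effect calling and coverage
denominators — it genuinely cannot localize the event.

Categories: `aa_deletion` (no replacement residues), `combo` (net length
change plus replacement residues; pure in-frame insertions fold in here,
flagged), `substitution` (equal length, ≥ 1 changed residue), `silent`.
In-frame changes whose replacement residues contain a stop are truncating
alleles, not residue-level information; they are filtered like frameshifts.
This rule is a commitment of this implementation: without it, stop-gaining
in-frame deletions behave as null alleles, ride the frameshift-driven
resistance route under positive selection, and produce spurious residue
hits.

The per-read quality filter drops reads with mean Phred < 30 (configurable
to a per-base-minimum mode); reads without stored qualities pass with a
warning.

## Quantification

An effect key is `(category, residue_start, affected_length,
alt_residues)`.  Its frequency divides its read count by the number of
retained (frame-acceptable) reads whose alignment fully contains the key's
codon-extended footprint; partial overlaps cannot establish presence or
absence of the event.  Keys under 9 reads are dropped (5 for the
mutagenesis-variety profile around a cut site, which also downsamples to
100 000 reads and restricts to ±20 nt of the cut).  Residues with zero
coverage are missing, never zero.  Multi-residue substitutions count their
read once per changed residue.  Amino-acid coverage counts residues touched
by ≥ 1 retained deletion/combo key spanning ≤ 3 residues.

## Scoring

Fold change = after/before frequency per key, defined only for keys retained
in the before library (a key absent afterwards scores 0; keys appearing only
after selection are excluded and logged — no pseudocounts).  Aggregation
follows the length-discounted sums given in the README with `w = 1` for
single-residue deletions (configurable); keys spanning more than 3 residues
are excluded as a false-positive guard.  The substitution cutoff is
`mean + 3·SD` (sample SD) of log10 of the positive after-selection
substitution frequencies; strict inequality, ties score 0.  For the
quantitative part, `log10 S_i` is z-scored over residues with
positive aggregate `S_i`, `p` is the upper-tail standard-normal probability,
and the essential score adds `sf_score` to `−log10 p`.  The base-10
logarithm is used throughout, and the standard normal is deliberately the
minimal reference distribution — it is isolated in one function so a
different null can be swapped in.  If the positive-`S` spread is zero, all
z are 0 (each residue contributes −log10 0.5).  Ranks order by descending
score with ties broken by residue index; the hit cutoff is `mean + k·SD` of
the essential scores with `k = 3` by default — the cutoff construction is an
assumption of this implementation (no printed formula exists for it) and
`k` is exposed as a parameter.  Replicate screens are scored independently
and per-residue scores are averaged before re-ranking and cutoff
computation, matching the two-replicate screening protocol.

## Synthetic screens

The simulator defines the study conditions under which the pipeline is
validated.  Defaults (a "desk-scale" diploid positive-selection screen):

| parameter | default | rationale |
|---|---|---|
| protein_length | 200 residues | small enough to iterate, large enough for ~150 guides |
| ploidy / inheritance | 2, recessive | the hardest standard case: resistance needs no functional allele left |
| n_cells | 20 000 | keeps ~5 reads per allele at the default depth, the read support per variant the full-scale protocol achieves at its recommended pre-selection depth |
| edit_rate | 0.8 | high per-allele editing after lentiviral delivery and two weeks of culture |
| guide_efficiency_concentration | 5 | per-guide efficiency ~ Beta(mean = edit_rate, κ = 5): guide-intrinsic, shared between replicates; this heterogeneity is what makes real replicate fold-change correlations high |
| indel spectrum | deletions 1–12 nt, P ∝ 0.7^len; 10% 1–2 nt insertions | a deletion-skewed stand-in for repair spectra (the assay characterizes but does not parameterize them); configurable |
| missense_rate | 0.05 | Cas9 repair yields few substitutions; point errors come mainly from RT/PCR/sequencing |
| fragment length | Normal(250, 25) nt | matches the ~250 bp fragmentation of the cDNA amplicon |
| seq_error_rate | 1e-3 per base | Illumina-class error |
| depth | 2×10⁵ reads per condition | desk-scale analogue of the deep sequencing the real assay needs |
| enrichment | 50 | selection advantage multiplier of resistant cells |

Each cell carries one integrated guide; each allele is edited independently
with the guide's efficiency, the outcome drawn from the indel spectrum or
missense.  Allele calls: frameshift or stop-gain → null; frame-preserving
change touching a planted critical residue → function-altering; anything
else → functional.  Phenotype: recessive resistance requires that no
functional allele remains; dominant needs one function-altering allele; for
essential genes the all-null genotype dies and is removed before either
library is sampled, and null-allele transcripts are additionally excluded
from after-library sampling.  Selection weights resistant cells by
`enrichment` in the after library.  Fragments are drawn over a UTR-extended
amplicon and trimmed to the CDS so that full-codon coverage is uniform
including terminal codons (real amplicons extend past the CDS; fragmenting
the bare CDS would starve terminal codons of coverage ~25-fold).  Error
counts are drawn at the nominal fragment length and position-thinned to the
trimmed length, so the realized per-base rate equals `seq_error_rate`.  The
simulator writes truth alignments (correct POS/CIGAR) directly, keeping
tests hermetic; FASTQ is emitted for users who want to run a real aligner.

Critical residues default to auto-placement: the centers of `n_critical`
equal strata of the *well-interrogated* residue set — residues touched by
the equivalent of ≥ 4 mean-efficiency in-frame deletion outcomes of the
library, computed with the same canonical-trimming logic the pipeline uses.
A residue with no reachable cut site (or reachable only by > 3-residue
deletions) carries no information in this assay class, so planting truth
there would test guide layout, not the scoring method.  Explicit
`critical_residues` override the auto-placement.

What the simulator does not model: sequence-dependent repair outcomes,
per-cell expression variation and nonsense-mediated decay (beyond the
essential-gene rules above), growth dynamics beyond a single enrichment
multiplier, PCR duplicates and alignment artifacts.  Passing the recovery
tests therefore shows the statistical machinery recovers planted truth
under this generative model, not that any particular wet-lab screen will.
Two in-frame variants can co-occur in one cell (one per allele), so the
hitchhiking failure mode exists in the population at its natural rate; no
printed rate exists to calibrate it separately.

## Numerical and degenerate-input choices

Sample SD (ddof = 1) everywhere a cutoff is computed; fewer than two
positive substitution frequencies → all `sf_score` 0 with a warning; zero
spread of positive aggregates → all z = 0 with a warning; empty effect
tables propagate to all-zero score vectors.  Strict inequality at every
cutoff.  Counting and scoring are deterministic; all sampling (downsampling,
subsampling, simulation) takes an explicit seed, and identical configuration
plus seed reproduces byte-identical outputs.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the synthetic study at
200 residues, 2×10⁵ reads per condition and two replicates per screen —
three screens under selection, twenty with selection disabled — plus a
2×10⁵-read mock library and a 200-read oracle comparison; together they
complete in a few minutes on one core.  These sizes are the package's
desk-scale study conditions; the full-scale assay runs orders of magnitude
deeper.
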