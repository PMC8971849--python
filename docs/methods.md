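# Methods

This note documents the models, estimators and numerical choices behind
`intronscan`, what the synthetic test bed does and does not emulate, and
the known limitations.

## The model

A search model is a structured multiple sequence alignment: rows over
`{A,C,G,U,-}` and a structure line assigning every column to a
single-stranded motif (one run of an integer label), a helix (two runs
of the same label, equal lengths), or a variable region (`.`). Helix
geometry is rigid by design — pair columns are indel-free — which
matches the biology of the group I catalytic core and keeps placement
enumeration exact; the flexibility of real introns lives entirely in the
variable regions, whose observed gap-stripped lengths per row define the
admissible spacer range between motifs.

Two helices whose occurrence intervals interleave cannot both be drawn
as nested brackets; scanning helices by 5' start, any helix that crosses
an already accepted one is flagged as a pseudoknot (in group I introns
this is the P7 pairing). The Stockholm exporter renders accepted helices
as `<...>` and each flagged helix as a distinct upper/lower-case letter
pair; downstream covariance-model tools then treat the pseudoknot at the
sequence level, which is exactly the information loss the export is
documented to accept.

## Profile estimation

Per single-strand column, base probabilities are estimated with
background-scaled pseudocounts,

    p(b | col) = (n_b + κ q_b) / (n_nongap + κ),     score = log2(p / q_b),

with κ = 1 by default and q uniform (optionally estimated from the
target genome). Helix pair columns are estimated jointly over the 16
ordered base pairs with pseudocount κ·q_i·q_j. Scores are in bits
throughout; a degenerate genome character (N, IUPAC codes) contributes 0
(background) rather than erroring. Columns that are all-gap in training
are dropped with a warning; a training row with a gap inside a helix
strand is excluded from that helix's counts (no deletions in helices).
Sequence weighting is deliberately omitted: the deduplication step of
the refinement loop (below) is the mechanism that keeps near-identical
rows from dominating the counts.

The per-motif training-score summary (`tstat`) scores every training row
against its own profiles (gap positions contribute 0) and suggests a
cutoff of `min(training scores) − margin`, margin 1 bit by default.

## Multi-level search

A strategy is 1–4 ordered levels, each adding a set of elements with a
cumulative score cutoff. Level 1 scans both strands of each contig for
placements of its elements whose inter-occurrence distances lie within
the variable-region bounds (`[observed_min, observed_max + 20% slack]`,
slack configurable); later levels enumerate admissible positions for
their elements inside the windows left between the placed anchors.
Spacer enumeration is exact — every admissible offset is considered, no
banding — and pruning uses admissible upper bounds only:

* exact per-position score arrays for single strands;
* for a helix 3' strand, the exact best pair score over the admissible
  5'-offset band (computed vectorised per offset);
* chain DP (sliding-window maxima) over these arrays for
  position-dependent suffix/prefix bounds at the genome-wide level;
* per-branch windowed suffix bounds anchored at the level's first
  placed occurrence.

Each level also prunes against the *final* cutoff using bounds over all
still-unplaced elements; this removes only placements that would
necessarily die at the last level, so the hit set is unchanged while the
early levels stay fast. A helix's 3' strand is enumerated immediately
after its 5' strand (windows are anchored on both sides, so enumeration
order does not change the placement set) so that the exact pair score
prunes as early as possible.

Overlapping placements of one model on the same contig and strand are
reduced to the best-scoring one; scores are rounded to 1e-6 bits before
comparison so float summation order cannot flip a tie, and ties go to
the leftmost placement. Hits are reported 1-based inclusive with strand
(BED export is 0-based half-open). A hit's uppercase element blocks are
its "conserved positions" for the conflict analysis.

## E-values

Best strategy scores on shuffled i.i.d. background sequences (default
500 shuffles of 10 kb, seeded) are fitted to a Gumbel by maximum
likelihood; then

    E(s) = (L_scanned / L_calib) · exp(−(s − μ) / β),

with `L_scanned` counting both strands by default (a flag exposes
single-strand accounting). The per-shuffle maximum is found by exact
branch-and-bound (same bounds as the search). The ML fit is
bulk-weighted, so the extreme tail decays slightly faster than the
fitted β predicts; on 1 Mb of random background the observed counts at
E ≤ {0.1, 1, 10} stay within a factor of ~2–3 of the nominal values,
which is the accuracy class this calibration aims for. E-values of real
intron hits sit tens of bits above μ, where this bias is irrelevant to
ranking or to the conflict margins.

## Automatic strategy construction

Motif conservation is measured as logo stack height,
`occupancy · (2 − H(p_col))` bits with pseudocounted probabilities,
averaged per motif (both strands for a helix). This occupancy-weighted
information content is a deliberate approximation of HMM-based logo
estimation. Level 1 is chosen by exhaustive enumeration of subsets (≤3
elements, leaving ≥2 for later levels) that (a) fit in one genomic
window of ≤500 nt under worst-case spacer lengths and (b) keep the
analytic false-positive estimate `2L·2^(−ΣI)` ≤ 10 expected random
hits/Mb; among feasible subsets the highest mean stack height wins, with
single strands preferred within a 0.1-bit tie (they are the cheap motifs
to scan). Middle level(s) add next-ranked elements until the budget
tightens to 0.1/Mb; the final level always completes the model. If no
subset is feasible the single most conserved element anchors level 1,
with a warning.

Per-level cutoffs: the final cutoff is the tstat total minimum minus the
margin; each earlier level's cutoff is the final cutoff minus the
maximum possible score of the elements not yet placed. This makes the
staged search provably lossless with respect to a single-level search at
the same final cutoff — a cutoff built only from the level's own
training minima can prune a placement whose weak anchor is compensated
by strong peripheral motifs, and fixture runs showed exactly that
failure mode.

## Iterative refinement

Each round retrains profiles, recalibrates E-values (seeded per round),
searches with the full model, keeps hits with E ≤ 1e-5 (cap 50/round),
drops hits within p-distance < threshold of each other or of existing
rows (single-linkage; 0.02 ≈ "identical", 0.10 ≈ "closely related";
Jukes–Cantor correction optional), and inserts the remainder verbatim
under the element columns — no realignment is needed because helices are
indel-free and single strands have fixed profile length. Variable
regions are widened (gap columns appended) when a recovered spacer does
not fit, and the observed spacer ranges are recomputed. The loop stops
when the hit locus set is unchanged or nothing new is added; re-running
on a converged model is a fixed point. Hit counts per round are logged
but not asserted monotone — retraining reshapes cutoffs. The manual
inspection steps of curator workflows are replaced by automatic
consistency checks (full element coverage, re-parse validation);
rejected hits are warned about, never silently dropped.

## Conflict analysis

Hits from different models sharing ≥1 nt of genomic interval are grouped
by connected components (same-model overlaps are already resolved at
search time). For every cross-model pair the shared conserved fraction
is `|A ∩ B| / min(|A|, |B|)` over element-block positions — the min
denominator is the symmetric, conservative reading of "proportion
shared between the hits", and it is configurable. A group is a
`conflicting_prediction` iff every cross-model pair shares > 0.95 and
has the same start/end within ±10 nt (the tolerance operationalises
"same or almost the same position"; for groups of ≥3 hits the rule is
applied pairwise-all). Everything else is `overlapping_introns` and
annotated as a candidate twintron. Resolution takes the lowest E-value;
the margin `log10(E_runnerup / E_winner)` below 2 orders flags the group
ambiguous — the quantitative form of "a large E-value difference allows
unambiguous assignment", and the signal used to decide that sister
sub-groups should be merged. The conflict matrix attributes each group
once, to the (winner, best competitor) model pair, so its upper-triangle
sum equals the group count.

## Synthetic test bed

The generator emulates the study system at desk scale: models with
single strands and helices (optionally one crossing pair, the P7
geometry), consensus drawn per column, training rows mutated at rate
1 − conservation with helix substitutions compensatory with probability
0.8 (creating genuine pair-column covariation — tests verify the pair
model outperforms treating a helix as two independent strands), spacers
drawn within per-region ranges, sister models obtained by mutating the
consensus at a chosen divergence on the same topology, and host genomes
of i.i.d. background at 70% A+T (the fungal mtDNA bias) with introns
implanted at non-overlapping loci on random strands plus a BED ground
truth. Defaults describe a well-conserved sub-group: 0.95 per-column
conservation, 20 training rows, 100 kb host genomes; sister divergence
0.30 (clearly separable sub-groups) with 0.03 standing in for the
nearly-inseparable regime. Everything is a deterministic function of the
seed.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: intron-encoded ORF insertions and the
resulting multi-kilobase length heterogeneity, derived introns with
missing peripheral motifs (partial hits are out of scope by design),
twintron nesting, codon/skew structure in the background, and
phylogenetic correlation between training rows.

## Numerical choices and degenerate inputs

Scores are float64 bits; placement-set comparisons use 1e-9 tolerance
and tie-breaking uses 1e-6-rounded scores. Unsatisfiable distance bounds
yield zero hits, not an error. An empty genome list yields an empty,
well-formed result. Calibration requires ≥10 finite shuffle maxima and
floors the Gumbel scale at 1e-6. Degenerate IUPAC characters score as
background everywhere. Model files reject length mismatches with the
offending sequence named; labels occurring more than twice, or helix
runs of unequal length, are format errors. More than 26 pseudoknot
helices would exhaust the WUSS letter alphabet and raise.

Search cutoffs for recovery-style runs are taken from the calibration
(the score whose E-value is 1e-3 on the scanned database) rather than
from training minima, with hits then filtered at the reporting
threshold (E ≤ 1e-5): training minima over 20 rows are a noisy lower
bound, and an implant drawn from the same distribution falls below them
once in ~20 draws, which would cap recall for no scientific reason.

## Problem sizes

The test suite and the acceptance script run on deliberately small
instances: oracle-equivalence fixtures use ≤5-element models on 3 kb
genomes (50 instances), recovery and merge experiments use 100 kb
genomes with 50–70 implants, calibration checks use 500 shuffles of
10 kb and a 1 Mb background scan, and round-trip checks use 100 random
models. These sizes were chosen so that exhaustive reference
enumerations remain tractable while every statistical contract is still
measurable; the search engine itself has no such limits and scans
megabase genomes in seconds.

## Known limitations

* Helix rigidity: an intron whose helix carries an indel relative to the
  model is invisible; the remedy in practice is sub-dividing models, not
  relaxing the geometry.
* No partial hits: a truncated or derived intron missing a modelled
  motif is not reported (by design; the Stockholm export exists to hand
  such cases to covariance-model tools).
* Gumbel tail bias of the bulk ML fit (factor ~2–3 at permissive
  E-values) — adequate for ranking and margins, not for precise
  per-database false-positive accounting.
* The false-positive budget in the auto-strategy is an analytic
  heuristic (`2L·2^(−I)`) that ignores inter-element distance
  constraints, so it overestimates random hits; it is used only to rank
  candidate subsets.
* `p_distance` clustering treats all positions equally; no evolutionary
  model beyond optional Jukes–Cantor correction.
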