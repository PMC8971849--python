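# intronscan

Motif + secondary-structure profile search for **group I introns** in
(mitochondrial) genome sequences.

Fungal mitochondrial genomes are dense with group I introns — ribozymes
with a conserved catalytic core of paired regions (P1–P9) but limited
primary-sequence conservation. Plain similarity search (BLAST-style)
fails on them: the conserved signal is small, scattered across up to
several kilobases of A+T-rich sequence, and partly structural (helices
conserved as *base pairings*, not letters; the P7 pairing is a
pseudoknot). Identifying and sub-classifying these introns (IA1, IA3,
IB, IB3, IC1, IC2, ID, …) therefore needs profile models that combine
sequence motifs with secondary structure, searched with distance
constraints between motifs.

`intronscan` provides that machinery end to end:

* **Structured-alignment models** — aligned RNA sequences plus a
  numbered structure line (a label occurring once = single-stranded
  motif, twice = the two strands of a helix; `.` columns are
  variable-length spacers). Crossing helices are detected and flagged as
  pseudoknots.
* **Profile training** — per-column log-odds over bases for single
  strands and per pair-column log-odds over the 16 ordered base pairs
  for helices (so compensatory substitutions score well), with
  background-scaled pseudocounts:
  `p(b|col) = (n_b + κ·q_b) / (n + κ)`, score `log2(p/q)` in bits.
* **Multi-level genome search** — an ordered strategy of 1–4 levels:
  level 1 anchors candidate regions with a cheap set of conserved
  motifs, later levels place the remaining elements inside the bounded
  spacer windows. Enumeration of spacer offsets is exact and pruning is
  admissible, so the staged search returns exactly what a brute-force
  enumeration would.
* **E-values** — a Gumbel model fitted to best-scores on shuffled
  background: `E(s) = (L_scanned / L_calib) · exp(−(s−μ)/β)`.
* **Auto-strategy** — builds 3–4 level strategies from per-motif logo
  stack heights (occupancy-weighted information content), preferring
  closely spaced, strongly conserved, single-stranded motifs for
  level 1, with an analytic false-positive budget.
* **Iterative refinement** — search → drop identical/closely related
  hits (p-distance clustering) → insert the best hits under the model
  columns → repeat until the hit set is stable.
* **Conflict analysis** — overlapping predictions from different
  sub-group models are grouped (≥1 shared nucleotide), classified as
  *conflicting predictions* (>95% shared conserved positions, same
  boundaries) vs *overlapping introns* (candidate twintrons), and
  resolved by best E-value; small E-value margins flag sub-groups that
  cannot be separated (the merge signal).
* **Stockholm/WUSS export** — nested helices as `<...>`, pseudoknotted
  helices as `AA..aa` letter pairs, for covariance-model pipelines.
* **Synthetic fixtures** — seeded generator for toy models, sister
  models at a chosen divergence, and A+T-rich host genomes with
  implanted introns plus a BED ground truth.

## Model file dialect

FASTA-like text; one `>structure` record with whitespace-separated
tokens, then the aligned sequences (RNA + `-`), all exactly as long as
the token list:

```
# model: myintron
>structure
1 1 1 . . 2 2 3 3 . . 2 2
>seqA
AUGCC--GGAUUCC
```

Grammar: `token := INT | "."`; contiguous runs of one integer form an
occurrence; one run → single strand, two runs → helix (equal lengths);
`.` runs are variable regions whose observed spacer lengths set the
search distance bounds. Profiles and strategies serialize to documented
JSON files (`intronscan build -o profiles.json`, `autostrategy -o
strategy.json`).

## Worked example

```bash
intronscan synth --seed 7 --implants 3 -o example
intronscan build example/synthA.model -o example/profiles.json
intronscan autostrategy example/synthA.model -o example/strategy.json \
    --rationale example/why.txt
intronscan calibrate example/synthA.model --strategy example/strategy.json \
    --seed 1 -o example/calib.json
intronscan search example/synthA.model example/genome.fasta \
    --strategy example/strategy.json --calib example/calib.json \
    -o example/hits.tsv --report example/report.txt
```

The rationale log shows the strategy construction — per-motif stack
heights and the staged cutoffs:

```
element 1: mean stack height 1.568 bits (info 14.1 bits)
element 3: mean stack height 1.629 bits (info 8.1 bits)
...
level 1: elements [1, 3, 5], cutoff 7.34 bits
level 2: elements [4], cutoff 26.79 bits
level 3: elements [2], cutoff 46.09 bits
level-1 expected random hits/Mb: 0.000302
```

Level 1 anchors the scan with the three single-stranded motifs (cheap to
match, jointly informative enough to expect ~0.0003 random hits/Mb);
the helices, which are costlier to place, join at levels 2–3. The search
recovers all three implanted introns, each at its true locus and strand:

```
model   contig   start  end    strand  score    evalue
synthA  contig1  24922  24990  +       78.2494  7.28e-09
synthA  contig1  50104  50177  -       78.2494  7.28e-09
synthA  contig1  75150  75218  +       74.3046  2.21e-08
```

Scores are total log-odds in bits; the E-value is the expected number of
equal-or-better matches in the scanned database (here 2 × 100 kb, both
strands). The report file prints each hit the way curators read them —
conserved blocks upper-case with spacer lengths between:

```
>1 E=7.28e-09 score=78.2494 contig=contig1 strand=+ span=24922-24990 model=synthA
GGUGUUAAC 5 UUACU 4 UACUC 4 CGCUC 9 AGUAA 4 GAGCG 2 GGGGUUU
```

`intronscan convert model -o model.sto` writes the Stockholm/WUSS form;
`intronscan conflicts hitsA.json hitsB.json -o conflicts.tsv --matrix
matrix.tsv` produces the cross-model conflict classification and count
matrix; `intronscan tally` tabulates exact motif variants (e.g. the P7
helix-bulge-helix, bulged residues printed between underscores).

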