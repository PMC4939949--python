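# Methods

This note records the algorithmic choices in `prosaa` precisely enough to
re-derive the implementation: the alignment model and recurrences, the
seeding and assembly machinery, the significance statistics, and the
evaluation arithmetic.

## 1. Model representation

A family is a profile HMM over the 20 amino acids with `L` nodes, each
carrying a match state M, an insert state I, and a delete state D. Models
are read from HMMER3 ASCII files (`HMMER3/b` and `HMMER3/f`), which store
negative natural-log probabilities with `*` meaning probability zero. Each
emission row and transition group is renormalised after decoding (the
fixed-point encoding leaves sums ~1e-6 from one) and validated to a 1e-5
tolerance. The `COMPO` line supplies the background composition; uniform
1/20 is used if absent.

Scoring uses bit-scaled log-odds: match/insert emission scores are
`log2(p_emit / p_background)` and transition scores are `log2(p_trans)`.
Only the seven core transitions per node are modelled
(`M→M, M→I, M→D, I→M, I→I, D→M, D→D`); the Plan7 special states are not
represented because locality is supplied explicitly (next section).

## 2. Alignment: local-local Viterbi, banded and full

The parse space is local in both the model and the target: a parse starts
in any match state with score 0, walks M/I/D states, and may end at any
match state. With `e_M(i, a)`, `e_I(i, a)` the emission scores and
`t(i, x→y)` the transition scores, the recurrences for target residue
`a_j` are

```
M[i, j] = e_M(i, a_j) + max( 0,                      # fresh local start
                             M[i-1, j-1] + t(i-1, M→M),
                             I[i-1, j-1] + t(i-1, I→M),
                             D[i-1, j-1] + t(i-1, D→M) )
I[i, j] = e_I(i, a_j) + max( M[i, j-1] + t(i, M→I),
                             I[i, j-1] + t(i, I→I) )
D[i, j] =               max( M[i-1, j] + t(i-1, M→D),
                             D[i-1, j] + t(i-1, D→D) )
```

and the alignment score is `max over (i, j) of M[i, j]`. Note the
`D[i-1, j-1]` index in the M-recurrence: a delete state consumes no target
residue, so the D→M predecessor sits on the previous *diagonal* cell, not
the previous row of the same column. The implementation is checked against
exhaustive enumeration of every parse on small instances (criterion-level
test), which pins this convention down. Ties in the max are broken with
preference M > I > D > fresh start so tracebacks are reproducible.

**Banding.** Given an anchor `(i0, j0)` — model position and target offset
of a seed — only cells with `|(i - i0) - (j - j0)| ≤ d` are computed
(default `d = 20`). The banded score is non-decreasing in `d`, is bounded
above by the full Viterbi score, and equals it once `d ≥ L + n`. A
score-only variant runs in O(band) memory and is what the assembly loop
calls.

**Forward.** The forward score replaces `max` by log-sum-exp (base 2) over
the same local parse space and upper-bounds the Viterbi score; it drives
final verification. The kernels are `numba`-compiled with true `-inf`
handling (an 'X' residue emits `-inf` from M and I and therefore can only
be skipped around via deletes or excluded from the local parse).

## 3. Seeding

For each window of `k = 6` consecutive match states, the *maximum seed
score* is `Σ_t max_a e_M(i0+t, a)` — the best log-odds any k-peptide can
achieve from those match emissions. Windows whose maximum is ≤ 0 carry no
anchoring signal and are skipped. Transitions are excluded from seed
scores: within the conserved windows worth seeding, M→M transitions are
near-deterministic and add a nearly constant offset.

Candidate reads come from a k-gram index keyed on the GBMR4 reduced
alphabet — four classes: {G}, {P}, {A,D,K,E,R,N,T,S,Q},
{Y,F,L,I,V,M,C,W,H}, with 'X' in a fifth class that never matches. Each
window contributes one lookup (its consensus k-gram's class string);
retrieved read windows are rescored in the full 20-letter alphabet and
kept when `score ≥ θ · max_seed_score` with θ = 0.8. The seeding output is
verified against a brute-force all-window scan at θ ∈ {0.5, 0.8, 1.0},
including the nesting of seed sets across θ.

## 4. Overlap graph

An *extension link* is a maximal exact suffix–prefix overlap of length
≥ 10 between an ordered pair of distinct reads; overlaps containing 'X'
never count. Links are found by hashing every read's first 10 residues and
scanning each read's suffix starts in ascending order, so the first
verified hit per pair is the maximal overlap. The index matches an
all-pairs brute-force computation (criterion-level test).

## 5. Simultaneous alignment and assembly

Each seed initialises a single-read contig scored by banded Viterbi around
the seed anchor. Branches extend alternately forward (C-terminal, links of
the last read) and backward (N-terminal, links of the first read); every
extension re-anchors the band and rescores the whole contig. A branch is
pruned when:

* its score drops more than 10 bits below the best score on that branch
  (drop-off);
* a direction has exceeded 5 extensions (depth limit);
* the added read, at its implied model position (bucketed to 10
  positions), was already consumed by an equal-or-better contig
  (redundancy check, applied both within a seed's search and globally);
* the per-seed branch count exceeds a guard (500).

A maximal path emits the snapshot with the best score it passed through,
and the reads of an emitted contig mark their (read, model-bucket) keys
consumed so later, worse seeds skip them.

**Recalibration.** Emitted contigs are greedily merged on exact overlaps
(longest first) using a prefix-keyed candidate map and a max-heap;
identical sequences collapse with the union of their reads; a merge that
would place a shared read at two different offsets is refused; contained
(substring) contigs are removed. Merged contigs are rescored with the full
(unbanded) Viterbi.

## 6. Significance statistics

Candidate contigs pass two gates:

1. **P-value gate** on the full Viterbi score, against 200 null scores of
   background-composition random sequences with lengths resampled from the
   candidate set, fit by a Gumbel (extreme-value) distribution. Cutoff
   0.05. With fewer than 30 null scores the fit is refused and an
   empirical rank P-value `(1 + #{null ≥ s}) / (N + 1)` is used.
2. **E-value gate** on the full forward score, with the same null
   construction and `E = n_candidates · P`. Cutoff 0.01. A hook allows an
   external HMMER-compatible searcher to replace this stage.

These statistics rank candidates; they calibrate one sequence against its
length's null and deliberately do not correct for best-of-database
selection (the verification cutoff absorbs that).

## 7. Read recruitment and family resolution

Reads map ungapped onto verified contigs at every offset, including
overhangs. A placement is accepted when the aligned fraction of the read
strictly exceeds 0.6 and has at most 3 mismatches ('X' always mismatches);
per (read, contig) the best placement minimises (mismatches, −overlap,
offset). An exact s-mer pigeonhole prefilter (`s = ceil((min_ov − m) /
(m + 1))`, lossless for the thresholds above) finds candidate offsets;
very short reads fall back to a full scan. A read recruited by several
families keeps the assignment with the most significant contig E-value
(ties: fewer mismatches, then family name).

## 8. Evaluation and abundance

* **Recall / precision / F** over read sets: `R = TP/(TP+FN)`,
  `P = TP/(TP+FP)`, `F = 2RP/(R+P)`; empty truth or prediction flags the
  respective rate as undefined rather than silently reporting 0.
* **N50**: smallest length ℓ such that contigs ≥ ℓ hold at least half the
  assembled residues; **normalized N50** divides by the model length
  (×3 in nucleotide space). Strict length filters (> 60 aa / > 180 nt)
  are applied before contig/read-precision counting when requested.
* **RPKM**: `count / (model_len·3/1000) / (total_reads/1e6)` — reads per
  nucleotide-equivalent kilobase of model per million database reads
  (an `aa` basis is available).

## 9. Synthetic benchmark

The benchmark generator samples homolog proteins from peaked random
profile HMMs (75% consensus concentration, M→M = 0.93), embeds them among
background-composition decoys, and fragments every protein into 33-aa
reads (`round(coverage · length / 33)` per protein, uniform starts, 1%
i.i.d. substitution errors). Ground truth labels a read with a family iff
it overlaps the homologous region by strictly more than 60% of the read —
the same rule recruitment uses. The acceptance benchmark (five families,
lengths 150–300, two homologs, 200 decoys, five dataset realisations)
requires mean read recall ≥ 0.80 and precision ≥ 0.90 at 10X coverage and
mean F at 10X ≥ mean F at 2X.

## 10. Default parameters

| parameter | default | role |
|---|---|---|
| `k` | 6 | seed window length |
| `theta` | 0.8 | fraction of the maximum seed score required |
| `min_overlap` | 10 | extension link / merge overlap threshold |
| `band` | 20 | Viterbi band half-width |
| `max_depth` | 5 | extensions per direction per branch |
| `dropoff` | 10 bits | branch abandonment threshold |
| `pvalue_cutoff` | 0.05 | candidate filter (Viterbi, Gumbel) |
| `evalue_cutoff` | 0.01 | verification filter (forward, Gumbel) |
| `max_mismatch` | 3 | recruitment mismatch limit |
| `min_portion` | 0.6 | recruitment overlap fraction (strict >) |
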