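# Methods

## The model

A motif-HMM for a family defined by a small number of short, ordered,
gap-free motif blocks. The state graph is a chain:

```
BEGIN → I_N → [Block 1] → I_link → [Block 2] → … → [Block m] → I_C → END
```

Each block of width n contributes match states M_1…M_n, insert states
I_1…I_{n−1} between neighbouring matches, and silent delete states D_2…D_n.
The flanking and linker inserts are single self-looping states (self-loop
0.99, exit 0.01, flat emission 0.05 per residue), so arbitrary inter-motif
sequence is absorbed at a constant per-residue cost. The model therefore
commits only to the motifs, their order, and nothing else about the
sequence — the design that suits families whose members share motifs but
not overall similarity.

Assumptions worth stating explicitly: one occurrence of each block per
sequence (the chain topology enforces this); blocks always appear in the
seed order; the first column of a block cannot be deleted (block entry is
at M_1); the last match/delete state of a block exits to the following
linker with probability 1, the linker itself playing the post-block insert
role. No training is performed — all parameters are fixed constants or
derived from the seed alignment as described below.

## Emissions

Match-state emissions for column j combine three ingredients:

1. raw column frequencies `f_l^j` from the seed block alignment;
2. flat pseudo-counts, `f̂_l^j = (f_l^j + 0.01)/1.2` (the divisor
   1 + 20·0.01 renormalizes exactly — pseudo-counted vectors sum to 1
   analytically, asserted at 1e-12);
3. a mutation model, `e_j(k) = Σ_l p_lk · f̂_l^j`.

The mutation matrix is derived from the BLOSUM50 score table as
`p_ls ∝ 2^(β·s(l,s))`, row-normalized, with a single scale β. Large β
recovers the identity (no evolutionary time, because every BLOSUM50 row has
its maximum on the diagonal); β → 0 gives the uniform matrix. The package
default β = 1.1508 was chosen once by calibration: minimize the summed
squared deviation of the emissions assigned to fully conserved Ser and His
columns from the anchor values 0.64 and 0.93. Under this one-parameter
family the His anchor is unreachable — a fully conserved column can emit
its consensus with probability at most 1.01/1.2 ≈ 0.842, since the mutation
matrix only redistributes mass away from the consensus — so calibration
reports achieved values and residuals (Ser 0.6453, residual +0.0053; His
0.8378, residual −0.0922) rather than asserting equality. The residuals are
part of the `CalibrationReport` attached to any calibrated
`MutationModel`.

The pseudo-count floor guarantees every emission is strictly positive
(`e_j(k) ≥ (0.01/1.2)·min_l p_lk`), so no sequence has probability zero
once it is long enough to reach END.

Insert states emit every residue at 0.05. Non-canonical symbols in target
sequences (B, Z, X, U, O, `*`) are emitted at 0.05 by *all* states and never
satisfy a catalytic-residue requirement; this keeps scores defined on real
proteome files without inventing substitution scores for ambiguity codes.

## Transitions

Intra-block transitions use fixed constants: t_MM = 0.99,
t_MI = t_MD = 0.005, t_IM = 0.99, t_II = 0.01, t_DM = 0.99, t_DD = 0.01,
t_ID = t_DI = 0. Match-to-match strongly dominates because insertions or
deletions inside the short conserved blocks are unlikely, but the small
insert/delete probabilities keep such paths representable. Every state's
outgoing distribution sums to 1 (asserted at 1e-12).

## Decoding

Delete states are silent. Rather than special-casing them in every
recursion, the model is compiled once to an emitting-state chain: transition
closure over silent paths uses `(I − T_ss)^{-1}` in the sum semiring
(forward/backward) and iterative relaxation in the max semiring (Viterbi).
The delete subgraph is acyclic, so both closures are exact. The test suite
checks this construction against brute-force path enumeration in the raw
graph, delete traversals included.

**Viterbi** runs in log space; its reported score is
`ln P(X, Π^V | M) − L·ln(1/20)` — log-odds against a null model emitting
residues uniformly. Subtraction (not division by L) is the normalization
that makes zero a meaningful threshold: insert emissions are exactly 1/20,
so background regions cancel and the score is driven by the match-state
log-odds plus transition costs. A block's match positions are read off the
decoded path; a match state absent from the path was traversed by deletion
and its position is recorded as absent.

**Forward/backward** use per-position scaling constants shared by both
passes. The forward- and backward-derived values of ln P(X|M) are compared
at relative 1e-9 on every call and a disagreement raises an internal
consistency error. The posterior matrix P(π_i = k | X, M) is normalized per
position over emitting states.

**Posterior decoding for motif-HMMs**: for each match state M_k,
`s_k = max_i P(π_i = M_k | X, M)` with the argmax position `j(k)`
(lowest index on ties). Motif score `S = Π_k s_k`; sequence score
`S_T = Σ_m S^m`. Summing rather than multiplying motif scores penalizes a
sequence with one weak and two strong motifs less — the desired behaviour
for positives carrying unusual mutations in a single block.

**PSSM baseline**: per block, all m − n + 1 windows of the log-emission
matrix are scored independently; the best window (lowest start on ties) is
reported, and the sequence score is the sum over blocks. A sequence shorter
than a block is flagged unscannable for that block and given a −∞ sentinel
total with a warning.

Tie-breaking everywhere is lowest position, then lowest state index, making
all decoders deterministic.

## PD/VD protocol and annotation

A sequence passes the PD/VD filter if, for every block, (i) the absolute
difference of the arithmetic means of the PD and VD position lists is
strictly below 3, and (ii) successive PD positions differ by at most 2 in
absolute value (repeats and small back-steps allowed). Criterion (i) is
symmetric in the two decoders; criterion (ii) reflects that deletions of
more than two residues within a block are implausible, and also rejects
scattered PD assignments whose mean happens to be close. When VD traverses
a block entirely by deletions the block cannot agree with PD and the filter
fails. Survivors are ranked by VD score.

GDSL annotation flags, computed on the VD path: all blocks present (a block
with more than half its match states deleted counts absent) and in order of
their start positions; the catalytic Ser at Block I match state 6 and His at
Block V match state 4 (an absent position fails the check); at least 20
residues between the end of one block and the start of the next
(`start(next) − end(prev) − 1 ≥ 20`). Classification is positive only if
every flag holds and the VD score exceeds 0. Scores within ±0.5 of the
threshold are additionally flagged borderline, since empirically both false
negatives and marginal false positives concentrate near zero; the flag never
changes the classification. Sequences shorter than the minimal emitting
path (7 residues for the three-block model) are recorded as negative with
the failure reason rather than crashing.

## Synthetic benchmark

The generator emulates the statistical structure the scanner assumes, at
desk scale. Positives: uniform-background sequences (lengths U(300, 500))
with one instance of each block implanted in order, inter-block gaps
U(20, 60). Block instances are drawn column-wise from the model's own
emission distributions; catalytic columns are set to the required consensus
residue; a per-residue point-mutation rate (default 0.05) then substitutes
residues uniformly, sparing catalytic columns. Negatives: pure background.
Decoys, labelled negative: positives with one block (chosen uniformly)
replaced by background, and positives with the catalytic residues
substituted — the two false-positive classes that dominate in practice.
Uniform background matches the 0.05 insert emission exactly, which makes
background regions score-neutral and the zero threshold exact on this data.

What the generator does **not** emulate: real proteome composition,
homology and paralog structure, repeat regions, partial/truncated entries.
Passing the benchmark therefore demonstrates correctness of the decoding
and filtering machinery under the model's own assumptions, not performance
on real proteomes.

Benchmark defaults (200 positives, 1000 negatives, 100 missing-block
decoys, 20 catalytic-mutant decoys) keep a full VD+PD scan under a minute
on one core while leaving enough positives for stable rate estimates.
Identical spec and seed give byte-identical output files.

## Evaluation

Sensitivity S = TP/(TP+FN) and false discovery proportion FDP = FP/(FP+TP)
at the fixed zero threshold; TN are counted but specificity is deliberately
not the headline metric, because with negatives dominating it is almost
blind to the false-positive count. Zero-denominator ratios are reported as
not-applicable, never as 0. Counts are additive over disjoint sequence
sets. Sequences removed by the PD/VD filter count as predicted-negative, so
eliminated true positives surface as false negatives.

## Numerical choices, in one place

- log base: natural; all scores in nats.
- forward/backward scaling shared between passes; Viterbi in log space.
- pseudo-count sum-to-one asserted at 1e-12; posterior row sums at 1e-9;
  forward-vs-backward agreement at relative 1e-9.
- ties: lowest position, then lowest state index.
- degenerate inputs: empty sequence → input error; sequence unable to reach
  END → decoding error, caught and recorded by the scanning pipeline.

## Known limitations

- One occurrence per block per sequence; repeated motifs are not found.
- No E-values or extreme-value calibration; raw thresholds only.
- The mutation model is a one-parameter family; both published emission
  anchors cannot be met simultaneously and the His residual (−0.09) is
  structural, not a numerical artifact.
- The packaged seed alignment is a synthetic stand-in with the documented
  block structure; models built from it are structurally faithful but its
  column frequencies are not those of a curated seed set.
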