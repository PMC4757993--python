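# motifhmm

Motif-HMM scanning for protein families that share little overall sequence
similarity but carry short, well-conserved motifs — the situation of the
GDSL esterase/lipase family, whose members are recognized by three conserved
sequence blocks (I, III, V) with a catalytic Ser in Block I and a catalytic
His in Block V, rather than by whole-length homology.

Unlike a profile-HMM, which models a full alignment, a **motif-HMM** models
only the motif blocks; everything between them is absorbed by single
self-looping insert states, so the composition and length of inter-motif
regions do not influence the score. The package provides:

- **Model construction** from a seed block alignment. Match-state emissions
  combine pseudo-counted column frequencies with a BLOSUM50-derived mutation
  model: `e_j(k) = Σ_l p_lk · f̂_l^j` with `f̂_l^j = (f_l^j + 0.01)/1.2` and
  `p_ls ∝ 2^(β·score(l,s))`, rows normalized. Intra-block transitions use
  the fixed constants t_MM = 0.99, t_MI = t_MD = 0.005, t_IM = 0.99,
  t_II = 0.01, t_DM = 0.99, t_DD = 0.01, t_ID = t_DI = 0.
- **Viterbi decoding (VD)** — most probable path, scored by a
  length-normalized log-odds `ln P(X, Π|M) − L·ln(1/20)` (nats); zero is a
  natural classification threshold because insert states emit exactly 1/20.
- **Posterior decoding (PD) for motif-HMMs** — forward/backward with
  per-position scaling; for each match state M_k the posterior is maximized
  over residue positions, `s_k = max_i P(π_i = M_k | X, M)`, each motif
  scores `S = s_1 ⋯ s_n`, and the sequence scores `S_T = Σ_m S^m`.
- **PSSM baseline** — independent per-block sliding-window scans over the
  log-emission matrices.
- **PD/VD agreement filter** — a sequence survives only if, for every
  block, |mean(PD positions) − mean(VD positions)| < 3 and successive PD
  positions differ by at most 2; survivors are ranked by VD score.
- **GDSL annotation criteria** — blocks present in order, catalytic
  Ser/His at their match states, inter-block gaps ≥ 20 residues, VD
  score > 0.
- **Synthetic benchmark generator** and **evaluation metrics**
  (sensitivity S = TP/(TP+FN), false discovery proportion FDP = FP/(FP+TP)).

The packaged seed fixture is a synthetic stand-in alignment (23 rows,
block widths 10/9/9, catalytic columns fully conserved) with the same
structure as a curated GDSL seed set.

## Worked example

```python
import numpy as np
import motifhmm as mh

blocks = mh.load_seed_blocks()                     # packaged GDSL seed
mut = mh.build_mutation_matrix(calibrate=True)     # BLOSUM50, calibrated scale
hmm = mh.assemble_motif_hmm(blocks, mut)

# a synthetic positive: consensus blocks implanted at 40, 90, 159
rng = np.random.default_rng(0)
bg = lambda n: "".join(mh.AMINO_ACIDS[i] for i in rng.integers(20, size=n))
cons = ["".join(mh.AMINO_ACIDS[int(np.argmax(E[j]))] for j in range(len(E)))
        for E in hmm.block_emissions]
seq = mh.ProteinSequence("demo", bg(39) + cons[0] + bg(40) + cons[1] + bg(60) + cons[2] + bg(80))

scan = mh.scan_sequence(seq, hmm)
print("VD score:", round(scan.vd.score, 2))
print("VD Block I positions:", scan.vd.block_positions["I"])
print("PD S_T:", round(scan.pd.total_score, 4))
print("PD/VD match:", scan.pdvd.overall)
rec = mh.annotate_gdsl(scan.vd, seq, hmm, pd_scan=scan.pd, pdvd=scan.pdvd)
print("classification:", rec.classification)
```

prints

```
VD score: 46.82
VD Block I positions: [40, 41, 42, 43, 44, 45, 46, 47, 48, 49]
PD S_T: 2.9966
PD/VD match: True
classification: GDSL-positive
```

The VD score of +46.8 is the log-odds (nats) of the best path against a
uniform background; the same pipeline gives about −16.8 for a pure
background sequence of the same composition, so the zero threshold cleanly
separates the two. `S_T` near its maximum of 3 says all three motifs are
confidently placed, and the PD positions agree with the VD positions, so
the PD/VD filter retains the sequence. Calibration reports the conserved
catalytic-column emissions it achieved (Ser 0.6453, His 0.8378 at scale
β = 1.1508) together with their residuals against the anchor values
0.64/0.93.

The same workflow is available from the shell:

```sh
motifhmm simulate -d bench/                 # synthetic labelled proteome
motifhmm scan -i bench/benchmark.fasta -o results.tsv --mode pdvd
motifhmm evaluate --results results.tsv --labels bench/benchmark.labels.tsv
```

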