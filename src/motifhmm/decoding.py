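"""Decoders: Viterbi, forward-backward, motif posterior decoding, PSSM scan.

All decoders operate on the emitting-state view of the model (delete states
are silent and were eliminated exactly at model compile time; a match state
missing from the decoded emitting path was therefore traversed by deletion).

Scores are natural-log (nats).  The Viterbi score is a length-normalized
log-odds: the log-probability of the best path minus L*ln(1/20), i.e. odds
against a null model emitting residues uniformly.  Because insert states emit
exactly 0.05 = 1/20, background regions are score-neutral and a score of zero
is a meaningful threshold separating motif-bearing from background sequences.

Numerics: Viterbi runs in log space; forward/backward use per-position
scaling factors shared by both passes, so sequences of arbitrary length do
not underflow.  All argmax tie-breaks take the lowest index (position first,
then state index), making every decoder deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alphabet import UNKNOWN, encode
from .exceptions import DecodingError, InputError
from .model import MotifHMM, Pssm

LOG_NULL = -np.log(20.0)  # per-residue log-probability of the uniform null


@dataclass(frozen=True)
class ProteinSequence:
    """A target sequence: identifier plus residue string."""

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


def _emission_columns(hmm: MotifHMM, encoded: np.ndarray) -> np.ndarray:
    """(L x n_emit) log-emission lookup; non-canonical symbols are emitted
    with the flat background probability by every state."""
    comp = hmm.compiled
    logE = comp.log_emissions  # (n_emit x alphabet)
    L = encoded.shape[0]
    out = np.empty((L, logE.shape[0]))
    known = encoded >= 0
    if known.any():
        out[known] = logE[:, encoded[known]].T
    if (~known).any():
        out[~known] = np.log(hmm.insert_emission)
    return out


@dataclass(frozen=True)
class ViterbiScan:
    """Most probable path and its length-normalized log-odds score."""

    sequence_id: str
    path: tuple[str, ...]                 # emitting-state names, one per residue
    raw_log_prob: float                   # ln P(X, path | M)
    score: float                          # raw_log_prob - L * ln(1/20)
    block_positions: dict[str, list[int | None]]  # per block: 1-based positions, None = deleted

    def positions(self, block_id: str) -> list[int | None]:
        return self.block_positions[block_id]


def viterbi_decode(seq: ProteinSequence, hmm: MotifHMM) -> ViterbiScan:
    """Best state path by the Viterbi recursion over emitting states."""
    if len(seq) == 0:
        raise InputError(f"{seq.id}: empty sequence")
    encoded = encode(seq.residues.upper(), alphabet=hmm.alphabet)
    comp = hmm.compiled
    logT = comp.log_t_max
    logE = _emission_columns(hmm, encoded)
    L, n = logE.shape

    v = comp.log_start_max + logE[0]
    pointers = np.zeros((L, n), dtype=np.int32)
    for i in range(1, L):
        cand = v[:, None] + logT
        ptr = np.argmax(cand, axis=0)
        pointers[i] = ptr
        v = cand[ptr, np.arange(n)] + logE[i]
    final = v + comp.log_end_max
    last = int(np.argmax(final))
    raw = float(final[last])
    if not np.isfinite(raw):
        raise DecodingError(
            f"{seq.id}: no valid path (sequence shorter than the minimal "
            f"emitting length {hmm.min_sequence_length}?)"
        )
    idx_path = np.empty(L, dtype=np.int64)
    idx_path[L - 1] = last
    for i in range(L - 1, 0, -1):
        idx_path[i - 1] = pointers[i, idx_path[i]]
    names = comp.emitting_states
    path = tuple(names[k] for k in idx_path)

    block_positions: dict[str, list[int | None]] = {
        bid: [None] * w for bid, w in zip(hmm.block_ids, hmm.block_widths)
    }
    for pos, state in enumerate(path, start=1):
        bid, _, tail = state.partition("/")
        if tail.startswith("M"):
            block_positions[bid][int(tail[1:]) - 1] = pos
    # null model: uniform residues at the insert emission (1/20 = 0.05 for
    # the amino-acid alphabet), so background regions are score-neutral
    return ViterbiScan(
        sequence_id=seq.id,
        path=path,
        raw_log_prob=raw,
        score=raw - L * np.log(hmm.insert_emission),
        block_positions=block_positions,
    )


@dataclass(frozen=True)
class Trellis:
    """Scaled forward/backward quantities and the posterior matrix."""

    sequence_id: str
    forward: np.ndarray        # (L x n_emit), scaled
    backward: np.ndarray       # (L x n_emit), scaled
    log_scales: np.ndarray     # (L,)
    posterior: np.ndarray      # (L x n_emit); rows sum to 1
    log_prob_forward: float    # ln P(X | M) from the forward pass
    log_prob_backward: float   # ln P(X | M) from the backward pass

    @property
    def log_prob(self) -> float:
        return self.log_prob_forward


def forward_backward(seq: ProteinSequence, hmm: MotifHMM) -> Trellis:
    """Scaled forward and backward passes plus the posterior state matrix.

    Raises :class:`DecodingError` if the model cannot generate the sequence,
    or if the two P(X|M) computations disagree beyond relative 1e-9.
    """
    if len(seq) == 0:
        raise InputError(f"{seq.id}: empty sequence")
    encoded = encode(seq.residues.upper(), alphabet=hmm.alphabet)
    comp = hmm.compiled
    with np.errstate(over="ignore"):
        T = np.exp(comp.log_t_sum)
        start = np.exp(comp.log_start_sum)
        end = np.exp(comp.log_end_sum)
    E = np.exp(_emission_columns(hmm, encoded))  # (L x n_emit)
    L, n = E.shape

    f = np.empty((L, n))
    log_scales = np.empty(L)
    u = start * E[0]
    for i in range(L):
        if i > 0:
            u = (f[i - 1] @ T) * E[i]
        c = u.sum()
        if c <= 0.0:
            raise DecodingError(
                f"{seq.id}: P(X|M) = 0 at position {i + 1} (sequence shorter "
                f"than the minimal emitting length {hmm.min_sequence_length}?)"
            )
        log_scales[i] = np.log(c)
        f[i] = u / c

    tail = float(f[L - 1] @ end)
    if tail <= 0.0:
        raise DecodingError(f"{seq.id}: no path reaches END")
    log_p_fwd = float(log_scales.sum() + np.log(tail))

    b = np.empty((L, n))
    b[L - 1] = end
    for i in range(L - 2, -1, -1):
        b[i] = (T @ (E[i + 1] * b[i + 1])) / np.exp(log_scales[i + 1])
    head = float((start * E[0] * b[0]).sum())
    log_p_bwd = float(log_scales[1:].sum() + np.log(head))

    if abs(log_p_fwd - log_p_bwd) > 1e-9 * max(1.0, abs(log_p_fwd)):
        raise DecodingError(
            f"{seq.id}: forward/backward disagree: {log_p_fwd} vs {log_p_bwd}"
        )

    posterior = f * b / tail
    return Trellis(
        sequence_id=seq.id,
        forward=f,
        backward=b,
        log_scales=log_scales,
        posterior=posterior,
        log_prob_forward=log_p_fwd,
        log_prob_backward=log_p_bwd,
    )


@dataclass(frozen=True)
class PosteriorScan:
    """Motif posterior decoding: per match state, the best-supported residue.

    For every match state M_k the posterior P(pi_i = M_k | X, M) is maximized
    over residue positions i, giving s_k and the position j(k).  A motif
    scores S = s_1 * ... * s_n and the sequence scores S_T = sum of the
    per-motif S (summing compensates for one weak motif among strong ones).
    """

    sequence_id: str
    s_values: dict[str, np.ndarray]       # per block: (width,) max posteriors
    positions: dict[str, list[int]]       # per block: 1-based argmax positions
    motif_scores: dict[str, float]        # per block: product of s_k
    total_score: float                    # S_T


def posterior_decode(trellis: Trellis, hmm: MotifHMM) -> PosteriorScan:
    """Motif posterior decoding from a computed trellis."""
    s_values: dict[str, np.ndarray] = {}
    positions: dict[str, list[int]] = {}
    motif_scores: dict[str, float] = {}
    for bid, w in zip(hmm.block_ids, hmm.block_widths):
        s = np.empty(w)
        pos = []
        for k in range(1, w + 1):
            col = trellis.posterior[:, hmm.match_state_index(bid, k)]
            i = int(np.argmax(col))  # lowest index on ties
            s[k - 1] = col[i]
            pos.append(i + 1)
        s_values[bid] = s
        positions[bid] = pos
        motif_scores[bid] = float(np.prod(s))
    return PosteriorScan(
        sequence_id=trellis.sequence_id,
        s_values=s_values,
        positions=positions,
        motif_scores=motif_scores,
        total_score=float(sum(motif_scores.values())),
    )


@dataclass(frozen=True)
class PssmScan:
    """Independent per-block best windows under the log-emission PSSMs."""

    sequence_id: str
    best_starts: dict[str, int | None]    # 1-based window start, None if unscannable
    window_scores: dict[str, float]       # best window score per block (nats)
    total_score: float                    # sum over blocks; -inf if any block unscannable
    unscannable: tuple[str, ...] = field(default=())


def pssm_window_scores(seq: ProteinSequence, pssm: Pssm, insert_emission: float = 0.05) -> np.ndarray:
    """Scores of all m - n + 1 candidate windows of one PSSM (nats)."""
    encoded = encode(seq.residues.upper())
    m, n = encoded.shape[0], pssm.width
    if m < n:
        return np.empty(0)
    log_flat = np.log(insert_emission)
    # per-position per-column score lookup, unknowns at the flat background
    col = np.where(
        encoded[:, None] >= 0,
        pssm.matrix.T[np.clip(encoded, 0, None)],
        log_flat,
    )  # (m x n): col[i, j] = score of residue i under PSSM column j+1
    starts = np.arange(m - n + 1)
    return np.stack([col[starts + j, j] for j in range(n)]).sum(axis=0)


def pssm_scan(seq: ProteinSequence, pssms: Sequence[Pssm], insert_emission: float = 0.05) -> PssmScan:
    """Scan each block's PSSM independently; lowest start wins ties."""
    if len(seq) == 0:
        raise InputError(f"{seq.id}: empty sequence")
    best_starts: dict[str, int | None] = {}
    window_scores: dict[str, float] = {}
    unscannable: list[str] = []
    for pssm in pssms:
        scores = pssm_window_scores(seq, pssm, insert_emission)
        if scores.size == 0:
            best_starts[pssm.block_id] = None
            window_scores[pssm.block_id] = -np.inf
            unscannable.append(pssm.block_id)
            continue
        i = int(np.argmax(scores))  # first occurrence = lowest start
        best_starts[pssm.block_id] = i + 1
        window_scores[pssm.block_id] = float(scores[i])
    if unscannable:
        warnings.warn(
            f"{seq.id}: too short for block(s) {unscannable}; total PSSM score undefined",
            stacklevel=2,
        )
        total = -np.inf
    else:
        total = float(sum(window_scores.values()))
    return PssmScan(
        sequence_id=seq.id,
        best_starts=best_starts,
        window_scores=window_scores,
        total_score=total,
        unscannable=tuple(unscannable),
    )
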