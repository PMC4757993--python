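"""PD/VD agreement filter and GDSL annotation criteria.

The PD/VD protocol keeps a sequence only when posterior decoding (PD) and
Viterbi decoding (VD) agree on all motifs:

  (i)  the absolute difference of the arithmetic means of the motif-residue
       positions returned by PD and by VD is < 3, and
  (ii) successive PD positions differ by at most 2 (repeats and small
       back-steps allowed: 40-41-41-43-44-45 passes, 44-47-48-49-50-51
       does not).

Survivors are ranked by VD score.  GDSL annotation then requires, on the VD
path: all blocks present in order, the catalytic Ser (Block I match state 6)
and His (Block V match state 4) at their predicted positions, inter-block
gaps of at least 20 residues, and a positive VD score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .decoding import (
    PosteriorScan,
    ProteinSequence,
    PssmScan,
    Trellis,
    ViterbiScan,
    forward_backward,
    posterior_decode,
    pssm_scan,
    viterbi_decode,
)
from .exceptions import DecodingError, InputError, ProtocolError
from .model import MotifHMM, Pssm

logger = logging.getLogger(__name__)

#: the protocol constants
MEAN_BOUND = 3.0          # criterion (i): |mean(PD) - mean(VD)| < 3 (strict)
CONSECUTIVE_BOUND = 2     # criterion (ii): |p_{k+1} - p_k| <= 2
MIN_BLOCK_GAP = 20        # annotation criterion (iii): residues between blocks
SCORE_THRESHOLD = 0.0     # VD classification threshold
BORDERLINE_BAND = 0.5     # |score| < 0.5 flagged for manual examination


@dataclass(frozen=True)
class MotifPrediction:
    """Ordered motif-residue positions predicted by one decoder for one block.

    VD predictions may contain ``None`` where a match state was traversed by
    deletion; the mean is taken over the positions that exist.
    """

    block_id: str
    positions: tuple[int | None, ...]

    @property
    def present(self) -> tuple[int, ...]:
        return tuple(p for p in self.positions if p is not None)

    @property
    def mean(self) -> float:
        present = self.present
        if not present:
            raise ProtocolError(f"block {self.block_id}: no predicted positions")
        return float(np.mean(present))


@dataclass(frozen=True)
class BlockMatchDecision:
    block_id: str
    criterion_i_pass: bool    # mean test
    criterion_ii_pass: bool   # consecutiveness test

    @property
    def matched(self) -> bool:
        return self.criterion_i_pass and self.criterion_ii_pass


@dataclass(frozen=True)
class MatchDecision:
    """Per-block PD/VD decisions; overall pass = all blocks match."""

    per_block: tuple[BlockMatchDecision, ...]

    @property
    def overall(self) -> bool:
        return all(d.matched for d in self.per_block)


def pdvd_match(
    pd: MotifPrediction,
    vd: MotifPrediction,
    mean_bound: float = MEAN_BOUND,
    consecutive_bound: int = CONSECUTIVE_BOUND,
) -> BlockMatchDecision:
    """PD/VD agreement for one block.

    Criterion (i) is symmetric in the two predictions (it compares means
    only); criterion (ii) applies to the PD positions.
    """
    if pd.block_id != vd.block_id:
        raise ProtocolError(f"block mismatch: {pd.block_id!r} vs {vd.block_id!r}")
    if not pd.present or not vd.present:
        raise ProtocolError(f"block {pd.block_id}: empty position list")
    crit_i = abs(pd.mean - vd.mean) < mean_bound
    pd_pos = pd.present
    crit_ii = all(
        abs(b - a) <= consecutive_bound for a, b in zip(pd_pos, pd_pos[1:])
    )
    return BlockMatchDecision(pd.block_id, crit_i, crit_ii)


def pdvd_decision(
    pd_scan: PosteriorScan,
    vd_scan: ViterbiScan,
    hmm: MotifHMM,
    mean_bound: float = MEAN_BOUND,
    consecutive_bound: int = CONSECUTIVE_BOUND,
) -> MatchDecision:
    """PD/VD agreement over all blocks of the model."""
    decisions = []
    for bid in hmm.block_ids:
        pd = MotifPrediction(bid, tuple(pd_scan.positions[bid]))
        vd = MotifPrediction(bid, tuple(vd_scan.block_positions[bid]))
        if not vd.present:
            # a fully deleted block cannot agree with PD
            decisions.append(BlockMatchDecision(bid, False, False))
            continue
        decisions.append(pdvd_match(pd, vd, mean_bound, consecutive_bound))
    return MatchDecision(per_block=tuple(decisions))


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-sequence decision with the reason trail."""

    sequence_id: str
    vd_score: float
    pd_total: float | None = None
    pssm_total: float | None = None
    block_positions: Mapping[str, tuple[int | None, ...]] = field(default_factory=dict)
    blocks_present_in_order: bool = False
    catalytic_ser_ok: bool = False
    catalytic_his_ok: bool = False
    min_gap_ok: bool = False
    pdvd_ok: bool | None = None
    too_short: bool = False
    borderline: bool = False
    classification: str = "negative"     # "GDSL-positive" / "negative"
    rank: int | None = None

    @property
    def positive(self) -> bool:
        return self.classification == "GDSL-positive"


def _block_span(positions: Sequence[int | None]) -> tuple[int, int] | None:
    present = [p for p in positions if p is not None]
    if not present:
        return None
    return min(present), max(present)


def _block_present(positions: Sequence[int | None]) -> bool:
    """A block traversed mostly by delete states (> half its match states
    absent) counts as absent."""
    absent = sum(1 for p in positions if p is None)
    return absent <= len(positions) // 2


def annotate_gdsl(
    vd_scan: ViterbiScan,
    seq: ProteinSequence,
    hmm: MotifHMM,
    pd_scan: PosteriorScan | None = None,
    pssm_result: PssmScan | None = None,
    pdvd: MatchDecision | None = None,
    min_gap: int = MIN_BLOCK_GAP,
    threshold: float = SCORE_THRESHOLD,
) -> AnnotationRecord:
    """Apply the GDSL annotation criteria to one decoded sequence."""
    residues = seq.residues.upper()
    positions = {bid: tuple(vd_scan.block_positions[bid]) for bid in hmm.block_ids}

    spans = [_block_span(positions[bid]) for bid in hmm.block_ids]
    present = [
        s is not None and _block_present(positions[bid])
        for bid, s in zip(hmm.block_ids, spans)
    ]
    in_order = all(present) and all(
        spans[i][0] < spans[i + 1][0] for i in range(len(spans) - 1)
    )

    def catalytic_ok(block_id: str) -> bool:
        for col, required in hmm.catalytic.get(block_id, {}).items():
            pos = positions[block_id][col - 1]
            if pos is None:                      # deleted catalytic position
                return False
            if residues[pos - 1] != required:    # non-canonical never matches
                return False
        return True

    ser_ok = catalytic_ok("I") if "I" in hmm.catalytic else all(
        catalytic_ok(b) for b in hmm.catalytic
    )
    his_ok = catalytic_ok("V") if "V" in hmm.catalytic else ser_ok

    gap_ok = all(p is not None for p in spans)
    if gap_ok:
        for i in range(len(spans) - 1):
            gap = spans[i + 1][0] - spans[i][1] - 1
            if gap < min_gap:
                gap_ok = False
                break

    flags_ok = in_order and ser_ok and his_ok and gap_ok
    if pdvd is not None:
        flags_ok = flags_ok and pdvd.overall
    positive = flags_ok and vd_scan.score > threshold
    return AnnotationRecord(
        sequence_id=seq.id,
        vd_score=vd_scan.score,
        pd_total=None if pd_scan is None else pd_scan.total_score,
        pssm_total=None if pssm_result is None else pssm_result.total_score,
        block_positions=positions,
        blocks_present_in_order=in_order,
        catalytic_ser_ok=ser_ok,
        catalytic_his_ok=his_ok,
        min_gap_ok=gap_ok,
        pdvd_ok=None if pdvd is None else pdvd.overall,
        borderline=abs(vd_scan.score) < BORDERLINE_BAND,
        classification="GDSL-positive" if positive else "negative",
    )


@dataclass(frozen=True)
class SequenceScan:
    """All decoder outputs for one sequence (absent where not requested)."""

    sequence: ProteinSequence
    vd: ViterbiScan | None = None
    pd: PosteriorScan | None = None
    pssm: PssmScan | None = None
    pdvd: MatchDecision | None = None
    error: str | None = None


def scan_sequence(
    seq: ProteinSequence,
    hmm: MotifHMM,
    pssms: Sequence[Pssm] | None = None,
    run_pd: bool = True,
) -> SequenceScan:
    """Run the requested decoders on one sequence; decoder failures (e.g.
    sequences too short for the model) are recorded, not raised."""
    try:
        vd = viterbi_decode(seq, hmm)
    except (DecodingError, InputError) as exc:
        logger.warning("skipping %s: %s", seq.id, exc)
        return SequenceScan(sequence=seq, error=str(exc))
    pd = pdvd = None
    if run_pd:
        trellis = forward_backward(seq, hmm)
        pd = posterior_decode(trellis, hmm)
        pdvd = pdvd_decision(pd, vd, hmm)
    ps = None if pssms is None else pssm_scan(seq, pssms, hmm.insert_emission)
    return SequenceScan(sequence=seq, vd=vd, pd=pd, pssm=ps, pdvd=pdvd)


def pdvd_filter(
    sequences: Iterable[ProteinSequence],
    hmm: MotifHMM,
    mean_bound: float = MEAN_BOUND,
    consecutive_bound: int = CONSECUTIVE_BOUND,
) -> list[SequenceScan]:
    """Run VD and PD on every sequence, keep only PD/VD matches, and rank
    the survivors by VD score (descending; input order breaks ties)."""
    kept = []
    for seq in sequences:
        scan = scan_sequence(seq, hmm, run_pd=True)
        if scan.error is not None:
            continue
        decision = pdvd_decision(scan.pd, scan.vd, hmm, mean_bound, consecutive_bound)
        if decision.overall:
            kept.append(replace(scan, pdvd=decision))
    kept.sort(key=lambda s: -s.vd.score)
    return kept


def rank_and_classify(
    records: Sequence[AnnotationRecord],
    mode: str = "vd",
    threshold: float = SCORE_THRESHOLD,
) -> list[AnnotationRecord]:
    """Sort records by the selected decoder's score (descending, stable) and
    re-apply the classification threshold to the VD score."""
    def sort_key(rec: AnnotationRecord) -> float:
        if mode in ("vd", "pdvd"):
            return rec.vd_score
        if mode == "pd":
            return rec.pd_total if rec.pd_total is not None else -np.inf
        if mode == "pssm":
            return rec.pssm_total if rec.pssm_total is not None else -np.inf
        raise ProtocolError(f"unknown ranking mode {mode!r}")

    order = sorted(range(len(records)), key=lambda i: -sort_key(records[i]))
    out = []
    for rank, i in enumerate(order, start=1):
        rec = records[i]
        positive = rec.positive and rec.vd_score > threshold
        out.append(
            replace(
                rec,
                rank=rank,
                classification="GDSL-positive" if positive else "negative",
            )
        )
    return out
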