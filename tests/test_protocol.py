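"""PD/VD agreement criteria, GDSL annotation and ranking."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import helpers
from motifhmm.decoding import ProteinSequence, forward_backward, posterior_decode, viterbi_decode
from motifhmm.exceptions import ProtocolError
from motifhmm.protocol import (
    AnnotationRecord,
    MotifPrediction,
    annotate_gdsl,
    pdvd_decision,
    pdvd_filter,
    pdvd_match,
    rank_and_classify,
    scan_sequence,
)


def _pred(positions):
    return MotifPrediction("I", tuple(positions))


class TestPdvdMatch:
    def test_mean_criterion_worked_example(self):
        """VD 40-45 consecutive vs PD split across a long interval: the
        means are 42.5 and 56, so criterion (i) fails."""
        vd = _pred([40, 41, 42, 43, 44, 45])
        pd = _pred([40, 41, 42, 70, 71, 72])
        assert vd.mean == 42.5
        assert pd.mean == 56.0
        decision = pdvd_match(pd, vd)
        assert not decision.criterion_i_pass
        assert not decision.matched

    @pytest.mark.parametrize(
        "positions, expected",
        [
            ([44, 45, 47, 48, 49, 50], True),   # allowed: max step 2
            ([44, 47, 48, 49, 50, 51], False),  # 44 -> 47 jumps by 3
            ([40, 41, 41, 43, 44, 45], True),   # repeats allowed
        ],
    )
    def test_consecutiveness_criterion_worked_examples(self, positions, expected):
        vd = _pred([40, 41, 42, 43, 44, 45])
        decision = pdvd_match(_pred(positions), vd)
        assert decision.criterion_ii_pass is expected

    def test_close_means_with_scattered_positions_rejected(self):
        """Means 42 vs 43 pass criterion (i), but the 22 -> 61 jump in the
        PD positions fails criterion (ii), so there is no PD/VD match."""
        pd = _pred([20, 21, 22, 61, 62, 64])
        vd = _pred([40, 41, 42, 43, 44, 45])
        decision = pdvd_match(pd, vd)
        assert decision.criterion_i_pass
        assert not decision.criterion_ii_pass
        assert not decision.matched

    def test_empty_positions_is_protocol_error(self):
        with pytest.raises(ProtocolError):
            pdvd_match(_pred([]), _pred([40]))

    @given(
        st.lists(st.integers(1, 500), min_size=1, max_size=12),
        st.lists(st.integers(1, 500), min_size=1, max_size=12),
    )
    def test_mean_criterion_is_symmetric(self, a, b):
        """Criterion (i) depends only on the two means, so swapping the PD
        and VD roles cannot change it."""
        d1 = pdvd_match(_pred(a), _pred(b))
        d2 = pdvd_match(_pred(b), _pred(a))
        assert d1.criterion_i_pass == d2.criterion_i_pass


class TestPdvdFilter:
    def test_consensus_positives_all_pass(self, gdsl_hmm):
        rng = np.random.default_rng(21)
        seqs = [
            ProteinSequence(
                f"p{i}", helpers.implant(gdsl_hmm, [30 + i, 100 + i, 170 + i], rng, 260)
            )
            for i in range(5)
        ]
        kept = pdvd_filter(seqs, gdsl_hmm)
        assert {s.sequence.id for s in kept} == {f"p{i}" for i in range(5)}
        scores = [s.vd.score for s in kept]
        assert scores == sorted(scores, reverse=True)

    def test_filtered_set_is_subset_of_vd_positives(self, gdsl_hmm):
        rng = np.random.default_rng(22)
        seqs = [
            ProteinSequence(f"n{i}", helpers.background(rng, 200, gdsl_hmm.alphabet))
            for i in range(6)
        ]
        seqs.append(
            ProteinSequence("p", helpers.implant(gdsl_hmm, [40, 110, 180], rng, 260))
        )
        vd_positive = {
            s.id for s in seqs if viterbi_decode(s, gdsl_hmm).score > 0
        }
        # PD/VD positives (filter survivors scoring > 0) are a pure subset
        pdvd_positive = {
            s.sequence.id for s in pdvd_filter(seqs, gdsl_hmm) if s.vd.score > 0
        }
        assert pdvd_positive <= vd_positive
        assert "p" in pdvd_positive


class TestAnnotation:
    def _scan(self, hmm, residues, seq_id="s"):
        seq = ProteinSequence(seq_id, residues)
        scan = scan_sequence(seq, hmm, run_pd=True)
        assert scan.error is None
        return seq, scan

    def test_consensus_positive_fully_flagged(self, gdsl_hmm):
        rng = np.random.default_rng(31)
        # gaps of 40 and 60 intervening residues
        starts = [31, 31 + 10 + 40, 31 + 10 + 40 + 9 + 60]
        seq, scan = self._scan(gdsl_hmm, helpers.implant(gdsl_hmm, starts, rng, 260))
        rec = annotate_gdsl(scan.vd, seq, gdsl_hmm, pd_scan=scan.pd, pdvd=scan.pdvd)
        assert rec.blocks_present_in_order
        assert rec.catalytic_ser_ok and rec.catalytic_his_ok
        assert rec.min_gap_ok
        assert rec.positive

    def test_catalytic_ser_mutant_is_a_negative_pseudoenzyme(self, gdsl_hmm):
        """Ser -> Gly at Block I match state 6, everything else conserved:
        high score, but the catalytic check demotes it."""
        rng = np.random.default_rng(32)
        blocks = helpers.consensus_blocks(gdsl_hmm)
        blocks[0] = blocks[0][:5] + "G" + blocks[0][6:]
        starts = [40, 110, 180]
        residues = helpers.implant(gdsl_hmm, starts, rng, 260, blocks=blocks)
        seq, scan = self._scan(gdsl_hmm, residues)
        rec = annotate_gdsl(scan.vd, seq, gdsl_hmm)
        assert scan.vd.score > 0
        assert not rec.catalytic_ser_ok
        assert rec.catalytic_his_ok
        assert not rec.positive

    def test_small_inter_block_gap_fails_distance_criterion(self, gdsl_hmm):
        rng = np.random.default_rng(33)
        starts = [40, 40 + 10 + 15, 40 + 10 + 15 + 9 + 40]  # first gap only 15
        seq, scan = self._scan(gdsl_hmm, helpers.implant(gdsl_hmm, starts, rng, 260))
        rec = annotate_gdsl(scan.vd, seq, gdsl_hmm)
        assert not rec.min_gap_ok
        assert not rec.positive

    def test_flags_only_demote(self, gdsl_hmm):
        """Adding a failed PD/VD flag can only demote a record."""
        rng = np.random.default_rng(34)
        seq, scan = self._scan(gdsl_hmm, helpers.implant(gdsl_hmm, [40, 110, 180], rng, 260))
        with_flags = annotate_gdsl(scan.vd, seq, gdsl_hmm, pdvd=scan.pdvd)
        without = annotate_gdsl(scan.vd, seq, gdsl_hmm)
        assert with_flags.positive <= without.positive


class TestRanking:
    def _rec(self, seq_id, score, positive=True):
        return AnnotationRecord(
            sequence_id=seq_id,
            vd_score=score,
            classification="GDSL-positive" if positive else "negative",
        )

    def test_threshold_application(self):
        ranked = rank_and_classify([self._rec("a", 4.2), self._rec("b", -0.3)])
        by_id = {r.sequence_id: r for r in ranked}
        assert by_id["a"].positive
        assert not by_id["b"].positive

    def test_all_negative_input_still_ranked(self):
        ranked = rank_and_classify([self._rec("a", -1.0, False), self._rec("b", -2.0, False)])
        assert [r.rank for r in ranked] == [1, 2]
        assert not any(r.positive for r in ranked)

    def test_shuffle_stability_of_score_order(self):
        records = [self._rec(f"s{i}", float(i % 7) - 3.0) for i in range(20)]
        ranked = rank_and_classify(records)
        shuffled = rank_and_classify(records[::-1])
        assert [r.vd_score for r in ranked] == [r.vd_score for r in shuffled]

    def test_ties_broken_by_input_order(self):
        ranked = rank_and_classify([self._rec("first", 1.0), self._rec("second", 1.0)])
        assert [r.sequence_id for r in ranked] == ["first", "second"]
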