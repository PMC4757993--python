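"""Decoder correctness against brute-force oracles and model invariants."""

import numpy as np
import pytest

import helpers
from motifhmm.decoding import (
    ProteinSequence,
    forward_backward,
    posterior_decode,
    pssm_scan,
    pssm_window_scores,
    viterbi_decode,
)
from motifhmm.exceptions import DecodingError, InputError
from motifhmm.model import MotifHMM, Pssm


class TestViterbiOracle:
    @pytest.mark.parametrize("model_fixture", ["tiny_hmm", "tiny2_hmm"])
    def test_matches_enumeration_on_short_sequences(self, model_fixture, request):
        """Viterbi probability equals the max over all enumerated raw-graph
        paths (including delete-state traversals) on every sequence of
        length <= 5 over the reduced alphabet."""
        hmm = request.getfixturevalue(model_fixture)
        lo = hmm.min_sequence_length
        for seq in helpers.all_sequences("ABC", 5):
            best, _ = helpers.enumerate_paths(hmm, seq)
            if len(seq) < lo:
                assert best == 0.0
                with pytest.raises(DecodingError):
                    viterbi_decode(ProteinSequence("s", seq), hmm)
                continue
            scan = viterbi_decode(ProteinSequence("s", seq), hmm)
            assert scan.raw_log_prob == pytest.approx(np.log(best), abs=1e-9)

    def test_implanted_consensus_recovered_at_known_starts(self, gdsl_hmm):
        rng = np.random.default_rng(42)
        starts = [40, 120, 200]
        seq = ProteinSequence(
            "implant", helpers.implant(gdsl_hmm, starts, rng, length=300)
        )
        scan = viterbi_decode(seq, gdsl_hmm)
        for bid, start, width in zip(gdsl_hmm.block_ids, starts, gdsl_hmm.block_widths):
            assert scan.block_positions[bid] == list(range(start, start + width))
        assert scan.score > 0

    def test_empty_sequence_is_input_error(self, gdsl_hmm):
        with pytest.raises(InputError):
            viterbi_decode(ProteinSequence("empty", ""), gdsl_hmm)

    def test_monotone_degradation_under_point_mutation(self, gdsl_hmm):
        """Mutating an implanted motif residue away from consensus never
        increases the Viterbi score."""
        rng = np.random.default_rng(7)
        starts = [50, 130, 210]
        base = helpers.implant(gdsl_hmm, starts, rng, length=320)
        base_score = viterbi_decode(ProteinSequence("b", base), gdsl_hmm).score
        consensus = helpers.consensus_blocks(gdsl_hmm)
        for b, (bid, start) in enumerate(zip(gdsl_hmm.block_ids, starts)):
            for offset in (0, 4, gdsl_hmm.block_widths[b] - 1):
                pos = start - 1 + offset
                original = base[pos]
                replacement = "W" if original != "W" else "A"
                mutated = base[:pos] + replacement + base[pos + 1:]
                score = viterbi_decode(ProteinSequence("m", mutated), gdsl_hmm).score
                assert score <= base_score + 1e-9


class TestForwardBackward:
    @pytest.mark.parametrize("model_fixture", ["tiny_hmm", "tiny2_hmm"])
    def test_total_probability_matches_enumeration(self, model_fixture, request):
        hmm = request.getfixturevalue(model_fixture)
        for seq in helpers.all_sequences("ABC", 5):
            if len(seq) < hmm.min_sequence_length:
                continue
            _, total = helpers.enumerate_paths(hmm, seq)
            trellis = forward_backward(ProteinSequence("s", seq), hmm)
            assert trellis.log_prob == pytest.approx(np.log(total), abs=1e-9)

    def test_forward_and_backward_totals_agree(self, gdsl_hmm):
        rng = np.random.default_rng(3)
        for _ in range(10):
            seq = ProteinSequence("r", helpers.background(rng, 150, gdsl_hmm.alphabet))
            trellis = forward_backward(seq, gdsl_hmm)
            assert trellis.log_prob_forward == pytest.approx(
                trellis.log_prob_backward, rel=1e-12, abs=1e-9
            )

    def test_posterior_rows_sum_to_one(self, gdsl_hmm):
        rng = np.random.default_rng(4)
        seq = ProteinSequence("r", helpers.background(rng, 200, gdsl_hmm.alphabet))
        trellis = forward_backward(seq, gdsl_hmm)
        assert np.allclose(trellis.posterior.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(trellis.posterior >= 0)
        assert np.all(trellis.posterior <= 1 + 1e-12)

    def test_max_path_bounded_by_total_probability(self, gdsl_hmm):
        rng = np.random.default_rng(5)
        for length in (60, 150):
            seq = ProteinSequence("r", helpers.background(rng, length, gdsl_hmm.alphabet))
            vd = viterbi_decode(seq, gdsl_hmm)
            fb = forward_backward(seq, gdsl_hmm)
            assert vd.raw_log_prob <= fb.log_prob + 1e-12 * abs(fb.log_prob)


class TestPosteriorDecode:
    def test_implanted_positions_agree_with_viterbi(self, gdsl_hmm):
        rng = np.random.default_rng(11)
        starts = [40, 110, 190]
        seq = ProteinSequence("p", helpers.implant(gdsl_hmm, starts, rng, length=280))
        vd = viterbi_decode(seq, gdsl_hmm)
        pd = posterior_decode(forward_backward(seq, gdsl_hmm), gdsl_hmm)
        for bid in gdsl_hmm.block_ids:
            assert pd.positions[bid] == vd.block_positions[bid]
            diffs = np.diff(pd.positions[bid])
            assert np.all(diffs == 1)

    def test_total_score_bounded_by_block_count(self, gdsl_hmm):
        rng = np.random.default_rng(12)
        seq = ProteinSequence("r", helpers.background(rng, 120, gdsl_hmm.alphabet))
        pd = posterior_decode(forward_backward(seq, gdsl_hmm), gdsl_hmm)
        assert 0.0 <= pd.total_score <= len(gdsl_hmm.block_ids)
        for bid in gdsl_hmm.block_ids:
            assert 0.0 <= pd.motif_scores[bid] <= 1.0

    def test_single_match_state_collapses_to_trellis_row_max(self, tiny_hmm):
        seq = ProteinSequence("s", "ABCAB")
        trellis = forward_backward(seq, tiny_hmm)
        pd = posterior_decode(trellis, tiny_hmm)
        col = trellis.posterior[:, tiny_hmm.match_state_index("A", 1)]
        assert pd.s_values["A"][0] == pytest.approx(col.max())
        assert pd.positions["A"][0] == int(np.argmax(col)) + 1


class TestPssmScan:
    def test_window_count_is_m_minus_n_plus_one(self, gdsl_pssms):
        by_id = {p.block_id: p for p in gdsl_pssms}
        seq = ProteinSequence("s", "A" * 20)
        assert pssm_window_scores(seq, by_id["III"]).size == 20 - 9 + 1 == 12

    def test_flat_pssm_ties_break_to_first_window(self):
        flat = Pssm("F", np.full((4, 20), np.log(0.05)))
        seq = ProteinSequence("s", "ACDEFGHIKL")
        scan = pssm_scan(seq, [flat])
        assert scan.best_starts["F"] == 1
        assert scan.window_scores["F"] == pytest.approx(4 * np.log(0.05))

    def test_best_window_matches_exhaustive_evaluation(self):
        rng = np.random.default_rng(9)
        matrix = np.log(rng.dirichlet(np.ones(20), size=3))
        pssm = Pssm("T", matrix)
        from motifhmm.alphabet import AMINO_ACIDS

        for _ in range(25):
            residues = "".join(
                AMINO_ACIDS[i] for i in rng.integers(20, size=rng.integers(3, 30))
            )
            seq = ProteinSequence("s", residues)
            scores = pssm_window_scores(seq, pssm)
            brute = [
                sum(matrix[j, AMINO_ACIDS.index(residues[start + j])] for j in range(3))
                for start in range(len(residues) - 2)
            ]
            assert np.allclose(scores, brute, atol=1e-12)
            scan = pssm_scan(seq, [pssm])
            assert scan.best_starts["T"] == int(np.argmax(brute)) + 1

    def test_too_short_sequence_flags_block_with_warning(self, gdsl_pssms):
        seq = ProteinSequence("s", "ACDEF")
        with pytest.warns(UserWarning, match="too short"):
            scan = pssm_scan(seq, gdsl_pssms)
        assert scan.total_score == -np.inf
        assert set(scan.unscannable) == {"I", "III", "V"}
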