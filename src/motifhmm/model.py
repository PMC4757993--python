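"""Motif-HMM assembly and per-block PSSMs.

The model chains an N-terminal flank insert, the motif blocks, single
self-looping linker inserts between consecutive blocks, and a C-terminal
flank insert:

    BEGIN -> I_N -> [Block 1] -> I_link -> [Block 2] -> ... -> I_C -> END

Within a block of width n, match states M_1..M_n are wired with insert states
I_1..I_{n-1} and silent delete states D_2..D_n using the fixed transition
constants

    t_MM = 0.99   t_MI = 0.005   t_MD = 0.005
    t_IM = 0.99   t_II = 0.01    t_ID = 0
    t_DM = 0.99   t_DI = 0       t_DD = 0.01

The last match (or delete) state of a block exits to the following linker
with probability 1; the linker itself plays the post-block insert role.
Flank and linker inserts self-loop with probability 0.99 and emit every
residue with the flat background probability 0.05, so the composition of the
regions between the motifs does not influence decoding.

Decoding runs on the emitting states only: the silent delete chains are
eliminated exactly (matrix-inverse closure for path sums, iterative
relaxation for path maxima), which preserves both total and maximum path
probabilities of the full model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .alphabet import AMINO_ACIDS
from .blocks import BlockAlignment, ColumnFrequencies
from .exceptions import ConfigurationError
from .mutation import MutationModel

#: the fixed intra-block transition constants
DEFAULT_TRANSITIONS: dict[str, float] = {
    "MM": 0.99, "MI": 0.005, "MD": 0.005,
    "IM": 0.99, "II": 0.01, "ID": 0.0,
    "DM": 0.99, "DI": 0.0, "DD": 0.01,
}
#: self-loop probability of flank and linker inserts (exit = 1 - self-loop)
DEFAULT_LINKER_SELF_LOOP: float = 0.99
#: flat insert emission probability per residue
INSERT_EMISSION: float = 0.05


def compute_emission_profile(block: BlockAlignment, mut: MutationModel) -> np.ndarray:
    """Match-state emissions of one block: e_j(k) = sum_l p_lk * f_hat_l(j).

    Returns a (width x 20) array; strictly positive by the pseudo-count floor.
    """
    fhat = np.stack(
        [ColumnFrequencies.from_column(block.column(j)).pseudo for j in range(1, block.width + 1)]
    )
    return fhat @ mut.matrix


@dataclass(frozen=True)
class Pssm:
    """Per-block position-specific scoring matrix: natural-log emissions."""

    block_id: str
    matrix: np.ndarray  # (width x alphabet) of ln e_j(k)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]


def build_pssms(blocks: Sequence[BlockAlignment], mut: MutationModel) -> list[Pssm]:
    """One PSSM per block; columns are logarithms of the match emissions."""
    return [
        Pssm(block_id=b.block_id, matrix=np.log(compute_emission_profile(b, mut)))
        for b in blocks
    ]


@dataclass(frozen=True)
class _Compiled:
    """Emitting-state view of the model after silent-state elimination."""

    emitting_states: tuple[str, ...]
    emissions: np.ndarray        # (n_emit x alphabet)
    log_emissions: np.ndarray
    log_t_sum: np.ndarray        # (n_emit x n_emit), path-sum transitions
    log_start_sum: np.ndarray
    log_end_sum: np.ndarray
    log_t_max: np.ndarray        # path-max transitions (Viterbi semiring)
    log_start_max: np.ndarray
    log_end_max: np.ndarray


class MotifHMM:
    """Assembled multi-block motif-HMM.

    Generic over the emission alphabet so that tiny test models can be built
    directly from hand-made emission tables; the GDSL model is produced by
    :func:`assemble_motif_hmm` from a seed block alignment and a mutation
    model.
    """

    def __init__(
        self,
        block_ids: Sequence[str],
        block_emissions: Sequence[np.ndarray],
        alphabet: str = AMINO_ACIDS,
        catalytic: Mapping[str, Mapping[int, str]] | None = None,
        transitions: Mapping[str, float] | None = None,
        linker_self_loop: float = DEFAULT_LINKER_SELF_LOOP,
        insert_emission: float = INSERT_EMISSION,
    ) -> None:
        if len(block_ids) == 0:
            raise ConfigurationError("a motif-HMM needs at least one block")
        if len(block_ids) != len(block_emissions):
            raise ConfigurationError("one emission table per block required")
        self.alphabet = alphabet
        self.block_ids = tuple(block_ids)
        self.block_emissions = [np.asarray(e, dtype=float) for e in block_emissions]
        for bid, e in zip(self.block_ids, self.block_emissions):
            if e.ndim != 2 or e.shape[1] != len(alphabet):
                raise ConfigurationError(f"block {bid}: emission table must be (width x alphabet)")
            if not np.all((e > 0) & (e <= 1)):
                raise ConfigurationError(f"block {bid}: emissions must lie in (0, 1]")
        self.block_widths = tuple(e.shape[0] for e in self.block_emissions)
        self.catalytic = {
            bid: dict(cols) for bid, cols in (catalytic or {}).items() if cols
        }
        for bid, cols in self.catalytic.items():
            if bid not in self.block_ids:
                raise ConfigurationError(f"catalytic annotation for unknown block {bid!r}")
            w = self.block_widths[self.block_ids.index(bid)]
            for col in cols:
                if not 1 <= col <= w:
                    raise ConfigurationError(f"block {bid}: catalytic column {col} outside [1, {w}]")
        self.transitions = dict(DEFAULT_TRANSITIONS if transitions is None else transitions)
        self.linker_self_loop = float(linker_self_loop)
        self.insert_emission = float(insert_emission)
        self._build_graph()
        self._compiled = self._compile()

    # ------------------------------------------------------------------
    # raw state graph (includes silent delete states)
    # ------------------------------------------------------------------

    def _build_graph(self) -> None:
        t = self.transitions
        trans: dict[str, dict[str, float]] = {}
        emitting: list[str] = []
        silent: list[str] = []
        emission_rows: list[np.ndarray] = []
        flat = np.full(len(self.alphabet), self.insert_emission)

        def add_emitting(name: str, row: np.ndarray) -> None:
            emitting.append(name)
            emission_rows.append(row)

        def add_edge(a: str, b: str, p: float) -> None:
            if p > 0:
                trans.setdefault(a, {})[b] = trans.setdefault(a, {}).get(b, 0.0) + p

        loop = self.linker_self_loop
        add_edge("BEGIN", "FLANK_N", 1.0)
        add_emitting("FLANK_N", flat)
        entry = "FLANK_N"
        n_blocks = len(self.block_ids)
        for b, (bid, E) in enumerate(zip(self.block_ids, self.block_emissions)):
            w = E.shape[0]
            first = f"{bid}/M1"
            add_edge(entry, entry, loop)
            add_edge(entry, first, 1.0 - loop)
            for j in range(1, w + 1):
                add_emitting(f"{bid}/M{j}", E[j - 1])
                if j < w:
                    add_emitting(f"{bid}/I{j}", flat)
                if j >= 2:
                    silent.append(f"{bid}/D{j}")
            nxt = f"LINK{b + 1}" if b < n_blocks - 1 else "FLANK_C"
            for j in range(1, w):
                add_edge(f"{bid}/M{j}", f"{bid}/M{j + 1}", t["MM"])
                add_edge(f"{bid}/M{j}", f"{bid}/I{j}", t["MI"])
                add_edge(f"{bid}/M{j}", f"{bid}/D{j + 1}", t["MD"])
                add_edge(f"{bid}/I{j}", f"{bid}/M{j + 1}", t["IM"])
                add_edge(f"{bid}/I{j}", f"{bid}/I{j}", t["II"])
                if j < w - 1:
                    add_edge(f"{bid}/I{j}", f"{bid}/D{j + 2}", t["ID"])
            for j in range(2, w):
                add_edge(f"{bid}/D{j}", f"{bid}/M{j + 1}", t["DM"])
                add_edge(f"{bid}/D{j}", f"{bid}/D{j + 1}", t["DD"])
                add_edge(f"{bid}/D{j}", f"{bid}/I{j}", t["DI"])
            # last match/delete state exits to the following linker
            add_edge(f"{bid}/M{w}", nxt, 1.0)
            if w >= 2:
                add_edge(f"{bid}/D{w}", nxt, 1.0)
            if b < n_blocks - 1:
                add_emitting(nxt, flat)
            entry = nxt
        add_emitting("FLANK_C", flat)
        add_edge("FLANK_C", "FLANK_C", loop)
        add_edge("FLANK_C", "END", 1.0 - loop)

        self.trans = trans
        self.emitting_states = tuple(emitting)
        self.silent_states = tuple(silent)
        self.states = ("BEGIN",) + self.emitting_states + self.silent_states + ("END",)
        self._emissions = np.stack(emission_rows)
        self._validate_graph()

    def _validate_graph(self) -> None:
        for state in self.states:
            if state == "END":
                continue
            total = sum(self.trans.get(state, {}).values())
            if abs(total - 1.0) > 1e-12:
                raise ConfigurationError(f"outgoing probabilities of {state} sum to {total!r}")

    # ------------------------------------------------------------------
    # silent-state elimination
    # ------------------------------------------------------------------

    def _compile(self) -> _Compiled:
        e_idx = {s: i for i, s in enumerate(self.emitting_states)}
        s_idx = {s: i for i, s in enumerate(self.silent_states)}
        n_e, n_s = len(e_idx), len(s_idx)
        T_ee = np.zeros((n_e, n_e))
        T_es = np.zeros((n_e, n_s))
        T_se = np.zeros((n_s, n_e))
        T_ss = np.zeros((n_s, n_s))
        start_e = np.zeros(n_e)
        start_s = np.zeros(n_s)
        end_e = np.zeros(n_e)
        end_s = np.zeros(n_s)

        for a, outs in self.trans.items():
            for b, p in outs.items():
                if a == "BEGIN":
                    if b in e_idx:
                        start_e[e_idx[b]] += p
                    elif b in s_idx:
                        start_s[s_idx[b]] += p
                elif b == "END":
                    if a in e_idx:
                        end_e[e_idx[a]] += p
                    else:
                        end_s[s_idx[a]] += p
                elif a in e_idx and b in e_idx:
                    T_ee[e_idx[a], e_idx[b]] += p
                elif a in e_idx:
                    T_es[e_idx[a], s_idx[b]] += p
                elif b in e_idx:
                    T_se[s_idx[a], e_idx[b]] += p
                else:
                    T_ss[s_idx[a], s_idx[b]] += p

        if n_s:
            # sum semiring: closure over silent chains (acyclic, so invertible)
            A = np.linalg.inv(np.eye(n_s) - T_ss)
            t_sum = T_ee + T_es @ A @ T_se
            start_sum = start_e + (start_s @ A) @ T_se
            end_sum = end_e + T_es @ (A @ end_s)
            # max semiring: best silent path products by relaxation
            best_se = T_se.copy()
            best_end = end_s.copy()
            for _ in range(n_s):
                best_se = np.maximum(best_se, (T_ss[:, :, None] * best_se[None, :, :]).max(axis=1))
                best_end = np.maximum(best_end, (T_ss * best_end[None, :]).max(axis=1))
            t_max = np.maximum(T_ee, (T_es[:, :, None] * best_se[None, :, :]).max(axis=1))
            start_max = np.maximum(start_e, (start_s[:, None] * best_se).max(axis=0))
            end_max = np.maximum(end_e, (T_es * best_end[None, :]).max(axis=1))
        else:
            t_sum = t_max = T_ee
            start_sum = start_max = start_e
            end_sum = end_max = end_e

        with np.errstate(divide="ignore"):
            return _Compiled(
                emitting_states=self.emitting_states,
                emissions=self._emissions,
                log_emissions=np.log(self._emissions),
                log_t_sum=np.log(t_sum),
                log_start_sum=np.log(start_sum),
                log_end_sum=np.log(end_sum),
                log_t_max=np.log(t_max),
                log_start_max=np.log(start_max),
                log_end_max=np.log(end_max),
            )

    # ------------------------------------------------------------------
    # public surface
    # ------------------------------------------------------------------

    @property
    def compiled(self) -> _Compiled:
        return self._compiled

    @property
    def n_match_states(self) -> int:
        return sum(self.block_widths)

    @property
    def n_emitting_states(self) -> int:
        return len(self.emitting_states)

    @property
    def min_sequence_length(self) -> int:
        """Shortest sequence with a nonzero-probability path: every flank and
        linker insert plus at least the first match state of every block."""
        return 2 + (len(self.block_ids) - 1) + len(self.block_ids)

    def match_state_index(self, block_id: str, k: int) -> int:
        """Emitting-state index of match state ``k`` (1-based) of a block."""
        return self.emitting_states.index(f"{block_id}/M{k}")

    def match_state_number(self, block_id: str, k: int) -> int:
        """Global 1-based match-state number (blocks numbered consecutively)."""
        b = self.block_ids.index(block_id)
        return sum(self.block_widths[:b]) + k

    def emission(self, block_id: str, k: int) -> np.ndarray:
        b = self.block_ids.index(block_id)
        return self.block_emissions[b][k - 1]

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "format": "motifhmm-model-v1",
            "alphabet": self.alphabet,
            "blocks": [
                {
                    "block_id": bid,
                    "emissions": [[float(x) for x in row] for row in E],
                    "catalytic": {str(c): r for c, r in self.catalytic.get(bid, {}).items()},
                }
                for bid, E in zip(self.block_ids, self.block_emissions)
            ],
            "transitions": self.transitions,
            "linker_self_loop": self.linker_self_loop,
            "insert_emission": self.insert_emission,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MotifHMM":
        payload = json.loads(text)
        if payload.get("format") != "motifhmm-model-v1":
            raise ConfigurationError("not a motifhmm model dump")
        return cls(
            block_ids=[b["block_id"] for b in payload["blocks"]],
            block_emissions=[np.array(b["emissions"]) for b in payload["blocks"]],
            alphabet=payload["alphabet"],
            catalytic={
                b["block_id"]: {int(c): r for c, r in b["catalytic"].items()}
                for b in payload["blocks"]
            },
            transitions=payload["transitions"],
            linker_self_loop=payload["linker_self_loop"],
            insert_emission=payload["insert_emission"],
        )

    def model_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def assemble_motif_hmm(
    blocks: Sequence[BlockAlignment],
    mut: MutationModel,
    transitions: Mapping[str, float] | None = None,
    linker_self_loop: float = DEFAULT_LINKER_SELF_LOOP,
) -> MotifHMM:
    """Build the motif-HMM from ordered seed blocks and a mutation model."""
    if len(blocks) == 0:
        raise ConfigurationError("a motif-HMM needs at least one block")
    return MotifHMM(
        block_ids=[b.block_id for b in blocks],
        block_emissions=[compute_emission_profile(b, mut) for b in blocks],
        catalytic={b.block_id: dict(b.catalytic) for b in blocks},
        transitions=transitions,
        linker_self_loop=linker_self_loop,
    )
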