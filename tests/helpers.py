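"""Shared test utilities: brute-force HMM oracles and sequence builders.

The enumeration oracle walks the RAW state graph (including silent delete
states), so it independently validates both the decoding recursions and the
silent-state elimination performed at model compile time.
"""

from __future__ import annotations

import itertools

import numpy as np

from motifhmm.model import MotifHMM


def enumerate_paths(hmm: MotifHMM, residues: str) -> tuple[float, float]:
    """(max path probability, total probability) by exhaustive enumeration
    of all valid paths through the raw state graph."""
    emit_idx = {s: i for i, s in enumerate(hmm.emitting_states)}
    E = hmm.compiled.emissions
    sym = {a: i for i, a in enumerate(hmm.alphabet)}
    encoded = [sym[ch] for ch in residues]
    L = len(encoded)
    best = 0.0
    total = 0.0

    def walk(state: str, pos: int, prob: float) -> None:
        nonlocal best, total
        for nxt, p in hmm.trans.get(state, {}).items():
            q = prob * p
            if nxt == "END":
                if pos == L:
                    total += q
                    if q > best:
                        best = q
            elif nxt in emit_idx:
                if pos < L:
                    walk(nxt, pos + 1, q * E[emit_idx[nxt], encoded[pos]])
            else:  # silent delete state
                walk(nxt, pos, q)

    walk("BEGIN", 0, 1.0)
    return best, total


def all_sequences(alphabet: str, max_length: int):
    """Every non-empty sequence over ``alphabet`` up to ``max_length``."""
    for length in range(1, max_length + 1):
        for combo in itertools.product(alphabet, repeat=length):
            yield "".join(combo)


def consensus_blocks(hmm: MotifHMM) -> list[str]:
    """Per-block consensus strings (argmax emission per column)."""
    return [
        "".join(hmm.alphabet[int(np.argmax(E[j]))] for j in range(E.shape[0]))
        for E in hmm.block_emissions
    ]


def background(rng: np.random.Generator, length: int, alphabet: str) -> str:
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=length))


def implant(
    hmm: MotifHMM,
    starts: list[int],
    rng: np.random.Generator,
    length: int,
    blocks: list[str] | None = None,
) -> str:
    """Uniform background of ``length`` with block instances written at the
    given 1-based starts (consensus blocks unless given explicitly)."""
    if blocks is None:
        blocks = consensus_blocks(hmm)
    seq = list(background(rng, length, hmm.alphabet))
    for start, inst in zip(starts, blocks):
        seq[start - 1:start - 1 + len(inst)] = list(inst)
    return "".join(seq)
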