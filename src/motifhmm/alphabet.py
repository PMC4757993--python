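"""The 20-letter amino-acid alphabet and sequence encoding.

Non-canonical symbols (B, Z, X, U, O, ``*``) occasionally appear in real
proteome files.  They are not part of the model alphabet: every emitting
state emits them with the flat background probability 0.05, and they never
satisfy a catalytic-residue requirement.  ``encode`` maps them to ``UNKNOWN``
(-1) so decoders can apply that rule uniformly.
"""

from __future__ import annotations

import numpy as np

from .exceptions import AlphabetError

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
N_RESIDUES: int = 20
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: symbols tolerated in target sequences but outside the model alphabet
NON_CANONICAL: frozenset[str] = frozenset("BZXUO*")

UNKNOWN: int = -1


def residue_index(symbol: str) -> int:
    """Index of a canonical residue; raises :class:`AlphabetError` otherwise."""
    try:
        return AA_INDEX[symbol]
    except KeyError:
        raise AlphabetError(f"symbol {symbol!r} is not a canonical amino acid") from None


def encode(residues: str, strict: bool = False, alphabet: str = AMINO_ACIDS) -> np.ndarray:
    """Encode a residue string as an int array over ``alphabet``.

    For the canonical amino-acid alphabet, non-canonical symbols become
    ``UNKNOWN`` (-1) unless ``strict``, in which case they raise
    :class:`AlphabetError` naming the offending symbol.  For any other
    (reduced) alphabet every symbol must be a member.
    """
    if alphabet == AMINO_ACIDS:
        index, tolerated = AA_INDEX, NON_CANONICAL
    else:
        index, tolerated = {a: i for i, a in enumerate(alphabet)}, frozenset()
    out = np.empty(len(residues), dtype=np.int64)
    for i, ch in enumerate(residues):
        idx = index.get(ch, UNKNOWN)
        if idx == UNKNOWN and (strict or ch not in tolerated):
            raise AlphabetError(
                f"symbol {ch!r} at position {i + 1} is not in the alphabet"
            )
        out[i] = idx
    return out
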