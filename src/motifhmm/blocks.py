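"""Seed block alignments and column frequency estimation.

A *block* is one gap-free aligned motif from the seed alignment.  The packaged
GDSL seed models three blocks (I, III, V; widths 10, 9, 9) with the catalytic
serine at Block I column 6 and the catalytic histidine at Block V column 4.

Column emission parameterization starts from raw per-column relative residue
frequencies, to which a flat pseudo-count of 0.01 per residue is added:

    f_hat(l) = (f(l) + 0.01) / 1.2

The divisor 1.2 = 1 + 20 * 0.01 renormalizes exactly, so pseudo-counted
vectors sum to 1 analytically.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS, N_RESIDUES
from .exceptions import AlphabetError, InputError, NormalizationError

PSEUDOCOUNT = 0.01
PSEUDO_NORM = 1.0 + N_RESIDUES * PSEUDOCOUNT  # = 1.2
PSEUDO_FLOOR = PSEUDOCOUNT / PSEUDO_NORM


@dataclass(frozen=True)
class BlockAlignment:
    """One gap-free aligned motif block from the seed set.

    ``catalytic`` maps 1-based column indices to the required residue symbol
    (e.g. ``{6: "S"}`` for the GDSL Block I serine).
    """

    block_id: str
    rows: tuple[str, ...]
    catalytic: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rows:
            raise InputError(f"block {self.block_id}: no rows")
        width = len(self.rows[0])
        if width == 0:
            raise InputError(f"block {self.block_id}: zero-width rows")
        for r, row in enumerate(self.rows):
            if len(row) != width:
                raise InputError(
                    f"block {self.block_id}: row {r + 1} has length {len(row)}, expected {width}"
                )
            for ch in row:
                if ch not in AA_INDEX:
                    raise AlphabetError(
                        f"block {self.block_id}: symbol {ch!r} in row {r + 1} "
                        "is not a canonical amino acid (gap-free blocks required)"
                    )
        for col, res in self.catalytic.items():
            if not 1 <= col <= width:
                raise InputError(
                    f"block {self.block_id}: catalytic column {col} outside [1, {width}]"
                )
            if res not in AA_INDEX:
                raise AlphabetError(f"block {self.block_id}: catalytic residue {res!r} unknown")

    @property
    def width(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> list[str]:
        """Residues of the 1-based column ``j``."""
        if not 1 <= j <= self.width:
            raise InputError(f"column {j} outside [1, {self.width}]")
        return [row[j - 1] for row in self.rows]


@dataclass(frozen=True)
class ColumnFrequencies:
    """Raw and pseudo-counted relative frequencies of one alignment column."""

    raw: np.ndarray
    pseudo: np.ndarray

    @classmethod
    def from_column(cls, column_residues: Sequence[str]) -> "ColumnFrequencies":
        raw = column_frequencies(column_residues)
        return cls(raw=raw, pseudo=apply_pseudocounts(raw))

    def as_dict(self, which: str = "pseudo") -> dict[str, float]:
        vec = self.pseudo if which == "pseudo" else self.raw
        return {a: float(vec[i]) for i, a in enumerate(AMINO_ACIDS)}


def column_frequencies(column_residues: Sequence[str]) -> np.ndarray:
    """Relative residue frequencies of one alignment column (sums to 1)."""
    if len(column_residues) == 0:
        raise AlphabetError("empty alignment column")
    counts = Counter(column_residues)
    freq = np.zeros(N_RESIDUES)
    for symbol, n in counts.items():
        if symbol not in AA_INDEX:
            raise AlphabetError(f"symbol {symbol!r} is not a canonical amino acid")
        freq[AA_INDEX[symbol]] = n / len(column_residues)
    return freq


def apply_pseudocounts(raw: np.ndarray) -> np.ndarray:
    """Flat pseudo-counts: (f + 0.01) / 1.2 per residue.

    Requires ``raw`` to sum to 1 (within 1e-9); the result then sums to 1
    exactly up to floating point, since (1 + 20*0.01)/1.2 = 1.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (N_RESIDUES,):
        raise NormalizationError(f"frequency vector must have length {N_RESIDUES}")
    total = raw.sum()
    if abs(total - 1.0) > 1e-9:
        raise NormalizationError(f"raw frequencies sum to {total!r}, expected 1")
    return (raw + PSEUDOCOUNT) / PSEUDO_NORM


# ---------------------------------------------------------------------------
# Seed block input formats
# ---------------------------------------------------------------------------

#: catalytic annotations of the packaged GDSL seed
GDSL_CATALYTIC: dict[str, dict[int, str]] = {"I": {6: "S"}, "V": {4: "H"}}


def _parse_block_fasta(text: str) -> dict[str, list[str]]:
    """Aligned FASTA with ids ``<seed>|<block>``; one gap-free row per record."""
    rows: dict[str, list[str]] = {}
    header: str | None = None
    buf: list[str] = []

    def flush() -> None:
        if header is None:
            return
        ident = header.split()[0]
        if "|" not in ident:
            raise InputError(f"seed record id {ident!r} lacks a '|<block>' suffix")
        block_id = ident.rsplit("|", 1)[1]
        rows.setdefault(block_id, []).append("".join(buf).upper())

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:]
            buf = []
        else:
            if header is None:
                raise InputError("sequence data before the first FASTA header")
            buf.append(line)
    flush()
    if not rows:
        raise InputError("no seed records found")
    return rows


def _parse_block_text(text: str) -> dict[str, list[str]]:
    """Plain-text block file: sections headed by ``# <block id>`` lines,
    followed by one aligned row per line."""
    rows: dict[str, list[str]] = {}
    block_id: str | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            block_id = line.lstrip("#").strip()
            if not block_id:
                raise InputError(f"line {lineno}: empty block header")
            rows.setdefault(block_id, [])
        else:
            if block_id is None:
                raise InputError(f"line {lineno}: alignment row before any '# <block>' header")
            rows[block_id].append(line.upper())
    if not rows:
        raise InputError("no seed blocks found")
    return rows


def load_seed_blocks(
    path: str | Path | None = None,
    catalytic: Mapping[str, Mapping[int, str]] | None = None,
    order: Iterable[str] | None = None,
) -> list[BlockAlignment]:
    """Load a seed block alignment from FASTA or plain-text block format.

    With no ``path``, loads the packaged GDSL seed fixture — a synthetic
    stand-in alignment constructed to match the published GDSL block
    structure (23 rows; widths 10/9/9; fully conserved catalytic Ser at
    Block I column 6 and His at Block V column 4) — with its catalytic
    annotations applied by default.
    """
    if path is None:
        text = (
            resources.files("motifhmm.data")
            .joinpath("seed_blocks_synthetic.fasta")
            .read_text()
        )
        if catalytic is None:
            catalytic = GDSL_CATALYTIC
        if order is None:
            order = ("I", "III", "V")
    else:
        text = Path(path).read_text()
    if catalytic is None:
        catalytic = {}
    stripped = text.lstrip()
    parsed = _parse_block_fasta(text) if stripped.startswith(">") else _parse_block_text(text)
    block_ids = list(order) if order is not None else list(parsed)
    missing = [b for b in block_ids if b not in parsed]
    if missing:
        raise InputError(f"seed file lacks blocks {missing}; found {sorted(parsed)}")
    return [
        BlockAlignment(
            block_id=bid,
            rows=tuple(parsed[bid]),
            catalytic=dict(catalytic.get(bid, {})),
        )
        for bid in block_ids
    ]
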