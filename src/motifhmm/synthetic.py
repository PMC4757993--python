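"""Labelled synthetic proteomes with the statistical structure the scanner
assumes.

Positives are uniform-background sequences with one instance of each motif
block implanted in order, separated by gaps drawn from the configured range
(>= 20 residues by default, matching the annotation criterion).  Because the
background is uniform over the 20 residues — exactly the flat 0.05 insert
emission — background regions are score-neutral under the length-normalized
Viterbi score, and the zero threshold is exact on this data.

Decoy classes mirror the false-positive classes observed on real proteomes:
sequences with one block replaced by background ("missing block") and
sequences whose catalytic Ser/His is substituted ("catalytic mutant").  Both
are labelled negative.

Block instances are sampled column-wise from the model's own emission
distributions e_j(.); catalytic columns are set to the required consensus
residue and exempt from point mutation unless a catalytic mutant is being
generated.  What this emulates and what it deliberately does not (real
proteome composition, homology structure) is discussed in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .alphabet import AMINO_ACIDS, N_RESIDUES
from .exceptions import ConfigurationError
from .model import MotifHMM

_BACKGROUND = np.asarray(list(AMINO_ACIDS))


@dataclass(frozen=True)
class BenchmarkSpec:
    """Study conditions of one synthetic benchmark."""

    n_positives: int = 200
    n_negatives: int = 1000
    n_decoys_missing_block: int = 100
    n_decoys_catalytic_mutant: int = 20
    length_range: tuple[int, int] = (300, 500)
    gap_range: tuple[int, int] = (20, 60)
    mutation_rate: float = 0.05
    seed: int = 17

    def __post_init__(self) -> None:
        for name in ("n_positives", "n_negatives", "n_decoys_missing_block",
                     "n_decoys_catalytic_mutant"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ConfigurationError("mutation_rate must lie in [0, 1]")
        if self.gap_range[0] < 0 or self.gap_range[1] < self.gap_range[0]:
            raise ConfigurationError("invalid gap range")
        if self.length_range[1] < self.length_range[0]:
            raise ConfigurationError("invalid length range")

    def validate_for(self, hmm: MotifHMM) -> None:
        total = sum(hmm.block_widths)
        need = total + (len(hmm.block_ids) - 1) * self.gap_range[1] + 2
        if self.length_range[0] < need:
            raise ConfigurationError(
                f"minimum length {self.length_range[0]} cannot hold "
                f"{len(hmm.block_ids)} blocks ({total} residues) plus gaps "
                f"up to {self.gap_range[1]} and flanks; need >= {need}"
            )


def sample_block_instance(
    emissions: np.ndarray,
    mutation_rate: float,
    rng: np.random.Generator,
    catalytic: Mapping[int, str] | None = None,
    mutate_catalytic: bool = False,
) -> str:
    """Sample one block instance from per-column emission distributions.

    Each column is drawn from e_j(.); catalytic columns (1-based map column
    -> required residue) are set to the required residue instead.  Each
    residue is then point-mutated to a uniformly random *other* residue with
    probability ``mutation_rate``; catalytic columns are exempt unless
    ``mutate_catalytic`` (which forces their substitution, producing a
    catalytic-mutant decoy).
    """
    width = emissions.shape[0]
    catalytic = dict(catalytic or {})
    symbols = []
    for j in range(width):
        probs = emissions[j] / emissions[j].sum()
        symbols.append(_BACKGROUND[rng.choice(N_RESIDUES, p=probs)])
    for col, res in catalytic.items():
        symbols[col - 1] = res
    for j in range(width):
        is_cat = (j + 1) in catalytic
        if is_cat and not mutate_catalytic:
            continue
        if is_cat or rng.random() < mutation_rate:
            current = symbols[j]
            alternatives = [a for a in AMINO_ACIDS if a != current]
            symbols[j] = alternatives[rng.integers(len(alternatives))]
    return "".join(symbols)


@dataclass(frozen=True)
class BenchmarkRecord:
    id: str
    residues: str
    label: str                                  # "positive" / "negative"
    category: str                               # positive / background / missing_block / catalytic_mutant
    implants: dict[str, tuple[int, int]] = field(default_factory=dict)  # block -> (start, end), 1-based
    note: str = ""


@dataclass(frozen=True)
class Benchmark:
    spec: BenchmarkSpec
    records: tuple[BenchmarkRecord, ...]

    @property
    def truth(self) -> dict[str, str]:
        return {r.id: r.label for r in self.records}

    def write(self, directory: str | Path, prefix: str = "benchmark") -> dict[str, Path]:
        """Write FASTA plus the two tab-separated companions (labels,
        implant coordinates)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        fasta = directory / f"{prefix}.fasta"
        labels = directory / f"{prefix}.labels.tsv"
        coords = directory / f"{prefix}.implants.tsv"
        with fasta.open("w") as fh:
            for rec in self.records:
                fh.write(f">{rec.id}\n")
                for i in range(0, len(rec.residues), 60):
                    fh.write(rec.residues[i:i + 60] + "\n")
        with labels.open("w") as fh:
            for rec in self.records:
                fh.write(f"{rec.id}\t{rec.label}\n")
        with coords.open("w") as fh:
            fh.write("id\tcategory\tblock\tstart\tend\tnote\n")
            for rec in self.records:
                if not rec.implants:
                    fh.write(f"{rec.id}\t{rec.category}\t-\t-\t-\t{rec.note}\n")
                for bid, (start, end) in rec.implants.items():
                    fh.write(f"{rec.id}\t{rec.category}\t{bid}\t{start}\t{end}\t{rec.note}\n")
        return {"fasta": fasta, "labels": labels, "implants": coords}


def _background(rng: np.random.Generator, length: int) -> list[str]:
    return list(_BACKGROUND[rng.integers(N_RESIDUES, size=length)])


def _implanted_sequence(
    hmm: MotifHMM,
    spec: BenchmarkSpec,
    rng: np.random.Generator,
    drop_block: int | None = None,
    mutate_catalytic: bool = False,
) -> tuple[str, dict[str, tuple[int, int]], str]:
    """Background sequence with block instances implanted in order."""
    lo, hi = spec.length_range
    length = int(rng.integers(lo, hi + 1))
    n_blocks = len(hmm.block_ids)
    gaps = [int(rng.integers(spec.gap_range[0], spec.gap_range[1] + 1))
            for _ in range(n_blocks - 1)]
    total = sum(hmm.block_widths)
    leftover = length - total - sum(gaps)
    n_flank = int(rng.integers(1, leftover))  # >= 1 residue on each flank
    residues = _background(rng, length)
    implants: dict[str, tuple[int, int]] = {}
    pos = n_flank  # 0-based start of the next block
    note = ""
    for b, (bid, width) in enumerate(zip(hmm.block_ids, hmm.block_widths)):
        instance = sample_block_instance(
            hmm.block_emissions[b],
            spec.mutation_rate,
            rng,
            catalytic=hmm.catalytic.get(bid),
            mutate_catalytic=mutate_catalytic,
        )
        if drop_block == b:
            note = f"missing_block_{bid}"
        else:
            residues[pos:pos + width] = list(instance)
            implants[bid] = (pos + 1, pos + width)
        pos += width + (gaps[b] if b < n_blocks - 1 else 0)
    if mutate_catalytic:
        note = "catalytic_mutant"
    return "".join(residues), implants, note


def generate_benchmark(spec: BenchmarkSpec, hmm: MotifHMM) -> Benchmark:
    """Generate the labelled benchmark; identical spec + seed give identical
    output."""
    spec.validate_for(hmm)
    rng = np.random.default_rng(spec.seed)
    records: list[BenchmarkRecord] = []
    for i in range(spec.n_positives):
        seq, implants, note = _implanted_sequence(hmm, spec, rng)
        records.append(BenchmarkRecord(
            id=f"pos_{i + 1:04d}", residues=seq, label="positive",
            category="positive", implants=implants, note=note,
        ))
    for i in range(spec.n_negatives):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        records.append(BenchmarkRecord(
            id=f"neg_{i + 1:04d}", residues="".join(_background(rng, length)),
            label="negative", category="background",
        ))
    for i in range(spec.n_decoys_missing_block):
        drop = int(rng.integers(len(hmm.block_ids)))
        seq, implants, note = _implanted_sequence(hmm, spec, rng, drop_block=drop)
        records.append(BenchmarkRecord(
            id=f"decoy_block_{i + 1:04d}", residues=seq, label="negative",
            category="missing_block", implants=implants, note=note,
        ))
    for i in range(spec.n_decoys_catalytic_mutant):
        seq, implants, note = _implanted_sequence(hmm, spec, rng, mutate_catalytic=True)
        records.append(BenchmarkRecord(
            id=f"decoy_cat_{i + 1:04d}", residues=seq, label="negative",
            category="catalytic_mutant", implants=implants, note=note,
        ))
    return Benchmark(spec=spec, records=tuple(records))
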