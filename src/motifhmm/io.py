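"""File I/O and scanner configuration.

FASTA in (via Bio.SeqIO), tab-separated results out, YAML flat-key config.
All warnings go to the logging stream, never stdout.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import yaml
from Bio import SeqIO

from .exceptions import ConfigurationError, InputError
from .decoding import ProteinSequence
from .mutation import DEFAULT_SCALE
from .protocol import (
    AnnotationRecord,
    CONSECUTIVE_BOUND,
    MEAN_BOUND,
    MIN_BLOCK_GAP,
    SCORE_THRESHOLD,
)

logger = logging.getLogger(__name__)

MODES = ("vd", "pd", "pssm", "pdvd")


@dataclass
class ScannerConfig:
    """Scanner configuration; defaults are the published constants."""

    mode: str = "pdvd"
    threshold: float = SCORE_THRESHOLD
    mean_bound: float = MEAN_BOUND
    consecutive_bound: int = CONSECUTIVE_BOUND
    min_gap: int = MIN_BLOCK_GAP
    mutation_scale: float = DEFAULT_SCALE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}, got {self.mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScannerConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a flat key mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def read_fasta(path: str | Path) -> Iterator[ProteinSequence]:
    """Stream sequences from a FASTA file.

    Ids are the first whitespace-delimited header token; residues are
    uppercased with a trailing '*' stripped.  A sequence line before the
    first header is a parse error naming the line; an empty file yields an
    empty stream with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            if not text.startswith(">"):
                raise InputError(f"{path}:{lineno}: sequence data before the first header")
            break
        else:
            logger.warning("%s: empty FASTA file", path)
            return
    n = 0
    for record in SeqIO.parse(str(path), "fasta"):
        residues = str(record.seq).upper().rstrip("*")
        yield ProteinSequence(id=record.id, residues=residues)
        n += 1
    if n == 0:
        logger.warning("%s: empty FASTA file", path)


def read_labels(path: str | Path) -> dict[str, str]:
    """Two-column tab-separated truth file: id, label in {positive, negative}."""
    labels: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise InputError(f"{path}:{lineno}: expected 'id<TAB>label'")
        labels[parts[0].strip()] = parts[1].strip()
    return labels


RESULT_COLUMNS = (
    "id", "mode", "vd_score", "pd_total", "pssm_total",
    "block_starts", "block_ends",
    "blocks_present_in_order", "catalytic_ser_ok", "catalytic_his_ok",
    "min_gap_ok", "pdvd_ok", "borderline", "classification", "rank",
)


def _fmt(value: object) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "yes" if value else "no"
    if isinstance(value, float):
        return f"{value:.4f}"
    return str(value)


def write_results(
    records: Sequence[AnnotationRecord],
    path: str | Path,
    config: ScannerConfig | None = None,
    model_hash: str | None = None,
    timestamp: bool = True,
) -> Path:
    """Write the stable results TSV with a '#'-commented metadata header.

    Apart from the timestamp line, identical inputs produce identical bytes.
    """
    path = Path(path)
    lines = ["# motifhmm results"]
    if timestamp:
        lines.append(f"# written: {time.strftime('%Y-%m-%dT%H:%M:%S')}")
    if model_hash is not None:
        lines.append(f"# model: {model_hash}")
    if config is not None:
        cfg = " ".join(f"{k}={v}" for k, v in sorted(asdict(config).items()))
        lines.append(f"# config: {cfg}")
    lines.append("\t".join(RESULT_COLUMNS))
    mode = config.mode if config is not None else "-"
    for rec in records:
        block_ids = sorted(rec.block_positions, key=str)
        starts, ends = [], []
        for bid in block_ids:
            present = [p for p in rec.block_positions[bid] if p is not None]
            starts.append(f"{bid}:{min(present)}" if present else f"{bid}:NA")
            ends.append(f"{bid}:{max(present)}" if present else f"{bid}:NA")
        row = (
            rec.sequence_id, mode,
            _fmt(rec.vd_score), _fmt(rec.pd_total), _fmt(rec.pssm_total),
            ",".join(starts) or "NA", ",".join(ends) or "NA",
            _fmt(rec.blocks_present_in_order), _fmt(rec.catalytic_ser_ok),
            _fmt(rec.catalytic_his_ok), _fmt(rec.min_gap_ok), _fmt(rec.pdvd_ok),
            _fmt(rec.borderline), rec.classification, _fmt(rec.rank),
        )
        lines.append("\t".join(row))
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise InputError(f"cannot write results to {path}: {exc}") from exc
    return path
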