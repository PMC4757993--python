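"""Residue mutation model derived from a substitution score matrix.

The emission parameterization needs a row-stochastic matrix P = [p_ls] giving
the probability that residue l is observed as residue s after some amount of
evolutionary time.  We derive it from the BLOSUM50 score table with a single
scale parameter beta:

    p_ls  proportional to  2 ** (beta * score(l, s)),   rows normalized.

beta -> infinity concentrates each row on its maximum score (the diagonal for
BLOSUM50, i.e. the identity: no evolutionary time); beta -> 0 gives the
uniform matrix (infinite time).  The packaged default scale was calibrated
once so that the emissions assigned to fully conserved Ser and His columns
come as close as a single parameter allows to the anchor values 0.64 and
0.93; the His anchor is not reachable in this family (a fully conserved
column can emit its consensus with probability at most 1.01/1.2 ~ 0.84), so
calibration minimizes the summed squared deviation and reports the residuals
rather than asserting equality.  See :func:`calibrate_scale` and
``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from io import StringIO

import numpy as np
from scipy.optimize import minimize_scalar

from .alphabet import AMINO_ACIDS, N_RESIDUES, residue_index
from .blocks import PSEUDO_FLOOR, PSEUDO_NORM, PSEUDOCOUNT
from .exceptions import ConfigurationError

#: substitution tables packaged with the module (NCBI-format score tables)
_PACKAGED_MATRICES = {"BLOSUM50": "BLOSUM50.txt"}

#: anchor emissions for fully conserved catalytic columns (Ser, His)
CALIBRATION_ANCHORS: dict[str, float] = {"S": 0.64, "H": 0.93}

#: scale frozen from calibrate_scale() against the anchors above
DEFAULT_SCALE: float = 1.1507811


def load_score_matrix(source: str = "BLOSUM50") -> np.ndarray:
    """20x20 integer score table over the canonical alphabet, from the
    packaged NCBI-format file."""
    try:
        fname = _PACKAGED_MATRICES[source.upper()]
    except KeyError:
        raise ConfigurationError(
            f"unknown substitution matrix {source!r}; available: {sorted(_PACKAGED_MATRICES)}"
        ) from None
    from Bio.Align import substitution_matrices

    text = resources.files("motifhmm.data").joinpath(fname).read_text()
    mat = substitution_matrices.read(StringIO(text))
    out = np.empty((N_RESIDUES, N_RESIDUES))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            out[i, j] = mat[a][b]
    return out


@dataclass(frozen=True)
class CalibrationReport:
    """Outcome of scale calibration against conserved-column anchors."""

    scale: float
    anchors: dict[str, float]
    achieved: dict[str, float]
    residuals: dict[str, float]
    sse: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        parts = [f"scale={self.scale:.6f}"]
        for res, target in self.anchors.items():
            parts.append(
                f"{res}: achieved={self.achieved[res]:.4f} target={target:.4f} "
                f"residual={self.residuals[res]:+.4f}"
            )
        return "; ".join(parts)


@dataclass(frozen=True)
class MutationModel:
    """Row-stochastic residue mutation matrix with its provenance."""

    matrix: np.ndarray
    source: str = "BLOSUM50"
    scale: float = DEFAULT_SCALE
    calibration_report: CalibrationReport | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (N_RESIDUES, N_RESIDUES):
            raise ConfigurationError("mutation matrix must be 20x20")
        if not np.all(m > 0):
            raise ConfigurationError("mutation matrix entries must be strictly positive")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("mutation matrix rows must sum to 1")


def build_mutation_matrix(
    source: str = "BLOSUM50",
    scale: float = DEFAULT_SCALE,
    calibrate: bool = False,
) -> MutationModel:
    """Build the mutation model p_ls ~ 2**(scale * score(l, s)), row-normalized.

    ``calibrate=True`` ignores ``scale`` and re-runs anchor calibration,
    attaching the resulting :class:`CalibrationReport`.
    """
    if calibrate:
        report = calibrate_scale(source)
        scale = report.scale
    else:
        report = None
    if scale <= 0:
        raise ConfigurationError("scale must be > 0")
    matrix = _stochastic_matrix(load_score_matrix(source), scale)
    return MutationModel(matrix=matrix, source=source.upper(), scale=scale, calibration_report=report)


def _stochastic_matrix(scores: np.ndarray, scale: float) -> np.ndarray:
    # subtract the row max before exponentiating for numerical stability
    z = scale * scores
    z = z - z.max(axis=1, keepdims=True)
    p = np.exp2(z)
    return p / p.sum(axis=1, keepdims=True)


def conserved_column_emission(matrix: np.ndarray, residue: str) -> float:
    """Emission probability of ``residue`` in a column fully conserved for it.

    The pseudo-counted frequency vector of a fully conserved column puts
    (1 + 0.01)/1.2 on the consensus and 0.01/1.2 elsewhere; the emission is
    that vector pushed through the mutation matrix.
    """
    k = residue_index(residue)
    fhat = np.full(N_RESIDUES, PSEUDO_FLOOR)
    fhat[k] = (1.0 + PSEUDOCOUNT) / PSEUDO_NORM
    return float(fhat @ matrix[:, k])


def calibrate_scale(
    source: str = "BLOSUM50",
    anchors: dict[str, float] | None = None,
    bounds: tuple[float, float] = (0.05, 5.0),
) -> CalibrationReport:
    """Choose the scale minimizing the summed squared deviation of conserved-
    column emissions from their anchor values."""
    if anchors is None:
        anchors = dict(CALIBRATION_ANCHORS)
    scores = load_score_matrix(source)

    def sse(beta: float) -> float:
        m = _stochastic_matrix(scores, beta)
        return sum((conserved_column_emission(m, r) - t) ** 2 for r, t in anchors.items())

    res = minimize_scalar(sse, bounds=bounds, method="bounded", options={"xatol": 1e-8})
    scale = float(res.x)
    m = _stochastic_matrix(scores, scale)
    achieved = {r: conserved_column_emission(m, r) for r in anchors}
    residuals = {r: achieved[r] - anchors[r] for r in anchors}
    return CalibrationReport(
        scale=scale,
        anchors=dict(anchors),
        achieved=achieved,
        residuals=residuals,
        sse=float(res.fun),
    )
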