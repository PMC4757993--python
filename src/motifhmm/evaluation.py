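"""Confusion counts, sensitivity and false discovery proportion.

When the overwhelming majority of scanned sequences are negatives,
specificity (TN/N) is insensitive to the number of false positives, so the
headline metrics are

    sensitivity  S   = TP / (TP + FN)
    false discovery  FDP = FP / (FP + TP)

Ratios with zero denominators are reported as not-applicable (``None``),
never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .exceptions import LabellingError

POSITIVE_LABELS = {"positive", "pos", "1", "true"}
NEGATIVE_LABELS = {"negative", "neg", "0", "false"}


def _as_bool(value: object, what: str) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in POSITIVE_LABELS:
        return True
    if text in NEGATIVE_LABELS:
        return False
    raise LabellingError(f"unrecognized {what} {value!r}")


@dataclass(frozen=True)
class EvaluationSummary:
    """TP/FP/FN/TN counts with sensitivity and FDP."""

    tp: int
    fp: int
    fn: int
    tn: int = 0

    @property
    def sensitivity(self) -> float | None:
        """TP / (TP + FN), or None when no labelled positives exist."""
        denom = self.tp + self.fn
        return None if denom == 0 else self.tp / denom

    @property
    def fdp(self) -> float | None:
        """FP / (FP + TP), or None when nothing was called positive."""
        denom = self.fp + self.tp
        return None if denom == 0 else self.fp / denom

    @property
    def sensitivity_pct(self) -> float | None:
        return None if self.sensitivity is None else round(100.0 * self.sensitivity, 1)

    @property
    def fdp_pct(self) -> float | None:
        return None if self.fdp is None else round(100.0 * self.fdp, 1)

    def __add__(self, other: "EvaluationSummary") -> "EvaluationSummary":
        return EvaluationSummary(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
            tn=self.tn + other.tn,
        )

    def __str__(self) -> str:
        fmt = lambda v: "n/a" if v is None else f"{v:.1f} %"
        return (
            f"TP={self.tp} FP={self.fp} FN={self.fn} TN={self.tn} "
            f"S={fmt(self.sensitivity_pct)} FDP={fmt(self.fdp_pct)}"
        )


def confusion_metrics(
    predictions: Mapping[str, object],
    truth: Mapping[str, object],
) -> EvaluationSummary:
    """Confusion counts of a labelled scan.

    ``predictions`` maps sequence id to the predicted class (bool or a
    positive/negative label); ``truth`` likewise.  Every predicted id must
    carry a truth label.
    """
    tp = fp = fn = tn = 0
    for seq_id, pred in predictions.items():
        if seq_id not in truth:
            raise LabellingError(f"sequence {seq_id!r} has no truth label")
        p = _as_bool(pred, "prediction")
        t = _as_bool(truth[seq_id], "truth label")
        if p and t:
            tp += 1
        elif p:
            fp += 1
        elif t:
            fn += 1
        else:
            tn += 1
    return EvaluationSummary(tp=tp, fp=fp, fn=fn, tn=tn)
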