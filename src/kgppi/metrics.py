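"""Confusion-matrix bookkeeping and binary-classification metrics.

The evaluation harness used throughout the pipeline: sensitivity,
specificity, precision, accuracy, F1 and the Matthews correlation
coefficient (MCC), all computed from the four confusion-matrix cells.
MCC is the headline metric because it stays informative on imbalanced
pair sets where accuracy saturates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

logger = logging.getLogger(__name__)

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "mcc", "report"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of true/false positives and negatives."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise TypeError(f"{name} must be an integer, got {value!r}")
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The six derived metrics; proportions in [0, 1], MCC in [-1, 1]."""

    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    f1: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "mcc": self.mcc,
        }


def confusion(predictions: Sequence[int], truth: Sequence[int]) -> ConfusionMatrix:
    """Tally a confusion matrix from two equal-length binary label vectors."""
    if len(predictions) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs {len(truth)} truths"
        )
    tp = tn = fp = fn = 0
    for pred, true in zip(predictions, truth):
        if pred not in (0, 1) or true not in (0, 1):
            raise ValueError(f"labels must be binary 0/1, got pred={pred!r} true={true!r}")
        if true == 1:
            if pred == 1:
                tp += 1
            else:
                fn += 1
        else:
            if pred == 1:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("degenerate denominator for %s; reporting 0", name)
        return 0.0
    return num / den


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient.

    (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)); defined as 0
    when any factor of the denominator vanishes (single-class input).
    """
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    factors = [tp + fp, tp + fn, tn + fp, tn + fn]
    if any(f == 0 for f in factors):
        return 0.0
    # integer arithmetic in the numerator avoids overflow/rounding at scale
    num = tp * tn - fp * fn
    den = math.sqrt(math.prod(float(f) for f in factors))
    return num / den


def report(cm: ConfusionMatrix) -> MetricsReport:
    """Compute all six metrics; ratios with a zero denominator report 0."""
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    return MetricsReport(
        sensitivity=_safe_ratio(tp, tp + fn, "sensitivity"),
        specificity=_safe_ratio(tn, tn + fp, "specificity"),
        precision=_safe_ratio(tp, tp + fp, "precision"),
        accuracy=_safe_ratio(tp + tn, cm.total, "accuracy"),
        f1=_safe_ratio(2 * tp, 2 * tp + fp + fn, "f1"),
        mcc=mcc(cm),
    )
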