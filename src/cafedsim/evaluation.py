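"""Confusion-matrix metrics and run-log summaries.

Precision, recall, F-measure and accuracy follow the standard binary
definitions, with the depression class as positive:

    precision = TP / (TP + FP)        recall = TP / (TP + FN)
    F = 2 P R / (P + R)               accuracy = (TP + TN) / total

Metrics are reported in percent; display formatting rounds half-up to two
decimals (the convention of the published result tables), while raw values
keep full precision.  A zero denominator yields an explicit ``None``
("undefined"), never a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "Metrics",
    "confusion_from_predictions",
    "metrics",
    "f_measure",
    "format_percent",
    "epochs_to_accuracy",
    "communication_summary",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for field in ("tp", "fp", "fn", "tn"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Metrics:
    """Percent-scale metrics; ``None`` marks an undefined ratio."""

    precision: Optional[float]
    recall: Optional[float]
    f_measure: Optional[float]
    accuracy: Optional[float]

    def formatted(self) -> dict[str, Optional[str]]:
        return {
            "precision": format_percent(self.precision),
            "recall": format_percent(self.recall),
            "f_measure": format_percent(self.f_measure),
            "accuracy": format_percent(self.accuracy),
        }


def format_percent(value: Optional[float]) -> Optional[str]:
    """Half-up rounding to two decimals, e.g. 93.333... -> '93.33'."""
    if value is None:
        return None
    return str(Decimal(repr(float(value))).quantize(Decimal("0.01"), ROUND_HALF_UP))


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else 100.0 * num / den


def f_measure(precision: Optional[float], recall: Optional[float]) -> Optional[float]:
    """Harmonic mean of precision and recall (percent in, percent out)."""
    if precision is None or recall is None or precision + recall == 0:
        return None
    return 2.0 * precision * recall / (precision + recall)


def metrics(cm: ConfusionMatrix) -> Metrics:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    p = _ratio(cm.tp, cm.tp + cm.fp)
    r = _ratio(cm.tp, cm.tp + cm.fn)
    return Metrics(
        precision=p,
        recall=r,
        f_measure=f_measure(p, r),
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
    )


def confusion_from_predictions(y_true, y_pred) -> ConfusionMatrix:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label/prediction length mismatch")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def epochs_to_accuracy(log, target: float) -> Optional[int]:
    """First global-epoch index whose test accuracy reaches ``target``.

    ``target`` is on the 0–1 scale.  Returns ``None`` if the log never
    reaches it.  Epochs count applied global updates, so this is directly
    comparable across synchronous and asynchronous trainers.
    """
    for row in log.metrics:
        acc = row.get("test_accuracy")
        if acc is not None and acc >= target:
            return int(row["epoch"])
    return None


def communication_summary(log) -> dict[str, int]:
    """Exact event counts: uploads (accepted pushes), downloads (pulls),
    drops (gated-out pushes) and applied global updates."""
    uploads = downloads = drops = updates = 0
    for event in log.events:
        kind = event["kind"]
        if kind == "pull":
            downloads += 1
        elif kind == "push_attempt" and event["payload"].get("accepted"):
            uploads += 1
        elif kind == "drop":
            drops += 1
        elif kind == "global_update":
            updates += 1
    return {"uploads": uploads, "downloads": downloads, "drops": drops, "updates": updates}
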