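"""Confusion counts and murmur-detection quality metrics.

"True Positive" means truly present, "True Negative" truly absent.
Alongside the standard derived rates (sensitivity, specificity, PPV,
NPV, accuracy), two composite scores are used in heart-sound screening:

* F-Score = 2 * PPV * Sensitivity / (PPV + Sensitivity)
* Weighted Accuracy = (5*TP + TN) / (5*TP + FN + FP + TN), the
  PhysioNet 2022 metric weighting true positives five-fold because a
  missed murmur costs far more than a false alarm.

Metrics with an undefined denominator are flagged as undefined (None)
rather than silently zeroed, so averages over repeated runs stay honest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "f_score",
    "weighted_accuracy",
    "report",
    "aggregate_reports",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Derived metrics; entries are None when their denominator is zero."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None
    f_score: float | None
    weighted_accuracy: float | None
    undefined: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Tally TP/FP/TN/FN from present/absent label vectors."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        bad = sorted(set(arr) - {"present", "absent"})
        if bad:
            raise ValueError(f"{name}: unknown labels {bad}")
    pos_t, pos_p = y_true == "present", y_pred == "present"
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def f_score(ppv: float, sensitivity: float) -> float:
    """Harmonic mean of positive predictive value and sensitivity."""
    if ppv == 0 and sensitivity == 0:
        raise ZeroDivisionError("f_score undefined: PPV and sensitivity both zero")
    return 2.0 * ppv * sensitivity / (ppv + sensitivity)


def weighted_accuracy(c: ConfusionCounts, weight: float = 5.0) -> float:
    """(w*TP + TN) / (w*TP + FN + FP + TN); the screening metric uses w=5.

    At weight 1 this reduces to plain accuracy.
    """
    denom = weight * c.tp + c.fn + c.fp + c.tn
    if denom == 0:
        raise ZeroDivisionError("weighted accuracy undefined: all counts zero")
    return (weight * c.tp + c.tn) / denom


def report(c: ConfusionCounts) -> MetricsReport:
    """All metrics from one confusion matrix, with undefined-denominator flags."""
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    undefined = []

    def ratio(num, denom, name):
        if denom == 0:
            undefined.append(name)
            return None
        return num / denom

    sens = ratio(c.tp, c.tp + c.fn, "sensitivity")
    spec = ratio(c.tn, c.tn + c.fp, "specificity")
    ppv = ratio(c.tp, c.tp + c.fp, "ppv")
    npv = ratio(c.tn, c.tn + c.fn, "npv")
    acc = (c.tp + c.tn) / c.total
    if ppv is None or sens is None or (ppv == 0 and sens == 0):
        undefined.append("f_score")
        f = None
    else:
        f = f_score(ppv, sens)
    wacc = weighted_accuracy(c)
    return MetricsReport(
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        accuracy=acc, f_score=f, weighted_accuracy=wacc, undefined=undefined,
    )


def aggregate_reports(reports: list) -> dict:
    """Mean and standard deviation of each metric over repeated runs.

    Undefined values are dropped per metric; the count of contributing
    runs is recorded alongside.
    """
    out = {}
    names = ["sensitivity", "specificity", "ppv", "npv", "accuracy", "f_score", "weighted_accuracy"]
    for name in names:
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        out[name] = {
            "mean": float(np.mean(vals)) if vals else None,
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0 if vals else None,
            "n": len(vals),
        }
    return out
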