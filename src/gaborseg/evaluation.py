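"""Segmentation accuracy metrics and ROC analysis.

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy =
(TP+TN)/total, evaluated over pixels inside the field of view (the DRIVE
convention). The ROC curve plots the true-positive fraction against the
false-positive fraction over all score thresholds; its area A_z is
computed by the trapezoid rule with tied scores collapsed into single
steps, and equals the Mann–Whitney U statistic divided by n₁·n₀.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["ConfusionCounts", "RocCurve", "confusion", "metrics", "roc",
           "youden_threshold", "format_report_table", "report_json"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class RocCurve:
    """Ordered ROC points, thresholds descending from +inf; az = area."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    az: float

    def __post_init__(self):
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC curve must be nondecreasing")


def confusion(pred, truth) -> ConfusionCounts:
    pred = np.asarray(pred).astype(bool).ravel()
    truth = np.asarray(truth).astype(bool).ravel()
    if pred.size == 0:
        raise ValueError("empty inputs")
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: pred {pred.size} vs truth {truth.size}")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    tn = int(np.sum(~pred & ~truth))
    fn = int(np.sum(~pred & truth))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy); an undefined ratio is NaN with a warning."""
    if c.total == 0:
        raise ValueError("all confusion counts are zero")
    if c.tp + c.fn > 0:
        sens = c.tp / (c.tp + c.fn)
    else:
        warnings.warn("no positive instances; sensitivity undefined", stacklevel=2)
        sens = float("nan")
    if c.tn + c.fp > 0:
        spec = c.tn / (c.tn + c.fp)
    else:
        warnings.warn("no negative instances; specificity undefined", stacklevel=2)
        spec = float("nan")
    acc = (c.tp + c.tn) / c.total
    return sens, spec, acc


def roc(scores, truth) -> RocCurve:
    """ROC curve over all distinct score thresholds, plus the (0,0)/(1,1) endpoints.

    Tied scores collapse into a single step. The area is the trapezoidal
    integral of TPR over FPR, identical (to rounding) to the probability
    that a random vessel pixel outscores a random background pixel.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth).astype(bool).ravel()
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal length")
    if truth.all() or not truth.any():
        raise ValueError("ROC requires both classes present in the truth labels")
    fpr, tpr, thresholds = _sk_roc_curve(truth.astype(int), scores,
                                         drop_intermediate=False)
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:   # guard; sklearn always ends at (1,1)
        fpr = np.append(fpr, 1.0)
        tpr = np.append(tpr, 1.0)
        thresholds = np.append(thresholds, -np.inf)
    az = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, az=az)


def youden_threshold(curve: RocCurve) -> float:
    """Operating threshold maximizing Youden's J = TPR − FPR.

    Ties go to the higher threshold (more specific operating point). The
    +inf endpoint is excluded so the returned cut is attainable.
    """
    j = curve.tpr - curve.fpr
    j[0] = -np.inf   # skip the (0,0) endpoint with threshold +inf
    return float(curve.thresholds[int(np.argmax(j))])


# --- reporting -------------------------------------------------------------

def format_report_table(rows: dict[str, tuple[float, float, float]]) -> str:
    """Plain-text metrics table: Specificity, Overall Accuracy, Sensitivity (%).

    ``rows`` maps a classifier label to (sensitivity, specificity, accuracy)
    on the [0, 1] scale.
    """
    lines = [f"{'Classifier':<12}{'Specificity':>12}{'Overall Accuracy':>18}{'Sensitivity':>13}"]
    for name, (sens, spec, acc) in rows.items():
        lines.append(f"{name:<12}{100 * spec:>12.1f}{100 * acc:>18.1f}{100 * sens:>13.1f}")
    return "\n".join(lines)


def report_json(rows: dict[str, dict]) -> str:
    return json.dumps(rows, indent=2, sort_keys=True)
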