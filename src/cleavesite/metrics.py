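"""Confusion-matrix metrics, ROC curves and AUC.

Eight evaluation parameters per classifier: accuracy, precision,
recall (sensitivity), false-positive rate, specificity, F1, F2, and
AUC. All are reported as percentages rounded to two decimals; internal
computation stays at full precision. Ratios with a zero denominator are
reported as missing (None) with a warning, never silently as 0.

Threshold convention: score >= threshold predicts positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

METRIC_NAMES = ("accuracy", "precision", "recall", "fpr", "specificity", "f1", "f2", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != scores.shape:
        raise ValueError("labels and scores differ in length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def f_beta(precision: float, recall: float, beta: float) -> float:
    """F-beta on proportions: (1 + b^2) P R / (b^2 P + R)."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must be proportions in [0, 1]")
    if precision == 0 and recall == 0:
        raise ValueError("F-beta undefined for precision = recall = 0")
    b2 = beta * beta
    return (1 + b2) * precision * recall / (b2 * precision + recall)


def roc_points(labels, scores) -> list:
    """ROC as ordered (fpr, tpr) pairs; thresholds swept over distinct scores.

    Tied scores move together, so the trapezoidal area equals the
    Mann-Whitney rank statistic with tie correction.
    """
    labels = np.asarray(labels)
    if len(set(np.unique(labels))) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, dtype=float))
    pts = list(zip(fpr.tolist(), tpr.tolist()))
    if pts[0] != (0.0, 0.0):
        pts.insert(0, (0.0, 0.0))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


def auc_from_points(points) -> float:
    xs, ys = zip(*points)
    return float(_trapezoid_auc(np.asarray(xs), np.asarray(ys)))


def _ratio(num: int, den: int, name: str) -> Optional[float]:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as missing")
        return None
    return num / den


def _pct(x: Optional[float]) -> Optional[float]:
    return None if x is None else 100.0 * x


@dataclass
class EvalReport:
    """The 8-metric report for one model on one evaluation surface.

    Metric fields are percentages at full precision (round for display);
    ``surface`` records what was evaluated: the 30% holdout, a CV fold,
    or a CV aggregate.
    """

    model_id: str
    surface: str
    counts: Optional[ConfusionCounts] = None
    accuracy: Optional[float] = None
    precision: Optional[float] = None
    recall: Optional[float] = None
    fpr: Optional[float] = None
    specificity: Optional[float] = None
    f1: Optional[float] = None
    f2: Optional[float] = None
    auc: Optional[float] = None
    roc: list = field(default_factory=list)
    seed: Optional[int] = None

    def metric_dict(self, ndigits: int = 2) -> dict:
        return {
            m: (None if getattr(self, m) is None else round(getattr(self, m), ndigits))
            for m in METRIC_NAMES
        }


def metric_suite(
    labels,
    scores,
    threshold: float = 0.5,
    model_id: str = "",
    surface: str = "holdout",
    seed: Optional[int] = None,
) -> EvalReport:
    """Compute all eight metrics from labels and scores at a threshold."""
    c = confusion_counts(labels, scores, threshold)
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    recall = _ratio(c.tp, c.tp + c.fn, "recall")
    fpr = _ratio(c.fp, c.fp + c.tn, "fpr")
    f1 = f2 = None
    if precision is not None and recall is not None and (precision, recall) != (0.0, 0.0):
        f1 = f_beta(precision, recall, 1.0)
        f2 = f_beta(precision, recall, 2.0)
    pts = roc_points(labels, scores)
    return EvalReport(
        model_id=model_id,
        surface=surface,
        counts=c,
        accuracy=_pct(_ratio(c.tp + c.tn, c.total, "accuracy")),
        precision=_pct(precision),
        recall=_pct(recall),
        fpr=_pct(fpr),
        specificity=None if fpr is None else 100.0 - _pct(fpr),
        f1=_pct(f1),
        f2=_pct(f2),
        auc=_pct(auc_from_points(pts)),
        roc=pts,
        seed=seed,
    )


def mean_report(reports, model_id: str, surface: str = "cv_mean") -> EvalReport:
    """Average metric values over per-fold reports (missing values skipped)."""
    agg = {}
    for m in METRIC_NAMES:
        vals = [getattr(r, m) for r in reports if getattr(r, m) is not None]
        agg[m] = float(np.mean(vals)) if vals else None
    return EvalReport(model_id=model_id, surface=surface, **agg)
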