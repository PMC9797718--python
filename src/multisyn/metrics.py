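"""Regression and classification performance metrics.

Regression: MSE, RMSE and the coefficient of determination R².
Classification: sensitivity, specificity, accuracy and Matthews correlation
coefficient from a confusion table, plus trapezoidal ROC/AUC.  Metrics with
a zero denominator are reported as flagged-undefined (NaN plus an entry in
``undefined``) rather than silently coerced to 0, so aggregate tables
cannot average them away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve

__all__ = [
    "RegressionScores",
    "ConfusionCounts",
    "ClassificationScores",
    "regression_scores",
    "confusion_counts",
    "classification_scores",
    "roc_auc",
]


@dataclass(frozen=True)
class RegressionScores:
    mse: float
    rmse: float
    r2_score: float


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValueError("confusion table is empty")


@dataclass(frozen=True)
class ClassificationScores:
    sen: float
    spe: float
    acc: float
    mcc: float
    auc: float = float("nan")
    undefined: frozenset[str] = field(default_factory=frozenset)


def regression_scores(y_true, y_pre) -> RegressionScores:
    """MSE, RMSE and R² of predictions against observed values."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pre = np.asarray(y_pre, dtype=float).ravel()
    if y_true.shape != y_pre.shape or y_true.size < 2:
        raise ValueError("y_true and y_pre must have equal length >= 2")
    if not (np.isfinite(y_true).all() and np.isfinite(y_pre).all()):
        raise ValueError("inputs must be finite")
    mse = float(np.mean((y_true - y_pre) ** 2))
    ss_tot = float(np.mean((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("y_true is constant; R² is undefined")
    return RegressionScores(mse=mse, rmse=float(np.sqrt(mse)), r2_score=1.0 - mse / ss_tot)


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).ravel().astype(int)
    y_pred = np.asarray(y_pred).ravel().astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def classification_scores(counts: ConfusionCounts) -> ClassificationScores:
    """SEN, SPE, ACC, MCC from a confusion table; zero denominators are flagged."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    undefined: set[str] = set()

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.add(name)
            return float("nan")
        return num / den

    sen = ratio(tp, tp + fn, "sen")
    spe = ratio(tn, fp + tn, "spe")
    acc = (tp + tn) / (tp + fn + fp + tn)
    mcc_den = np.sqrt(float(tp + fn) * (tp + fp) * (tn + fn) * (tn + fp))
    if mcc_den == 0:
        undefined.add("mcc")
        mcc = float("nan")
    else:
        mcc = float(tp * tn - fp * fn) / float(mcc_den)
    return ClassificationScores(sen=sen, spe=spe, acc=acc, mcc=mcc, undefined=frozenset(undefined))


def roc_auc(labels, scores) -> tuple[float, np.ndarray]:
    """Trapezoidal AUC and ROC points (fpr, tpr, threshold).

    Equals the rank statistic: the probability that a random positive
    outscores a random negative, ties counted half.
    """
    labels = np.asarray(labels).ravel().astype(int)
    scores = np.asarray(scores, dtype=float).ravel()
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    points = np.column_stack([fpr, tpr, thr])
    return auc, points
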