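"""Classification metrics for imbalanced binary problems.

Implements the study's metric suite directly from the confusion counts:
accuracy, Matthews correlation coefficient, root-mean-squared error, F-score
(F1), plus the ROC curve and its trapezoidal AUC on the positive-class
probability. The positive class (label 1) is the minority/patient class
throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_curve

from .data_io import LabeledDataset


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.total == 0:
            raise ValueError("confusion counts must describe at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, labels: np.ndarray, predicted: np.ndarray) -> "ConfusionCounts":
        labels = np.asarray(labels, dtype=int)
        predicted = np.asarray(predicted, dtype=int)
        if labels.shape != predicted.shape:
            raise ValueError("labels and predictions must have equal length")
        return cls(
            tp=int(((labels == 1) & (predicted == 1)).sum()),
            tn=int(((labels == 0) & (predicted == 0)).sum()),
            fp=int(((labels == 0) & (predicted == 1)).sum()),
            fn=int(((labels == 1) & (predicted == 0)).sum()),
        )


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + FN + TN + FP)."""
    return (c.tp + c.tn) / c.total


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0.

    (TP·TN − FP·FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)); ranges over
    [−1, 1] with 1 a perfectly correct and −1 a fully inverted classifier.
    """
    denom = (c.tp + c.fn) * (c.tn + c.fp) * (c.tp + c.fp) * (c.tn + c.fn)
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def rmse(targets: np.ndarray, predictions: np.ndarray) -> float:
    """sqrt(mean((x_i - y_i)^2)) over targets x and predictions y."""
    targets = np.asarray(targets, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if targets.shape != predictions.shape or targets.size == 0:
        raise ValueError("targets and predictions must be equal-length and nonempty")
    return float(np.sqrt(np.mean((targets - predictions) ** 2)))


def f_score(c: ConfusionCounts) -> float:
    """F1 = 2·P·R / (P + R) with P = TP/(TP+FP), R = TP/(TP+FN); 0 if TP = 0."""
    if c.tp == 0:
        return 0.0
    precision = c.tp / (c.tp + c.fp)
    recall = c.tp / (c.tp + c.fn)
    return 2 * precision * recall / (precision + recall)


def recall(c: ConfusionCounts) -> float:
    """Sensitivity on the positive (minority) class; 0 if no positives."""
    if c.tp + c.fn == 0:
        return 0.0
    return c.tp / (c.tp + c.fn)


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> tuple[float, list[tuple[float, float]]]:
    """ROC curve (thresholds at every distinct score) and trapezoidal AUC.

    Returns (auc, [(fpr, tpr), ...]) with the curve starting at (0, 0) and
    ending at (1, 1); tied scores share a threshold.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes in the labels")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


@dataclass
class EvaluationReport:
    """Full metric report for one model on one test set."""

    counts: ConfusionCounts
    accuracy: float
    mcc: float
    rmse: float
    f_score: float
    auc: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "counts": {"tp": self.counts.tp, "tn": self.counts.tn,
                       "fp": self.counts.fp, "fn": self.counts.fn},
            "accuracy": round(self.accuracy, 6),
            "mcc": round(self.mcc, 6),
            "rmse": round(self.rmse, 6),
            "f1": round(self.f_score, 6),
            "auc": round(self.auc, 6),
            "roc": [[round(x, 6), round(y, 6)] for x, y in self.roc_points],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def evaluate(model, test: LabeledDataset, rmse_on_proba: bool = False) -> EvaluationReport:
    """Score a fitted model on a test set.

    The model must expose ``predict(features)``; probability-aware models
    (``predict_proba``) contribute a positive-class score for the ROC curve,
    otherwise the hard labels are used as scores. RMSE is computed on hard
    labels by default, on positive-class probabilities with
    ``rmse_on_proba=True``.
    """
    predicted = np.asarray(model.predict(test.features))
    if hasattr(model, "predict_proba"):
        scores = np.asarray(model.predict_proba(test.features))[:, 1]
    else:
        scores = predicted.astype(float)
    counts = ConfusionCounts.from_predictions(test.labels, predicted)
    auc, points = roc_auc(test.labels, scores)
    err = rmse(test.labels, scores if rmse_on_proba else predicted)
    return EvaluationReport(
        counts=counts,
        accuracy=accuracy(counts),
        mcc=mcc(counts),
        rmse=err,
        f_score=f_score(counts),
        auc=auc,
        roc_points=points,
    )
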