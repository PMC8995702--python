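"""ROC analysis, Youden cutoff selection and confusion-matrix metrics.

The ROC curve is swept over the unique score values (ties advance both
rates simultaneously), so the trapezoidal area equals the Mann-Whitney
probability that a random positive outscores a random negative (ties count
half).  The operating cutoff maximizes Youden's J = sensitivity +
specificity − 1, breaking ties toward higher specificity; prediction calls
``score >= cutoff`` positive.

:class:`ThresholdScoreClassifier` wraps the whole procedure as a
scikit-learn classifier: ``fit`` computes the ROC, AUC and Youden cutoff on
a 1-D score, ``predict`` thresholds new scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "RocResult",
    "roc_curve",
    "youden_cutoff",
    "confusion_metrics",
    "ThresholdScoreClassifier",
]


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    cutoff: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None

    @property
    def roc_points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


def _check_scores_labels(scores, labels, positive_label) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, float).ravel()
    y = np.asarray(labels).ravel()
    if len(s) != len(y):
        raise ValueError("scores and labels must have equal length")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {len(classes)}")
    if positive_label is None:
        positive_label = classes[1]
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} absent from labels")
    ybin = (y == positive_label).astype(int)
    if ybin.all() or not ybin.any():
        raise ValueError("both classes must be present")
    return s, ybin


def roc_curve(scores, labels, positive_label=None) -> RocResult:
    """ROC points and trapezoidal AUC of a scalar score against binary labels."""
    s, y = _check_scores_labels(scores, labels, positive_label)
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(auc=auc, fpr=fpr, tpr=tpr, thresholds=thr)


def youden_cutoff(roc: RocResult) -> tuple[float, float, float]:
    """(cutoff, sensitivity, specificity) maximizing Youden's J.

    Ties in J are broken toward higher specificity (lower false-positive
    rate).  The returned cutoff is a score value; ``score >= cutoff``
    predicts positive.  A cutoff of +inf predicts all-negative.
    """
    j = roc.tpr - roc.fpr
    best = np.flatnonzero(j == j.max())
    idx = best[np.argmin(roc.fpr[best])]
    cutoff = float(roc.thresholds[idx])
    roc.cutoff = cutoff
    roc.sensitivity = float(roc.tpr[idx])
    roc.specificity = float(1.0 - roc.fpr[idx])
    return cutoff, roc.sensitivity, roc.specificity


def confusion_metrics(scores, labels, cutoff: float, positive_label=None) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) of thresholding at ``cutoff``."""
    s, y = _check_scores_labels(scores, labels, positive_label)
    pred = (s >= cutoff).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    accuracy = (tp + tn) / len(y)
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    return accuracy, sensitivity, specificity


class ThresholdScoreClassifier(BaseEstimator, ClassifierMixin):
    """Binary classifier thresholding a scalar score at the Youden cutoff.

    Parameters
    ----------
    positive_label : optional
        Which class is "positive" (e.g. post-operative/inflamed).  Defaults
        to the second class in sorted order.

    Fitted attributes
    -----------------
    classes_, roc_result_, auc_, cutoff_, sensitivity_, specificity_,
    accuracy_ (resubstitution accuracy at the fitted cutoff).
    """

    def __init__(self, positive_label=None):
        self.positive_label = positive_label

    @staticmethod
    def _flatten(X) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X.ravel()
        if X.ndim != 1:
            raise ValueError("expected a 1-D score (or an (n, 1) column)")
        return X

    def fit(self, X, y):
        s = self._flatten(X)
        y = np.asarray(y).ravel()
        self.classes_ = np.unique(y)
        pos = self.positive_label if self.positive_label is not None else self.classes_[1]
        roc = roc_curve(s, y, positive_label=pos)
        cutoff, sens, spec = youden_cutoff(roc)
        acc, _, _ = confusion_metrics(s, y, cutoff, positive_label=pos)
        roc.accuracy = acc
        self.positive_label_ = pos
        self.roc_result_ = roc
        self.auc_ = roc.auc
        self.cutoff_ = cutoff
        self.sensitivity_ = sens
        self.specificity_ = spec
        self.accuracy_ = acc
        return self

    def predict(self, X):
        s = self._flatten(X)
        neg = self.classes_[self.classes_ != self.positive_label_][0]
        return np.where(s >= self.cutoff_, self.positive_label_, neg)

    def decision_function(self, X):
        return self._flatten(X) - self.cutoff_
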