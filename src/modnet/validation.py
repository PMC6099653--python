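"""Classifier validation of driver gene sets.

Driver genes are validated as classification features: a linear
maximum-margin classifier (SVM, C = 1) separates the focal subtype from the
rest in stratified k-fold cross-validation on the drivers' expression only.
Confusion counts are pooled across folds (micro) and summarized as accuracy,
precision, recall and F-measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = ["ConfusionCounts", "MetricSet", "confusion_metrics", "cross_validate_one_vs_rest"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f_measure: float


def confusion_metrics(c: ConfusionCounts) -> MetricSet:
    """Accuracy, precision, recall and F from pooled confusion counts.

    Zero-denominator precision/recall (and hence F) are defined as 0.
    """
    if min(c.tp, c.tn, c.fp, c.fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    if c.total == 0:
        raise ValueError("confusion counts are all zero")
    accuracy = (c.tp + c.tn) / c.total
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else 0.0
    f = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return MetricSet(accuracy=accuracy, precision=precision, recall=recall, f_measure=f)


def cross_validate_one_vs_rest(
    driver_expr: pd.DataFrame,
    labels: Sequence[str],
    focal_subtype: str,
    folds: int = 10,
    seed: int = 0,
) -> Tuple[MetricSet, ConfusionCounts]:
    """Stratified k-fold linear-SVM one-vs-rest CV on driver-gene expression.

    ``driver_expr`` is genes x samples (driver genes only); the focal
    subtype is the positive class. Confusion counts are pooled over folds
    before computing the metrics.
    """
    y = np.asarray([1 if str(l) == focal_subtype else 0 for l in labels])
    X = driver_expr.to_numpy(dtype=float).T
    if X.shape[0] != y.size:
        raise ValueError("labels must match expression samples")
    if y.min() == y.max():
        raise ValueError("both the focal class and the rest must be present")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if folds > min(n_pos, n_neg):
        raise ValueError(
            f"folds={folds} exceeds the smaller class size {min(n_pos, n_neg)}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    tp = tn = fp = fn = 0
    for train_idx, test_idx in skf.split(X, y):
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        truth = y[test_idx]
        tp += int(((pred == 1) & (truth == 1)).sum())
        tn += int(((pred == 0) & (truth == 0)).sum())
        fp += int(((pred == 1) & (truth == 0)).sum())
        fn += int(((pred == 0) & (truth == 1)).sum())
    counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    return confusion_metrics(counts), counts
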