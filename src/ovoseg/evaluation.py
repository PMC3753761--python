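"""Evaluation machinery: confusion matrices, per-class metrics, CV, day transfer.

Conventions follow the common machine-learning-toolkit reporting style:
rows of a confusion matrix are true classes, columns predictions, class
order is the seven long bones followed by NOI; the false-positive rate
denominator excludes the true-class row; weighted averages weight by
class support; report values are rounded to three decimals while full
precision is kept internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .classifier import DEFAULT_C, DEFAULT_GAMMA, train
from .model import ANNOTATION_CLASSES, ANNOTATION_COLUMN, NOI

__all__ = [
    "ConfusionMatrix", "MetricsReport", "confusion_matrix",
    "metrics_from_confusion", "roc_auc", "cross_validate", "leave_day_out",
]


@dataclass
class ConfusionMatrix:
    """8 x 8 integer counts; rows = truth, columns = prediction."""

    counts: np.ndarray
    classes: tuple[str, ...] = ANNOTATION_CLASSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"expected a {k} x {k} matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


@dataclass
class MetricsReport:
    """Per-class and weighted-average classification metrics."""

    per_class: pd.DataFrame      # index: class; columns: tp_rate .. f_measure
    weighted: pd.Series
    accuracy: float

    def rounded(self, decimals: int = 3) -> pd.DataFrame:
        """Display-style table (three decimals, as in published reports)."""
        return self.per_class.round(decimals)


def confusion_matrix(truth, predicted,
                     classes: tuple[str, ...] = ANNOTATION_CLASSES) -> ConfusionMatrix:
    """Count matrix of true vs predicted labels."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.size == 0:
        raise ValueError("empty label arrays")
    if truth.shape != predicted.shape:
        raise ValueError("truth and prediction lengths differ")
    index = {c: i for i, c in enumerate(classes)}
    unknown = (set(truth) | set(predicted)) - set(classes)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(truth, predicted):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, classes)


def metrics_from_confusion(m: ConfusionMatrix) -> MetricsReport:
    """Per-class TP/FP rates, precision, recall, F-measure and averages.

    Precision of a class with an empty prediction column is 0 by
    convention; F is 0 when precision + recall is 0.
    """
    counts = m.counts.astype(np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.where(row > 0, tp / row, 0.0)
        precision = np.where(col > 0, tp / col, 0.0)
        fp = col - tp
        fp_rate = np.where(total - row > 0, fp / (total - row), 0.0)
        denom = precision + recall
        f = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    per_class = pd.DataFrame(
        {
            "tp_rate": recall,
            "fp_rate": fp_rate,
            "precision": precision,
            "recall": recall,
            "f_measure": f,
        },
        index=list(m.classes),
    )
    weights = row / total
    weighted = per_class.mul(weights, axis=0).sum()
    accuracy = float(tp.sum() / total)
    return MetricsReport(per_class=per_class, weighted=weighted, accuracy=accuracy)


def roc_auc(truth, probabilities: pd.DataFrame) -> pd.Series:
    """One-vs-rest ROC area per class (midrank ties); NA where undefined."""
    truth = np.asarray(truth)
    rows = probabilities.to_numpy().sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-3):
        raise ValueError("probability rows must sum to ~1")
    out = {}
    for cls in probabilities.columns:
        y = (truth == cls).astype(int)
        if y.min() == y.max():
            out[cls] = np.nan
            continue
        out[cls] = roc_auc_score(y, probabilities[cls].to_numpy())
    return pd.Series(out)


def cross_validate(
    table: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
) -> tuple[ConfusionMatrix, MetricsReport]:
    """Stratified k-fold CV; out-of-fold predictions pooled into one matrix."""
    if len(table) < k:
        raise ValueError("fewer rows than folds")
    y = table[ANNOTATION_COLUMN].to_numpy()
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    truth_all, pred_all = [], []
    for train_idx, test_idx in cv.split(np.zeros(len(y)), y):
        model = train(table.iloc[train_idx], C=C, gamma=gamma, seed=seed,
                      calibrate=False, require_all_classes=False)
        pred = model.predict(table.iloc[test_idx])
        truth_all.append(y[test_idx])
        pred_all.append(pred.to_numpy())
    m = confusion_matrix(np.concatenate(truth_all), np.concatenate(pred_all))
    return m, metrics_from_confusion(m)


def leave_day_out(
    table: pd.DataFrame,
    day: int,
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
    seed: int = 0,
) -> float:
    """Train on all other incubation days; return accuracy on the held-out day."""
    days = table["day_of_incubation"].to_numpy()
    held = days == day
    if not held.any():
        raise ValueError(f"day {day} absent from the table")
    if held.all():
        raise ValueError("table contains only the held-out day")
    model = train(table.loc[~held], C=C, gamma=gamma, seed=seed,
                  require_all_classes=False)
    test = table.loc[held]
    # the calibrated model is what gets applied to unseen days
    pred = model.predict_proba(test).idxmax(axis=1)
    truth = test[ANNOTATION_COLUMN].to_numpy()
    return float((pred.to_numpy() == truth).mean())
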