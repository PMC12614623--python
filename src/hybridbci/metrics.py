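"""Multiclass evaluation statistics.

Classification accuracy is the confusion-matrix trace over its total, x100;
precision/recall/F1 are per-class with unweighted (macro) averages, reported
in percent; modality comparisons use one-way fixed-effects ANOVA on the
per-run accuracies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datamodel import ValidationError

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "classification_accuracy",
    "precision_recall_f1",
    "anova_modalities",
]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """N x N counts; rows = actual class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValidationError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


def confusion(actual, predicted, n_classes: int = 4) -> ConfusionMatrix:
    """counts[i][j] = #(actual = i+1, predicted = j+1), labels in 1..N."""
    actual = np.asarray(actual, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if actual.shape != predicted.shape:
        raise ValidationError("label vectors have mismatched lengths")
    for name, v in (("actual", actual), ("predicted", predicted)):
        if v.size and (v.min() < 1 or v.max() > n_classes):
            raise ValidationError(f"{name} labels outside 1..{n_classes}")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (actual - 1, predicted - 1), 1)
    return ConfusionMatrix(counts)


def classification_accuracy(cm: ConfusionMatrix) -> float:
    """100 x trace / total."""
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def precision_recall_f1(cm: ConfusionMatrix) -> dict:
    """Per-class and macro precision/recall/F1 in percent.

    Division by zero (class never predicted, or absent from the test set)
    yields 0 for the affected metric, with a log note.
    """
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    counts = cm.counts.astype(float)
    diag = np.diag(counts)
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / col, 0.0)
        recall = np.where(row > 0, diag / row, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    if np.any(col == 0) or np.any(row == 0):
        logger.info("zero-division in precision/recall: reported as 0 by convention")
    return {
        "precision": (100.0 * precision).tolist(),
        "recall": (100.0 * recall).tolist(),
        "f1": (100.0 * f1).tolist(),
        "macro_precision": 100.0 * float(precision.mean()),
        "macro_recall": 100.0 * float(recall.mean()),
        "macro_f1": 100.0 * float(f1.mean()),
    }


def anova_modalities(groups) -> tuple[float, float]:
    """One-way fixed-effects ANOVA over per-run accuracy groups.

    ``groups`` is a list of numeric sequences (or objects with a ``run_ca``
    attribute, e.g. evaluation reports), one per modality.  Returns (F, p).
    """
    from scipy import stats as sp_stats

    arrays = [
        np.asarray(getattr(g, "run_ca", g), dtype=float) for g in groups
    ]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValidationError("need >= 2 groups with >= 2 values each")
    allv = np.concatenate(arrays)
    if np.ptp(allv) == 0:
        raise ValidationError("degenerate groups: all values identical")
    # explicit sums-of-squares decomposition
    grand = allv.mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = len(allv) - len(arrays)
    if ss_within == 0:
        raise ValidationError("degenerate groups: zero within-group variance")
    F = (ss_between / df_between) / (ss_within / df_within)
    p = float(sp_stats.f.sf(F, df_between, df_within))
    return float(F), p
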