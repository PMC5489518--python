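"""Classification metrics computed from a confusion matrix.

Accuracy, Cohen's kappa, precision/recall (weighted or macro averaged) and
the dimension percentage — the selected-subset size as a percentage of the
full feature count — i.e. the quantities a feature-selection benchmark
reports per dataset and method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "accuracy",
    "kappa",
    "precision_recall",
    "dimension_pct",
]


@dataclass
class ConfusionMatrix:
    """K x K count matrix; rows are truth, columns are predictions."""

    counts: np.ndarray
    class_order: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        K = len(self.class_order)
        if self.counts.shape != (K, K):
            raise ValueError("counts must be K x K for K classes")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_labels(cls, y_true, y_pred, class_order=None) -> "ConfusionMatrix":
        y_true = list(np.asarray(y_true).tolist())
        y_pred = list(np.asarray(y_pred).tolist())
        if len(y_true) != len(y_pred):
            raise ValueError("y_true and y_pred differ in length")
        if class_order is None:
            class_order = []
            for lab in y_true + y_pred:
                if lab not in class_order:
                    class_order.append(lab)
        index = {c: k for k, c in enumerate(class_order)}
        counts = np.zeros((len(class_order), len(class_order)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(counts, list(class_order))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _require_scored(cm: ConfusionMatrix) -> None:
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of samples on the diagonal."""
    _require_scored(cm)
    return float(np.trace(cm.counts) / cm.total)


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e), 0 by convention when p_e = 1."""
    _require_scored(cm)
    total = cm.total
    p_o = np.trace(cm.counts) / total
    rows = cm.counts.sum(axis=1)
    cols = cm.counts.sum(axis=0)
    p_e = float(rows @ cols) / total**2
    if p_e >= 1.0:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def precision_recall(cm: ConfusionMatrix,
                     averaging: str = "weighted") -> tuple[float, float]:
    """Averaged per-class precision and recall.

    Per-class precision is TP/(TP+FP) and recall TP/(TP+FN), with 0 when
    the denominator vanishes (a class never predicted, or absent from the
    truth).  ``averaging`` is ``"weighted"`` (by class support, the
    default) or ``"macro"``.
    """
    _require_scored(cm)
    if averaging not in ("weighted", "macro"):
        raise ValueError("averaging must be 'weighted' or 'macro'")
    counts = cm.counts.astype(float)
    tp = np.diag(counts)
    support = counts.sum(axis=1)       # truth counts per class (TP + FN)
    predicted = counts.sum(axis=0)     # prediction counts per class (TP + FP)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(predicted > 0, tp / predicted, 0.0)
        rec = np.where(support > 0, tp / support, 0.0)
    if averaging == "macro":
        return float(prec.mean()), float(rec.mean())
    w = support / support.sum()
    return float(prec @ w), float(rec @ w)


def dimension_pct(selected: int, total: int) -> float:
    """Selected feature count as a percentage of the full dimension."""
    if total <= 0:
        raise ValueError("total feature count must be positive")
    if not 0 <= selected <= total:
        raise ValueError(f"selected = {selected} outside [0, {total}]")
    return 100.0 * selected / total
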