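"""Confusion-matrix metrics, ROC/AUC, and report formatting.

Conventions: positives are hotspots.  Accuracy = (TP+TN)/N, recall =
TP/(TP+FN), precision = TP/(TP+FP), specificity = TN/(TN+FP), F1 the
harmonic mean of precision and recall.  A metric whose denominator is zero
is reported as absent (None), never silently as 0, so comparisons between
models are not biased by degenerate slices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = ["ConfusionMatrix", "MetricReport", "confusion", "metrics", "roc_auc", "roc_points", "write_report", "format_table"]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Derived scores; None marks an undefined (zero-denominator) metric."""

    accuracy: float | None
    recall: float | None
    precision: float | None
    f1: float | None
    specificity: float | None
    auc: float | None = None


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    """Exact TP/TN/FP/FN counts for binary label vectors."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size < 1:
        raise ValueError("need at least one example")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """Accuracy, recall, precision, F1 and specificity from counts."""
    if cm.total < 1:
        raise ValueError("empty confusion matrix")
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    f1 = None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    return MetricReport(
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        recall=recall,
        precision=precision,
        f1=f1,
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
    )


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve (trapezoidal; ties grouped).

    Equals the probability that a random positive outranks a random
    negative.  Requires both classes present and finite scores.
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("length mismatch")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC AUC undefined with a single class")
    return float(roc_auc_score(y_true, scores))


def roc_points(y_true: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """(fpr, tpr, threshold) rows of the ROC curve, for plotting/dumping."""
    fpr, tpr, thr = roc_curve(np.asarray(y_true).astype(int), np.asarray(scores, dtype=float))
    return np.column_stack([fpr, tpr, thr])


def format_table(reports: dict[str, MetricReport]) -> str:
    """Aligned text table (Acc, Recall, Pre, F1, Spe, AUC), one row per set."""
    cols = ["Acc", "Recall", "Pre", "F1", "Spe", "AUC"]
    keys = ["accuracy", "recall", "precision", "f1", "specificity", "auc"]
    width = max(len(n) for n in reports) if reports else 8
    lines = ["Data set".ljust(width) + "".join(c.rjust(9) for c in cols)]
    for name, rep in reports.items():
        d = asdict(rep)
        cells = "".join(
            (f"{d[k]:.4f}" if d[k] is not None else "--").rjust(9) for k in keys
        )
        lines.append(name.ljust(width) + cells)
    return "\n".join(lines)


def write_report(path: str | Path, reports: dict[str, MetricReport]) -> None:
    payload = {name: asdict(rep) for name, rep in reports.items()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
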