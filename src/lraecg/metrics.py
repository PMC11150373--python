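"""Multiclass evaluation: one-vs-rest counts, precision/recall/F1, accuracy.

The confusion matrix convention is rows = true class, columns = predicted
class.  For class k the one-vs-rest counts are TP = C[k,k],
FP = column k minus TP, FN = row k minus TP, TN = the rest; then
P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R) and
Acc = trace(C)/sum(C).  Zero-denominator cells return 0 and set the
class's ``degenerate`` flag instead of producing NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ClassMetrics", "MetricsReport", "confusion_matrix", "class_metrics", "f1_score"]


@dataclass
class ClassMetrics:
    label: int
    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    f1: float
    degenerate: bool = False


@dataclass
class MetricsReport:
    per_class: list[ClassMetrics]
    accuracy: float
    macro_f1: float
    total: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "total": self.total,
            "per_class": [vars(m).copy() for m in self.per_class],
        }


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    C = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(C, (y_true, y_pred), 1)
    return C


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision < 0 or recall < 0:
        raise ValueError("precision and recall must be nonnegative")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def class_metrics(confusion: np.ndarray) -> MetricsReport:
    """Per-class one-vs-rest metrics and overall accuracy from a confusion matrix."""
    C = np.asarray(confusion)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {C.shape}")
    if np.any(C < 0) or not np.issubdtype(C.dtype, np.integer):
        if np.any(C < 0) or not np.allclose(C, np.round(C)):
            raise ValueError("confusion matrix must hold nonnegative integers")
        C = C.astype(int)
    total = int(C.sum())
    per_class: list[ClassMetrics] = []
    for k in range(C.shape[0]):
        tp = int(C[k, k])
        fp = int(C[:, k].sum()) - tp
        fn = int(C[k, :].sum()) - tp
        tn = total - tp - fp - fn
        degenerate = (tp + fp == 0) or (tp + fn == 0)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        per_class.append(
            ClassMetrics(
                label=k, tp=tp, fp=fp, tn=tn, fn=fn,
                precision=p, recall=r, f1=f1_score(p, r), degenerate=degenerate,
            )
        )
    acc = float(np.trace(C)) / total if total else 0.0
    macro_f1 = float(np.mean([m.f1 for m in per_class])) if per_class else 0.0
    return MetricsReport(per_class=per_class, accuracy=acc, macro_f1=macro_f1, total=total)
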