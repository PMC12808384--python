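"""Classification evaluation suite for the six-class frame vocabulary.

Per-class metrics are computed one-vs-rest from the K x K confusion matrix
(rows = true class, columns = predicted):

    sensitivity = TP/(TP+FN)      specificity = TN/(TN+FP)
    precision   = TP/(TP+FP)      accuracy    = (TP+TN)/(TP+TN+FP+FN)
    F1 = 2 * precision * sensitivity / (precision + sensitivity)

Weighted averages use class-support shares as weights, which makes the
support-weighted sensitivity identical to micro accuracy (trace / total).
Ranking metrics are one-vs-rest as well: AUC is the trapezoidal integral of
the ROC curve with tied scores grouped into single threshold steps, and AP
is the untruncated step integral of precision over recall.  Zero
denominators yield 0 with a warning flag (never NaN), so weighted averages
stay defined on degenerate inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "MetricReport",
    "confusion_matrix",
    "per_class_metrics",
    "weighted_average",
    "roc_curve",
    "roc_auc",
    "precision_recall_curve",
    "average_precision",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    labels: tuple[str, ...]
    counts: np.ndarray  # K x K ints, rows true, cols predicted

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("confusion matrix must be square")
        if arr.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix size")
        if (arr < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")
        object.__setattr__(self, "counts", arr)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def support(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def one_vs_rest(self, i: int) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) collapsing class i against the rest."""
        tp = int(self.counts[i, i])
        fn = int(self.counts[i].sum() - tp)
        fp = int(self.counts[:, i].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, tn, fp, fn


@dataclass(frozen=True)
class ClassMetrics:
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    f1: float
    support: int
    degenerate: frozenset[str] = frozenset()  # metrics forced to 0 by a 0/0


@dataclass(frozen=True)
class MetricReport:
    labels: tuple[str, ...]
    per_class: tuple[ClassMetrics, ...]
    weighted: ClassMetrics

    def as_dict(self) -> dict:
        def row(m: ClassMetrics) -> dict:
            return {
                "precision": m.precision,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "f1": m.f1,
                "accuracy": m.accuracy,
                "support": m.support,
                "degenerate": sorted(m.degenerate),
            }

        out = {lab: row(m) for lab, m in zip(self.labels, self.per_class)}
        out["weighted average"] = row(self.weighted)
        return out


def confusion_matrix(
    y_true: Sequence[str], y_pred: Sequence[str],
    labels: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Tally (true, predicted) pairs into a K x K matrix."""
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted"
        )
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        try:
            counts[index[t], index[p]] += 1
        except KeyError as exc:
            raise ValueError(f"label {exc.args[0]!r} not in label set") from None
    return ConfusionMatrix(tuple(labels), counts)


def _safe_div(num: float, den: float, name: str, flags: set[str]) -> float:
    if den == 0:
        flags.add(name)
        return 0.0
    return num / den


def per_class_metrics(cm: ConfusionMatrix) -> MetricReport:
    """One-vs-rest sensitivity/specificity/precision/accuracy/F1 per class,
    plus the support-share weighted average row."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    rows: list[ClassMetrics] = []
    support = cm.support()
    for i in range(len(cm.labels)):
        tp, tn, fp, fn = cm.one_vs_rest(i)
        flags: set[str] = set()
        sens = _safe_div(tp, tp + fn, "sensitivity", flags)
        spec = _safe_div(tn, tn + fp, "specificity", flags)
        prec = _safe_div(tp, tp + fp, "precision", flags)
        acc = _safe_div(tp + tn, tp + tn + fp + fn, "accuracy", flags)
        f1 = _safe_div(2.0 * prec * sens, prec + sens, "f1", flags)
        rows.append(ClassMetrics(sens, spec, prec, acc, f1,
                                 int(support[i]), frozenset(flags)))
    w = support.astype(float)
    weighted = ClassMetrics(
        sensitivity=weighted_average([m.sensitivity for m in rows], w),
        specificity=weighted_average([m.specificity for m in rows], w),
        precision=weighted_average([m.precision for m in rows], w),
        accuracy=weighted_average([m.accuracy for m in rows], w),
        f1=weighted_average([m.f1 for m in rows], w),
        support=cm.total,
        degenerate=frozenset().union(*[m.degenerate for m in rows]),
    )
    return MetricReport(cm.labels, tuple(rows), weighted)


def weighted_average(per_class_values: Sequence[float],
                     weights: Sequence[float]) -> float:
    """Sum of w_i * P_i with the weights normalized to sum to one."""
    v = np.asarray(per_class_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    return float((v * w).sum() / total)


def _ranked_arrays(scores: Sequence[float], positive: Sequence[bool]):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(positive, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    return s, y


def roc_curve(scores: Sequence[float],
              positive: Sequence[bool]) -> tuple[np.ndarray, np.ndarray]:
    """ROC points (FPR, TPR) swept from the highest threshold down.

    Equal scores are grouped into a single threshold step; the curve always
    includes the endpoints (0, 0) and (1, 1).
    """
    s, y = _ranked_arrays(scores, positive)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    # group ties: indices where a new (lower) score value begins
    distinct = np.where(np.diff(s))[0]
    cut = np.concatenate([distinct, [len(s) - 1]])
    tps = np.cumsum(y)[cut]
    fps = np.cumsum(~y)[cut]
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    return fpr, tpr


def roc_auc(scores: Sequence[float], positive: Sequence[bool]) -> float:
    """Trapezoidal area under the ROC curve:
    0.5 * sum (FPR_{i+1} - FPR_i) * (TPR_{i+1} + TPR_i)."""
    fpr, tpr = roc_curve(scores, positive)
    return float(0.5 * np.sum(np.diff(fpr) * (tpr[1:] + tpr[:-1])))


def precision_recall_curve(
    scores: Sequence[float], positive: Sequence[bool],
) -> tuple[np.ndarray, np.ndarray]:
    """(recall, precision) at every rank, descending-score order."""
    s, y = _ranked_arrays(scores, positive)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("precision-recall needs at least one positive")
    order = np.argsort(-s, kind="stable")
    y = y[order]
    tp = np.cumsum(y)
    k = np.arange(1, len(y) + 1)
    return tp / n_pos, tp / k


def average_precision(scores: Sequence[float],
                      positive: Sequence[bool]) -> float:
    """Step integral of precision over recall (no interpolation):
    sum over positive ranks k of (delta recall) * precision@k."""
    recall, precision = precision_recall_curve(scores, positive)
    prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev) * precision))
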