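"""Confusion matrices and multiclass metrics.

Metrics derive from the K x K confusion matrix (rows = true class, columns =
predicted class) through per-class one-vs-rest reductions:

    accuracy_k  = (TP_k + TN_k) / N          error_rate = 1 - accuracy
    precision_k = TP_k / (TP_k + FP_k)       recall_k   = TP_k / (TP_k + FN_k)
    F1_k        = 2 P R / (P + R)

with 0/0 defined as 0.  Three aggregations are always reported and labeled
explicitly — micro (pooled counts; for single-label multiclass problems micro
precision = micro recall = overall accuracy), macro (unweighted class mean),
and weighted (support-weighted mean) — because published tables often mix
conventions without saying which one each column uses.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

__all__ = ["ConfusionMatrix", "MetricReport", "build_confusion", "metrics_from_confusion"]


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (K, K) int, rows = true, cols = predicted

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError(f"confusion matrix must be square, got shape {c.shape}")
        if np.any(c < 0):
            raise ValueError("confusion matrix entries must be nonnegative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclasses.dataclass(frozen=True)
class MetricReport:
    """Per-class and aggregated metrics, all as fractions in [0, 1]."""

    accuracy: float
    error_rate: float
    per_class: dict[str, np.ndarray]  # accuracy/precision/recall/f1, each (K,)
    micro: dict[str, float]
    macro: dict[str, float]
    weighted: dict[str, float]
    support: np.ndarray

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "error_rate": self.error_rate,
            "per_class": {k: v.tolist() for k, v in self.per_class.items()},
            "micro": dict(self.micro),
            "macro": dict(self.macro),
            "weighted": dict(self.weighted),
            "support": self.support.tolist(),
        }


def build_confusion(true_labels, predicted_labels, num_classes: int) -> ConfusionMatrix:
    """Count (true, predicted) pairs into a K x K matrix."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("label sequences must be 1-D and of equal length")
    if t.size and (t.min() < 0 or t.max() >= num_classes or p.min() < 0 or p.max() >= num_classes):
        raise ValueError(f"labels out of range [0, {num_classes})")
    counts = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricReport:
    """All metrics from one confusion matrix; raises on an empty matrix."""
    c = cm.counts
    n = cm.total
    if n == 0:
        raise ValueError("confusion matrix is empty")
    k = c.shape[0]
    tp = np.diag(c).astype(float)
    fn = c.sum(axis=1) - tp  # true class missed
    fp = c.sum(axis=0) - tp  # wrongly claimed
    tn = n - tp - fn - fp
    support = c.sum(axis=1)
    if np.any(support == 0):
        zero = np.where(support == 0)[0].tolist()
        warnings.warn(f"classes {zero} have zero support; their precision/recall set to 0")

    per_acc = (tp + tn) / n
    prec = _safe_div(tp, tp + fp)
    rec = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * prec * rec, prec + rec)

    accuracy = float(tp.sum() / n)
    micro_p = float(tp.sum() / (tp.sum() + fp.sum()))
    micro_r = float(tp.sum() / (tp.sum() + fn.sum()))
    micro_f1 = 2 * micro_p * micro_r / (micro_p + micro_r) if micro_p + micro_r else 0.0
    wts = support / n
    report = MetricReport(
        accuracy=accuracy,
        error_rate=1.0 - accuracy,
        per_class=dict(accuracy=per_acc, precision=prec, recall=rec, f1=f1),
        micro=dict(precision=micro_p, recall=micro_r, f1=float(micro_f1)),
        macro=dict(
            precision=float(prec.mean()), recall=float(rec.mean()), f1=float(f1.mean())
        ),
        weighted=dict(
            precision=float(wts @ prec), recall=float(wts @ rec), f1=float(wts @ f1)
        ),
        support=support,
    )
    return report
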