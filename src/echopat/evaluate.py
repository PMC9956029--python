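"""Classification metrics: confusion matrices, the five headline rates, and
one-vs-rest ROC/AUC.

Multiclass metrics reduce each class to a one-vs-rest binary table and are
reported per class plus macro-averaged (unweighted mean over classes); the
micro average and overall accuracy (trace over total) are also included.
Zero-denominator rates follow the 0-with-flag convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc, roc_curve

__all__ = ["BinaryMetrics", "MetricsReport", "binary_metrics", "multiclass_metrics", "roc_ovr"]


@dataclass(frozen=True)
class BinaryMetrics:
    """The five rates of one binary (or one-vs-rest) table."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
        }


@dataclass(frozen=True)
class MetricsReport:
    """Per-class, macro and micro metrics of a multiclass confusion matrix."""

    confusion: np.ndarray
    classes: tuple
    per_class: dict
    macro: dict
    micro: dict
    overall_accuracy: float
    roc: dict = field(default_factory=dict)


def _safe_div(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def binary_metrics(tp: int, tn: int, fp: int, fn: int) -> BinaryMetrics:
    """Accuracy, sensitivity (recall), specificity, precision and F1.

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    F1          = 2 * precision * recall / (precision + recall)
    """
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be nonnegative")
    total = sum(counts)
    if total == 0:
        raise ValueError("at least one count must be positive")
    flags: list[str] = []
    acc = (tp + tn) / total
    sens = _safe_div(tp, tp + fn, "sensitivity", flags)
    spec = _safe_div(tn, tn + fp, "specificity", flags)
    prec = _safe_div(tp, tp + fp, "precision", flags)
    f1 = _safe_div(2 * prec * sens, prec + sens, "f1", flags)
    return BinaryMetrics(tp, tn, fp, fn, acc, sens, spec, prec, f1, tuple(flags))


def multiclass_metrics(confusion: np.ndarray, classes=None) -> MetricsReport:
    """One-vs-rest reduction of a square confusion matrix (rows = truth)."""
    cm = np.asarray(confusion)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {cm.shape}")
    if (cm < 0).any():
        raise ValueError("confusion entries must be nonnegative")
    total = int(cm.sum())
    if total == 0:
        raise ValueError("confusion matrix is empty")
    k = cm.shape[0]
    classes = tuple(classes) if classes is not None else tuple(range(k))

    per_class: dict = {}
    agg = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    for i, cls in enumerate(classes):
        tp = int(cm[i, i])
        fn = int(cm[i].sum() - tp)
        fp = int(cm[:, i].sum() - tp)
        tn = total - tp - fn - fp
        per_class[cls] = binary_metrics(tp, tn, fp, fn)
        for key, val in zip(("tp", "tn", "fp", "fn"), (tp, tn, fp, fn)):
            agg[key] += val

    names = ("accuracy", "sensitivity", "specificity", "precision", "f1")
    macro = {n: float(np.mean([per_class[c].as_dict()[n] for c in classes])) for n in names}
    micro = binary_metrics(agg["tp"], agg["tn"], agg["fp"], agg["fn"]).as_dict()
    return MetricsReport(
        confusion=cm,
        classes=classes,
        per_class=per_class,
        macro=macro,
        micro=micro,
        overall_accuracy=float(np.trace(cm)) / total,
    )


def roc_ovr(scores: np.ndarray, labels, classes=None) -> dict:
    """One-vs-rest ROC curves and AUCs from per-class decision scores.

    ``scores`` is (n_samples, n_classes); column j scores class j against
    the rest.  Returns {class: {"fpr", "tpr", "thresholds", "auc"}}.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.ndim != 2 or scores.shape[0] != labels.shape[0]:
        raise ValueError("scores must be (n_samples, n_classes) aligned with labels")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least two classes for ROC analysis")
    classes = list(classes) if classes is not None else list(uniq)
    if len(classes) != scores.shape[1]:
        raise ValueError("number of score columns must match number of classes")
    out = {}
    for j, cls in enumerate(classes):
        positive = labels == cls
        if positive.all() or not positive.any():
            raise ValueError(f"class {cls!r} needs both positive and negative samples")
        fpr, tpr, thr = roc_curve(positive, scores[:, j])
        out[cls] = {"fpr": fpr, "tpr": tpr, "thresholds": thr, "auc": float(auc(fpr, tpr))}
    return out
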