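"""Segmentation and severity-classification metrics.

All metrics derive from a K x K confusion matrix (rows = ground truth,
columns = prediction) via one-vs-rest counts:

* Jaccard (IoU)          TP / (TP + FP + FN)
* Precision              TP / (TP + FP)
* Recall                 TP / (TP + FN)
* MPA                    mean over evaluated classes of per-class accuracy,
                         where per-class accuracy is TP_i / (TP_i + FN_i)
                         (i.e. the class recall)
* Accuracy (one-vs-rest) (TP + TN) / (TP + TN + FP + FN)
* F1                     2 TP / (2 TP + FN + FP), equal to the harmonic
                         mean of precision and recall

Pixel-level matrices feed :func:`segmentation_metrics`; case-level 3x3
matrices (mild/moderate/severe) feed :func:`classification_metrics`.
Macro ("Total") values are unweighted means over the reported classes.
Empty-class divisions are reported as 0.0 and flagged, not NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_from_masks",
    "segmentation_metrics",
    "classification_metrics",
    "f1_from_precision_recall",
    "macro_mean",
]

SEG_CLASS_NAMES = ("background", "MR", "LA")
GRADE_NAMES = ("mild", "moderate", "severe")


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # K x K int64, rows=truth, cols=prediction

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    def one_vs_rest(self, c: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for class ``c``."""
        tp = int(self.counts[c, c])
        fp = int(self.counts[:, c].sum() - tp)
        fn = int(self.counts[c, :].sum() - tp)
        tn = int(self.counts.sum() - tp - fp - fn)
        return tp, fp, fn, tn


@dataclass
class MetricsReport:
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    mpa: float | None = None
    zero_division_flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        out = {"per_class": self.per_class, "macro": self.macro}
        if self.mpa is not None:
            out["mpa"] = self.mpa
        if self.zero_division_flags:
            out["zero_division"] = self.zero_division_flags
        return out


def confusion_from_masks(pred: np.ndarray, truth: np.ndarray, k: int) -> ConfusionMatrix:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if pred.max(initial=0) >= k or truth.max(initial=0) >= k:
        raise ValueError(f"labels must be < {k}")
    if pred.min(initial=0) < 0 or truth.min(initial=0) < 0:
        raise ValueError("labels must be non-negative")
    idx = truth.ravel().astype(np.int64) * k + pred.ravel().astype(np.int64)
    counts = np.bincount(idx, minlength=k * k).reshape(k, k)
    return ConfusionMatrix(counts)


def _safe_div(num: float, den: float, flags: list[str], what: str) -> float:
    if den == 0:
        flags.append(what)
        return 0.0
    return num / den


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); the identity form of F1 = 2TP/(2TP+FP+FN)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def macro_mean(values) -> float:
    values = list(values)
    return float(np.mean(values))


def segmentation_metrics(
    cm: ConfusionMatrix,
    class_names=SEG_CLASS_NAMES,
    report_classes: tuple[int, ...] = (1, 2),
) -> MetricsReport:
    """Per-class Jaccard/precision/recall/accuracy for the foreground classes
    (MR jet and LA by default) plus their unweighted means and the MPA."""
    flags: list[str] = []
    per_class: dict[str, dict[str, float]] = {}
    for c in report_classes:
        tp, fp, fn, tn = cm.one_vs_rest(c)
        name = class_names[c]
        prec = _safe_div(tp, tp + fp, flags, f"{name}.precision")
        rec = _safe_div(tp, tp + fn, flags, f"{name}.recall")
        per_class[name] = {
            "jaccard": _safe_div(tp, tp + fp + fn, flags, f"{name}.jaccard"),
            "precision": prec,
            "recall": rec,
            "accuracy": _safe_div(tp + tn, tp + tn + fp + fn, flags, f"{name}.accuracy"),
            "f1": f1_from_precision_recall(prec, rec),
        }
    macro = {
        m: macro_mean(per_class[class_names[c]][m] for c in report_classes)
        for m in ("jaccard", "precision", "recall", "accuracy", "f1")
    }
    mpa = macro_mean(per_class[class_names[c]]["recall"] for c in report_classes)
    return MetricsReport(per_class, macro, mpa=mpa, zero_division_flags=flags)


def classification_metrics(cm: ConfusionMatrix, class_names=GRADE_NAMES) -> MetricsReport:
    """Case-level one-vs-rest metrics for the 3x3 severity matrix; the Total
    row is the unweighted (macro) mean of each per-class column."""
    if cm.k != len(class_names):
        raise ValueError(f"expected {len(class_names)} classes, got {cm.k}")
    flags: list[str] = []
    per_class: dict[str, dict[str, float]] = {}
    for c, name in enumerate(class_names):
        tp, fp, fn, tn = cm.one_vs_rest(c)
        prec = _safe_div(tp, tp + fp, flags, f"{name}.precision")
        rec = _safe_div(tp, tp + fn, flags, f"{name}.recall")
        per_class[name] = {
            "precision": prec,
            "recall": rec,
            "accuracy": _safe_div(tp + tn, tp + tn + fp + fn, flags, f"{name}.accuracy"),
            "f1": f1_from_precision_recall(prec, rec),
        }
    macro = {
        m: macro_mean(per_class[n][m] for n in class_names)
        for m in ("precision", "recall", "accuracy", "f1")
    }
    return MetricsReport(per_class, macro, zero_division_flags=flags)
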