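"""Classification and segmentation evaluation.

Segmentation quality between a ground-truth mask tau and a predicted mask rho
is scored from the pixel confusion counts

    tp = sum tau*rho        tn = sum (1-tau)(1-rho)
    fp = sum (1-tau)*rho    fn = sum tau*(1-rho)

via precision P = tp/(tp+fp), recall R = tp/(tp+fn), F1 = 2PR/(P+R) and
accuracy A = (tp+tn)/(tp+tn+fp+fn).  Undefined ratios (0/0) are reported as
NaN and excluded from set averages, which are macro (per-slide arithmetic
mean).  Slide-level classification is scored by accuracy, macro one-vs-rest
ROC AUC, per-class sensitivity and the full confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class BinaryMaskPair:
    """Ground-truth (tau) and predicted (rho) binary masks of equal shape."""

    tau: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau)
        rho = np.asarray(self.rho)
        if tau.shape != rho.shape:
            raise ValueError(f"mask shapes differ: {tau.shape} vs {rho.shape}")
        for name, m in (("tau", tau), ("rho", rho)):
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"{name} contains non-binary values")
        object.__setattr__(self, "tau", tau.astype(np.int64))
        object.__setattr__(self, "rho", rho.astype(np.int64))


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
class MetricsReport:
    """Precision, recall, F1 and accuracy; NaN marks an undefined (0/0) ratio."""

    precision: float
    recall: float
    f1: float
    accuracy: float


def confusion_counts(pair: BinaryMaskPair) -> ConfusionCounts:
    tau, rho = pair.tau, pair.rho
    return ConfusionCounts(
        tp=int((tau * rho).sum()),
        tn=int(((1 - tau) * (1 - rho)).sum()),
        fp=int(((1 - tau) * rho).sum()),
        fn=int((tau * (1 - rho)).sum()),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def prf_accuracy(c: ConfusionCounts) -> MetricsReport:
    p = _ratio(c.tp, c.tp + c.fp)
    r = _ratio(c.tp, c.tp + c.fn)
    if np.isnan(p) or np.isnan(r):
        f1 = float("nan")
    elif p + r == 0:
        f1 = 0.0
    else:
        f1 = 2 * p * r / (p + r)
    a = _ratio(c.tp + c.tn, c.total)
    return MetricsReport(precision=p, recall=r, f1=f1, accuracy=a)


def evaluate_segmentation_set(
    pairs: list[BinaryMaskPair], average: str = "macro"
) -> tuple[MetricsReport, dict[str, int]]:
    """Average P/R/F1/A over a set of mask pairs.

    ``macro`` (default) averages per-slide metrics arithmetically, skipping
    undefined entries; ``micro`` pools pixels over the set first.  Returns the
    averaged report and the count of undefined entries skipped per metric.
    """
    if not pairs:
        raise ValueError("evaluate_segmentation_set needs at least one mask pair")
    if average == "micro":
        counts = [confusion_counts(p) for p in pairs]
        pooled = ConfusionCounts(
            tp=sum(c.tp for c in counts),
            tn=sum(c.tn for c in counts),
            fp=sum(c.fp for c in counts),
            fn=sum(c.fn for c in counts),
        )
        return prf_accuracy(pooled), {k: 0 for k in ("precision", "recall", "f1", "accuracy")}
    if average != "macro":
        raise ValueError(f"unknown averaging {average!r}")
    reports = [prf_accuracy(confusion_counts(p)) for p in pairs]
    out = {}
    skipped = {}
    for name in ("precision", "recall", "f1", "accuracy"):
        vals = np.array([getattr(r, name) for r in reports], dtype=np.float64)
        defined = vals[~np.isnan(vals)]
        skipped[name] = int(np.isnan(vals).sum())
        out[name] = float(defined.mean()) if defined.size else float("nan")
    return MetricsReport(**out), skipped


def binarize_saliency(plane: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Min-max normalize a saliency plane and threshold it into a binary mask."""
    plane = np.asarray(plane, dtype=np.float64)
    lo, hi = plane.min(), plane.max()
    if hi - lo <= 0:
        return np.zeros(plane.shape, dtype=np.int64)
    return ((plane - lo) / (hi - lo) >= threshold).astype(np.int64)


@dataclass(frozen=True)
class ClassificationReport:
    accuracy: float                 # percent
    auc: float                      # percent, macro one-vs-rest
    per_class_sensitivity: np.ndarray
    confusion_matrix: np.ndarray    # C x C, rows = true class


def classification_report(probs: np.ndarray, labels: np.ndarray) -> ClassificationReport:
    """Slide-level metrics from predicted class probabilities.

    ``probs`` is M x C with rows summing to 1; ``labels`` are integer class
    indices.  AUC is one-vs-rest, macro-averaged with midrank tie handling;
    sensitivity is per-class recall (diagonal over row sums of the confusion
    matrix).  Accuracy and AUC are reported in percent.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    C = probs.shape[1]
    if labels.min() < 0 or labels.max() >= C:
        raise ValueError("label outside [0, n_classes)")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    preds = probs.argmax(axis=1)
    cm = _sk_confusion(labels, preds, labels=list(range(C)))
    acc = 100.0 * float(np.trace(cm)) / len(labels)
    present = np.unique(labels)
    if present.size < 2:
        auc = float("nan")
    elif present.size < C:
        aucs = [
            roc_auc_score((labels == c).astype(int), probs[:, c]) for c in present
        ]
        auc = 100.0 * float(np.mean(aucs))
    else:
        auc = 100.0 * float(roc_auc_score(labels, probs, multi_class="ovr", average="macro"))
    row_sums = cm.sum(axis=1)
    sens = np.divide(
        np.diag(cm), row_sums, out=np.full(C, np.nan), where=row_sums > 0
    )
    return ClassificationReport(
        accuracy=acc, auc=auc, per_class_sensitivity=sens, confusion_matrix=cm
    )


def accuracy_improvement(acc_a: float, acc_b: float) -> float:
    """Accuracy difference in percentage points, rounded to 2 decimals."""
    for v in (acc_a, acc_b):
        if not 0.0 <= v <= 100.0:
            raise ValueError("accuracies must be percentages in [0, 100]")
    return round(acc_a - acc_b, 2)
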