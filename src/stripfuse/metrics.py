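"""Multi-class evaluation metrics from the confusion matrix, plus ROC/AUC.

All scalar metrics derive from a K x K confusion matrix (rows = true class,
columns = predicted class) through the one-vs-rest reduction: for class k,
TP is the diagonal cell, FP the rest of column k, FN the rest of row k and
TN everything else.  Precision = TP/(TP+FP), recall = TP/(TP+FN), and F1 is
their harmonic mean; any 0/0 is reported as 0 so that macro averages stay
totals over all classes.  Macro averages are unweighted class means.  Since
the two common "macro F1" conventions (mean of per-class F1 versus harmonic
mean of macro precision and macro recall) differ in the fourth decimal, the
report carries both.

ROC curves are one-vs-rest threshold sweeps over a class's predicted score,
with AUC by the trapezoid rule; the micro-average curve pools all (label,
score) pairs across classes into a single binary problem before sweeping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "confusion_matrix",
    "accuracy",
    "precision_recall",
    "f1_score",
    "roc_curve_binary",
    "roc_curves",
    "MetricsReport",
    "compute_report",
]


def confusion_matrix(y_true, y_pred, num_classes: int) -> np.ndarray:
    """K x K count matrix; cell (i, j) counts true-i items predicted j."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences must have equal length")
    if y_true.size and (
        y_true.min() < 0 or y_true.max() >= num_classes
        or y_pred.min() < 0 or y_pred.max() >= num_classes
    ):
        raise ValueError(f"labels must lie in 0..{num_classes - 1}")
    cm = np.zeros((num_classes, num_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def accuracy(cm: np.ndarray) -> float:
    """Correctly predicted fraction: trace / total."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm) / total)


def precision_recall(cm: np.ndarray, class_k: int) -> tuple[float, float]:
    """One-vs-rest precision and recall of class ``class_k`` (0 when 0/0)."""
    cm = np.asarray(cm)
    tp = cm[class_k, class_k]
    fp = cm[:, class_k].sum() - tp
    fn = cm[class_k, :].sum() - tp
    precision = float(tp / (tp + fp)) if tp + fp > 0 else 0.0
    recall = float(tp / (tp + fn)) if tp + fn > 0 else 0.0
    return precision, recall


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def roc_curve_binary(y: np.ndarray, scores: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """(fpr, tpr, auc) of a binary problem by sweeping the score threshold."""
    y = np.asarray(y, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    pos = y.sum()
    neg = y.size - pos
    if pos == 0 or neg == 0:
        raise ValueError("ROC needs both positive and negative items")
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    # keep only the last index of each tied score block
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tp[distinct] / pos]
    fpr = np.r_[0.0, fp[distinct] / neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def roc_curves(y_true, scores) -> dict:
    """Per-class one-vs-rest ROC curves plus the micro-average curve.

    ``scores`` is an (N, K) array of class probabilities.  Classes absent
    from ``y_true`` get ``None`` for their AUC (undefined, not zero).
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n, k = scores.shape
    result: dict = {"per_class": {}, "per_class_auc": {}}
    for c in range(k):
        y_bin = y_true == c
        if y_bin.all() or not y_bin.any():
            result["per_class"][c] = None
            result["per_class_auc"][c] = None
            continue
        fpr, tpr, auc = roc_curve_binary(y_bin, scores[:, c])
        result["per_class"][c] = (fpr, tpr)
        result["per_class_auc"][c] = auc
    onehot = np.zeros((n, k), dtype=bool)
    onehot[np.arange(n), y_true] = True
    fpr, tpr, auc = roc_curve_binary(onehot.ravel(), scores.ravel())
    result["micro"] = (fpr, tpr)
    result["micro_auc"] = auc
    return result


def export_roc_points(rocs: dict, path) -> None:
    """Write ROC curve points (curve, fpr, tpr) as tab-delimited text."""
    with open(path, "w") as fh:
        fh.write("curve\tfpr\ttpr\n")
        for c, curve in rocs["per_class"].items():
            if curve is None:
                continue
            for fpr, tpr in zip(*curve):
                fh.write(f"class_{c}\t{fpr:.6f}\t{tpr:.6f}\n")
        for fpr, tpr in zip(*rocs["micro"]):
            fh.write(f"micro\t{fpr:.6f}\t{tpr:.6f}\n")


@dataclass
class MetricsReport:
    """Full evaluation report for one labelled prediction set."""

    confusion: np.ndarray
    class_names: list[str]
    overall_accuracy: float
    per_class_precision: list[float]
    per_class_recall: list[float]
    per_class_f1: list[float]
    macro_precision: float
    macro_recall: float
    macro_f1_mean: float          # mean of per-class F1
    macro_f1_harmonic: float      # harmonic mean of macro P and macro R
    per_class_auc: list[float | None] | None = None
    micro_auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "confusion_matrix": self.confusion.tolist(),
            "overall_accuracy": self.overall_accuracy,
            "per_class": {
                name: {
                    "precision": self.per_class_precision[i],
                    "recall": self.per_class_recall[i],
                    "f1": self.per_class_f1[i],
                    "auc": None if self.per_class_auc is None
                    else self.per_class_auc[i],
                }
                for i, name in enumerate(self.class_names)
            },
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1_mean": self.macro_f1_mean,
            "macro_f1_harmonic": self.macro_f1_harmonic,
            "micro_auc": self.micro_auc,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_text(self) -> str:
        lines = [
            f"{'class':<14s} {'precision':>9s} {'recall':>9s} {'f1':>9s} {'auc':>9s}"
        ]
        for i, name in enumerate(self.class_names):
            auc = "-" if self.per_class_auc is None or self.per_class_auc[i] is None \
                else f"{self.per_class_auc[i]:.4f}"
            lines.append(
                f"{name:<14s} {self.per_class_precision[i]:>9.4f} "
                f"{self.per_class_recall[i]:>9.4f} {self.per_class_f1[i]:>9.4f} "
                f"{auc:>9s}"
            )
        lines.append(f"overall accuracy  {self.overall_accuracy:.4f}")
        lines.append(
            f"macro P/R/F1      {self.macro_precision:.4f} {self.macro_recall:.4f} "
            f"{self.macro_f1_mean:.4f} (harmonic {self.macro_f1_harmonic:.4f})"
        )
        if self.micro_auc is not None:
            lines.append(f"micro-average AUC {self.micro_auc:.4f}")
        return "\n".join(lines)


def compute_report(
    y_true,
    y_pred,
    class_names: list[str],
    scores: np.ndarray | None = None,
) -> MetricsReport:
    """Build the full report; pass ``scores`` to include ROC/AUC figures."""
    k = len(class_names)
    cm = confusion_matrix(y_true, y_pred, k)
    precisions, recalls, f1s = [], [], []
    for c in range(k):
        p, r = precision_recall(cm, c)
        precisions.append(p)
        recalls.append(r)
        f1s.append(f1_score(p, r))
    macro_p = float(np.mean(precisions))
    macro_r = float(np.mean(recalls))
    per_class_auc = micro_auc = None
    if scores is not None:
        rocs = roc_curves(y_true, scores)
        per_class_auc = [rocs["per_class_auc"][c] for c in range(k)]
        micro_auc = rocs["micro_auc"]
    return MetricsReport(
        confusion=cm,
        class_names=list(class_names),
        overall_accuracy=accuracy(cm),
        per_class_precision=precisions,
        per_class_recall=recalls,
        per_class_f1=f1s,
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_f1_mean=float(np.mean(f1s)),
        macro_f1_harmonic=f1_score(macro_p, macro_r),
        per_class_auc=per_class_auc,
        micro_auc=micro_auc,
    )
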