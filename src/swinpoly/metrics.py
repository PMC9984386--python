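"""Multi-class evaluation in the one-vs-rest convention.

Each class is scored as a binary problem (that class positive, the rest
negative), yielding per-class TP/TN/FP/FN and

    accuracy  = (TP+TN) / (TP+FP+TN+FN)
    precision = TP / (TP+FP)
    recall    = TP / (TP+FN)
    F1        = 2·precision·recall / (precision+recall)

plus a one-vs-rest ROC AUC.  The report carries per-class rows, an
unweighted macro "Average" row, and the overall accuracy (fraction of
correct predictions), which differs from the per-class one-vs-rest
accuracy.  Undefined ratios (zero denominators, single-class AUC) are
reported as 0.0 with an explicit ``undefined`` flag so serialized reports
stay JSON-clean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix, roc_auc_score, roc_curve

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_counts", "prf1",
           "auc_ovr", "roc_points", "report"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _validate_labels(y: np.ndarray, n_classes: int, name: str) -> np.ndarray:
    y = np.asarray(y)
    if y.size and (y.min() < 0 or y.max() >= n_classes):
        raise ValueError(f"{name} contains labels outside 0..{n_classes - 1}")
    return y


def confusion_counts(y_true, y_pred, n_classes: int) -> list[ConfusionCounts]:
    """One-vs-rest TP/TN/FP/FN per class."""
    y_true = _validate_labels(y_true, n_classes, "y_true")
    y_pred = _validate_labels(y_pred, n_classes, "y_pred")
    cm = confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))
    total = cm.sum()
    out = []
    for k in range(n_classes):
        tp = int(cm[k, k])
        fn = int(cm[k].sum() - tp)
        fp = int(cm[:, k].sum() - tp)
        out.append(ConfusionCounts(tp=tp, tn=int(total - tp - fn - fp),
                                   fp=fp, fn=fn))
    return out


def prf1(counts: ConfusionCounts) -> dict:
    """Per-class accuracy/precision/recall/F1 from one-vs-rest counts.

    Zero denominators yield 0.0 and are listed in the ``undefined`` flag.
    """
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    acc = ratio(counts.tp + counts.tn, counts.n, "accuracy")
    prec = ratio(counts.tp, counts.tp + counts.fp, "precision")
    rec = ratio(counts.tp, counts.tp + counts.fn, "recall")
    f1 = ratio(2 * prec * rec, prec + rec, "f1") if (prec + rec) else 0.0
    if prec + rec == 0:
        undefined.append("f1")
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1,
            "undefined": undefined}


def auc_ovr(y_true, class_probs) -> tuple[list[float], float, list[int]]:
    """One-vs-rest ROC AUC per class and its macro mean.

    Ties in the scores are handled by midpoint ranking (trapezoidal area
    under the empirical ROC).  Classes absent from ``y_true`` (or covering
    all of it) have no ROC curve; they score 0.0 and are returned in the
    ``undefined`` list, and are excluded from the macro mean.
    """
    y_true = np.asarray(y_true)
    probs = np.asarray(class_probs, dtype=float)
    if probs.ndim != 2 or probs.shape[0] != y_true.shape[0]:
        raise ValueError("class_probs must be (n_samples, n_classes)")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-5):
        raise ValueError("probability rows must sum to 1")
    per_class, undefined = [], []
    for k in range(probs.shape[1]):
        pos = (y_true == k).astype(int)
        if pos.min() == pos.max():
            per_class.append(0.0)
            undefined.append(k)
        else:
            per_class.append(float(roc_auc_score(pos, probs[:, k])))
    defined = [a for k, a in enumerate(per_class) if k not in undefined]
    macro = float(np.mean(defined)) if defined else 0.0
    return per_class, macro, undefined


def roc_points(y_true, scores, positive_class: int) -> np.ndarray:
    """(fpr, tpr, threshold) rows of the one-vs-rest ROC curve."""
    pos = (np.asarray(y_true) == positive_class).astype(int)
    fpr, tpr, thr = roc_curve(pos, np.asarray(scores, dtype=float))
    return np.column_stack([fpr, tpr, thr])


@dataclass
class MetricsReport:
    class_names: list[str]
    per_class: list[dict]
    average: dict
    overall_accuracy: float
    confusion: list[list[int]]

    def to_dict(self) -> dict:
        return {
            "classes": self.class_names,
            "per_class": self.per_class,
            "average": self.average,
            "overall_accuracy": self.overall_accuracy,
            "confusion_matrix": self.confusion,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        return cls(class_names=d["classes"], per_class=d["per_class"],
                   average=d["average"], overall_accuracy=d["overall_accuracy"],
                   confusion=d["confusion_matrix"])


def report(y_true, y_pred, class_probs=None,
           class_names: list[str] | None = None) -> MetricsReport:
    """Assemble the full per-class + macro-average evaluation table."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    if class_probs is not None:
        n_classes = np.asarray(class_probs).shape[1]
    else:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    if class_names is None:
        class_names = [f"class_{k}" for k in range(n_classes)]
    if len(class_names) != n_classes:
        raise ValueError("class_names length mismatch")
    counts = confusion_counts(y_true, y_pred, n_classes)
    rows = [prf1(c) for c in counts]
    if class_probs is not None:
        aucs, macro_auc, auc_undef = auc_ovr(y_true, class_probs)
        for k, row in enumerate(rows):
            row["auc"] = aucs[k]
            if k in auc_undef:
                row["undefined"] = row["undefined"] + ["auc"]
    for name, row in zip(class_names, rows):
        row["class"] = name
    keys = ["accuracy", "precision", "recall", "f1"] + (
        ["auc"] if class_probs is not None else [])
    average = {k: float(np.mean([r[k] for r in rows])) for k in keys}
    cm = confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))
    return MetricsReport(
        class_names=list(class_names),
        per_class=rows,
        average=average,
        overall_accuracy=float((y_true == y_pred).mean()) if y_true.size else 0.0,
        confusion=cm.astype(int).tolist(),
    )
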