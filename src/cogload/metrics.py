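"""Classification evaluation surface.

Confusion matrix, one-vs-rest per-class sensitivity / specificity /
balanced accuracy and precision / recall / F1, overall accuracy with an
exact (Clopper-Pearson) confidence interval and a one-sided exact binomial
test against the no-information rate, Cohen's kappa, and ROC/AUC for the
low-vs-high contrast within each task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "RocResult",
    "confusion_matrix",
    "class_metrics",
    "balanced_accuracy",
    "f1_score",
    "overall_accuracy_ci",
    "cohens_kappa",
    "roc_auc",
    "evaluation_report",
]


@dataclass
class ConfusionMatrix:
    """Integer counts; rows are true classes, columns predicted."""

    classes: list
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


@dataclass
class ClassMetrics:
    cls: object
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    precision: float
    recall: float
    f1: float


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def confusion_matrix(true, pred, classes: list | None = None) -> ConfusionMatrix:
    true = np.asarray(true)
    pred = np.asarray(pred)
    if true.shape != pred.shape:
        raise ValueError("label sequences must have equal length")
    if classes is None:
        classes = sorted(set(true.tolist()))
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true, pred):
        if t not in index or p not in index:
            raise ValueError(f"label outside the class set: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(classes=list(classes), counts=counts)


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Mean of sensitivity and specificity."""
    return (sensitivity + specificity) / 2.0


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


def class_metrics(cm: ConfusionMatrix, cls) -> ClassMetrics:
    """One-vs-rest metrics for one class; undefined ratios become NaN."""
    if cls not in cm.classes:
        raise ValueError(f"class {cls!r} not in confusion matrix")
    i = cm.classes.index(cls)
    tp = cm.counts[i, i]
    fn = cm.counts[i, :].sum() - tp
    fp = cm.counts[:, i].sum() - tp
    tn = cm.total - tp - fn - fp

    def ratio(num, den):
        return float(num) / float(den) if den > 0 else float("nan")

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    return ClassMetrics(
        cls=cls,
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=balanced_accuracy(sens, spec),
        precision=prec,
        recall=sens,
        f1=f1_score(prec, sens),
    )


def overall_accuracy_ci(cm: ConfusionMatrix, level: float = 0.95) -> dict:
    """Accuracy, exact binomial CI, and one-sided test against the NIR.

    The no-information rate is the largest true-class frequency in the
    evaluated set; the p-value is the one-sided exact binomial probability
    of at least the observed number of correct predictions under it.
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    correct = int(np.trace(cm.counts))
    acc = correct / total
    test = stats.binomtest(correct, total, p=0.5)  # placeholder p; the CI only needs k, n
    ci = test.proportion_ci(confidence_level=level, method="exact")
    nir = float(cm.counts.sum(axis=1).max()) / total
    p_value = float(stats.binomtest(correct, total, p=nir, alternative="greater").pvalue)
    return {
        "accuracy": acc,
        "ci_low": float(ci.low),
        "ci_high": float(ci.high),
        "level": level,
        "nir": nir,
        "p_value": p_value,
    }


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement; NaN when expected agreement is 1."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    po = np.trace(cm.counts) / total
    marg = cm.counts.sum(axis=1) / total, cm.counts.sum(axis=0) / total
    pe = float(np.dot(*marg))
    if pe >= 1.0:
        return float("nan")
    return float((po - pe) / (1.0 - pe))


def roc_auc(scores, labels, positive=None) -> RocResult:
    """ROC by threshold sweep and trapezoidal AUC for a binary contrast.

    ``scores`` are posterior probabilities (or discriminant scores) of the
    positive class.  Both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError(f"ROC needs exactly 2 classes, got {classes}")
    positive = positive if positive is not None else classes[1]
    y = (labels == positive).astype(int)
    if y.sum() in (0, len(y)):
        raise ValueError("one class absent from the evaluated rows")
    fpr, tpr, thr = _roc_curve(y, scores)
    return RocResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_trapezoid_auc(fpr, tpr)))


def evaluation_report(true, pred, posteriors=None, classes=None, tasks=None, loads=None) -> dict:
    """Full evaluation of a multiclass prediction set.

    When ``posteriors`` (rows x classes), ``tasks`` and ``loads`` are given,
    per-task low-vs-high ROC/AUC is computed from the posterior probability
    of the task's high-load class.
    """
    cm = confusion_matrix(true, pred, classes=classes)
    report = {
        "confusion_matrix": cm,
        "overall": overall_accuracy_ci(cm),
        "kappa": cohens_kappa(cm),
        "per_class": {c: class_metrics(cm, c) for c in cm.classes},
    }
    if posteriors is not None and tasks is not None:
        posteriors = np.asarray(posteriors, dtype=float)
        tasks = np.asarray(tasks)
        loads = np.asarray(loads)
        true = np.asarray(true)
        roc = {}
        for task, high_cls in (("mental_calculation", "mc_high"), ("visual_search", "vs_high")):
            sel = tasks == task
            if sel.sum() == 0 or len(set(loads[sel].tolist())) < 2:
                continue
            j = cm.classes.index(high_cls)
            roc[task] = roc_auc(posteriors[sel, j], loads[sel], positive="high")
        report["roc"] = roc
    return report
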