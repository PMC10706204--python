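"""Evaluation metrics: confusion-matrix scores, ROC/AUC, Kendall tau-b.

Threshold metrics are macro-averaged over one-vs-rest class decompositions:
ACC is trace/total; per-class sensitivity TP/(TP+FN), precision TP/(TP+FP),
specificity TN/(TN+FP); the F-measure is the harmonic mean of the macro
precision and macro sensitivity.  All are reported as percentages.

AUC is the area under the one-vs-rest ROC per class plus a micro average
that pools every (score, binary label) pair across classes into one curve.
Kendall's tau-b relates feature values to the ordinal grades with tie
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "confusion_matrix_counts",
    "confusion_metrics",
    "roc_auc",
    "kendall_tau_b",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # K x K ints, rows = true, cols = predicted
    classes: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion-matrix entries must be non-negative")


@dataclass
class MetricReport:
    """Percentages throughout; per-class entries keyed by class label."""

    acc: float
    sen: float
    pre: float
    spe: float
    f_measure: float
    per_class: dict = field(default_factory=dict)
    auc_per_class: dict = field(default_factory=dict)
    auc_micro: float | None = None

    def as_dict(self) -> dict:
        return {
            "ACC": self.acc,
            "SEN": self.sen,
            "PRE": self.pre,
            "SPE": self.spe,
            "F": self.f_measure,
            "AUC_micro": self.auc_micro,
            "AUC_per_class": dict(self.auc_per_class),
            "per_class": {str(k): v for k, v in self.per_class.items()},
        }


def confusion_matrix_counts(y_true, y_pred, classes=None) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


def confusion_metrics(cm: ConfusionMatrix) -> MetricReport:
    """ACC and macro-averaged one-vs-rest SEN/PRE/SPE (+ F) in percent.

    Classes with a zero denominator contribute 0 to the macro average, with
    a warning.
    """
    counts = cm.counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    acc = np.trace(counts) / total
    sens, pres, spes = [], [], []
    per_class = {}
    for k, cls in enumerate(cm.classes):
        tp = counts[k, k]
        fn = counts[k].sum() - tp
        fp = counts[:, k].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0 or tp + fp == 0 or tn + fp == 0:
            warnings.warn(f"class {cls}: zero denominator; metric set to 0")
        sen = tp / (tp + fn) if tp + fn else 0.0
        pre = tp / (tp + fp) if tp + fp else 0.0
        spe = tn / (tn + fp) if tn + fp else 0.0
        sens.append(sen)
        pres.append(pre)
        spes.append(spe)
        per_class[cls] = {"SEN": 100 * sen, "PRE": 100 * pre, "SPE": 100 * spe}
    m_sen = float(np.mean(sens))
    m_pre = float(np.mean(pres))
    f = 2 * m_pre * m_sen / (m_pre + m_sen) if (m_pre + m_sen) > 0 else 0.0
    return MetricReport(
        acc=100 * float(acc),
        sen=100 * m_sen,
        pre=100 * m_pre,
        spe=100 * float(np.mean(spes)),
        f_measure=100 * f,
        per_class=per_class,
    )


def roc_auc(scores: np.ndarray, y_true, classes) -> dict:
    """One-vs-rest AUC per class and the micro average, in percent.

    `scores` has one column per entry of `classes`.  A class absent from
    the truth has undefined AUC and is excluded with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    classes = np.asarray(classes)
    per_class: dict = {}
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for k, cls in enumerate(classes):
        binary = (y_true == cls).astype(int)
        pooled_scores.append(scores[:, k])
        pooled_labels.append(binary)
        if binary.min() == binary.max():
            warnings.warn(f"class {cls} absent from truth (or fills it); AUC undefined")
            continue
        per_class[cls] = 100 * float(roc_auc_score(binary, scores[:, k]))
    micro_labels = np.concatenate(pooled_labels)
    micro_scores = np.concatenate(pooled_scores)
    micro = 100 * float(roc_auc_score(micro_labels, micro_scores))
    return {"per_class": per_class, "micro": micro}


def kendall_tau_b(x, y) -> tuple[float, float]:
    """Kendall's tau-b with tie correction; two-sided p from the normal
    approximation.  All-tied input in either vector is an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau-b undefined for an all-tied vector")
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
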