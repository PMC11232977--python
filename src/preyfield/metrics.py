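"""Confusion-matrix construction and per-class evaluation metrics for the
frame-level image classifier.

Besides the standard one-vs-rest metrics (precision, recall,
specificity, NPV, prevalence, balanced accuracy, F1), a per-class
*threat score* (critical success index) ``TP / (TP + FP + FN)`` is
reported as ``accuracy_threat_score``.  Published per-class "accuracy"
values for this kind of evaluation are often threat scores even when a
``(TP+TN)``-style formula is quoted: the threat score ignores the large
true-negative count that dominates one-vs-rest accuracy on multi-class
problems.  The conventional ``(TP+TN)/N`` is exposed separately as
``accuracy_standard`` so the two are never conflated.

Zero-denominator metrics are reported as NaN and listed in the
``undefined`` field rather than silently coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class ConfusionMatrix:
    """Truth x predicted label counts.

    ``counts`` is a square DataFrame indexed by truth label (rows) and
    predicted label (columns), over the union of observed classes in
    sorted order.
    """

    counts: pd.DataFrame

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.counts.index)

    @property
    def n_total(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest metrics for a single class.

    Counts may be non-integer when reconstructed from published rates
    (see :func:`metrics_from_rates`).
    """

    cls: str
    tp: float
    fp: float
    fn: float
    tn: float
    accuracy_threat_score: float
    accuracy_standard: float
    precision: float
    recall: float
    specificity: float
    npv: float
    prevalence: float
    balanced_accuracy: float
    f1: float
    undefined: frozenset[str] = frozenset()


def confusion(truth, predicted) -> ConfusionMatrix:
    """Build a confusion matrix from parallel truth/prediction label sequences."""
    t = list(truth)
    p = list(predicted)
    if len(t) != len(p):
        raise ValidationError(f"length mismatch: {len(t)} truth vs {len(p)} predicted labels")
    if not t:
        raise ValidationError("empty label sequences")
    classes = sorted(set(t) | set(p))
    tab = pd.crosstab(pd.Series(t, name="truth"), pd.Series(p, name="predicted"))
    tab = tab.reindex(index=classes, columns=classes, fill_value=0)
    return ConfusionMatrix(counts=tab)


def _metrics_from_counts(cls: str, tp: float, fp: float, fn: float, tn: float) -> ClassMetrics:
    n_total = tp + fp + fn + tn
    undefined: set[str] = set()

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.add(name)
            return math.nan
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    specificity = ratio(tn, tn + fp, "specificity")
    prevalence = ratio(tp + fn, n_total, "prevalence")
    threat = ratio(tp, tp + fp + fn, "accuracy_threat_score")
    standard = ratio(tp + tn, n_total, "accuracy_standard")
    # NPV via the prevalence identity
    # spec*(1-prev) / ((1-recall)*prev + spec*(1-prev)),
    # algebraically TN/(TN+FN) on count data.
    npv_den = (
        (1.0 - recall) * prevalence + specificity * (1.0 - prevalence)
        if not (math.isnan(recall) or math.isnan(specificity) or math.isnan(prevalence))
        else 0.0
    )
    npv = ratio(specificity * (1.0 - prevalence), npv_den, "npv")
    balanced = (
        (recall + specificity) / 2.0
        if not (math.isnan(recall) or math.isnan(specificity))
        else math.nan
    )
    if math.isnan(balanced):
        undefined.add("balanced_accuracy")
    f1 = ratio(2.0 * precision * recall, precision + recall, "f1") if not (
        math.isnan(precision) or math.isnan(recall)
    ) else math.nan
    if math.isnan(f1):
        undefined.add("f1")
    return ClassMetrics(
        cls=cls,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        accuracy_threat_score=threat,
        accuracy_standard=standard,
        precision=precision,
        recall=recall,
        specificity=specificity,
        npv=npv,
        prevalence=prevalence,
        balanced_accuracy=balanced,
        f1=f1,
        undefined=frozenset(undefined),
    )


def class_metrics(m: ConfusionMatrix, cls: str) -> ClassMetrics:
    """One-vs-rest metrics for ``cls`` from a confusion matrix."""
    if cls not in m.classes:
        raise ValidationError(f"class {cls!r} not in matrix classes {m.classes}")
    c = m.counts
    tp = float(c.loc[cls, cls])
    fp = float(c[cls].sum() - tp)
    fn = float(c.loc[cls].sum() - tp)
    tn = float(m.n_total - tp - fp - fn)
    return _metrics_from_counts(cls, tp, fp, fn, tn)


def metrics_from_rates(
    recall: float, precision: float, prevalence: float, n_total: float, cls: str = ""
) -> ClassMetrics:
    """Reconstruct per-class metrics from published recall/precision/prevalence.

    Useful for checking internal consistency of reported evaluation
    tables when raw counts are not deposited: the implied (generally
    non-integer) counts are ``TP = recall * prevalence * n``,
    ``FN = prevalence*n - TP``, ``FP = TP * (1 - precision)/precision``,
    ``TN = n - TP - FP - FN``.
    """
    for name, v in (("recall", recall), ("precision", precision), ("prevalence", prevalence)):
        if not 0 < v <= 1:
            raise ValidationError(f"{name} must be in (0, 1], got {v}")
    tp = recall * prevalence * n_total
    fn = prevalence * n_total - tp
    fp = tp * (1.0 - precision) / precision
    tn = n_total - tp - fp - fn
    return _metrics_from_counts(cls, tp, fp, fn, tn)


def overall_accuracy(m: ConfusionMatrix) -> float:
    """Fraction of records on the confusion-matrix diagonal."""
    if m.n_total == 0:
        raise ValidationError("empty confusion matrix")
    return float(np.trace(m.counts.to_numpy()) / m.n_total)


def metrics_table(m: ConfusionMatrix) -> pd.DataFrame:
    """Per-class metrics, one row per class (published-table layout)."""
    rows = []
    for cls in m.classes:
        cm = class_metrics(m, cls)
        rows.append(
            {
                "class": cls,
                "accuracy_threat_score": cm.accuracy_threat_score,
                "accuracy_standard": cm.accuracy_standard,
                "recall": cm.recall,
                "specificity": cm.specificity,
                "precision": cm.precision,
                "npv": cm.npv,
                "prevalence": cm.prevalence,
                "balanced_accuracy": cm.balanced_accuracy,
                "f1": cm.f1,
            }
        )
    return pd.DataFrame(rows)
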