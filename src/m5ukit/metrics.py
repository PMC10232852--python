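"""Binary-classification metrics for site prediction.

The confusion-count statistics follow the standard definitions

.. math::

    ACC = \\frac{TP + TN}{TP + FP + TN + FN} \\qquad
    PRE = \\frac{TP}{TP + FP} \\qquad
    Recall = \\frac{TP}{TP + FN}

.. math::

    F = \\frac{2\\,TP}{2\\,TP + FP + FN} \\qquad
    MCC = \\frac{TP \\cdot TN - FN \\cdot FP}
               {\\sqrt{(TP+FN)(TN+FP)(TP+FP)(TN+FN)}}

with label 1 the positive (modified) class.  Degenerate denominators — an
empty predicted-positive margin, an empty class — return 0 with a warning
rather than raising, so heavily imbalanced (1:10) evaluations stay total.

ROC and PR curves and their areas are delegated to scikit-learn: thresholds
sweep the unique scores descending, the ROC area is trapezoidal, and the PR
area uses the step-interpolation (average-precision) convention, which avoids
the optimistic bias of trapezoidal PR interpolation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.metrics import (auc, average_precision_score, precision_recall_curve,
                             roc_curve as _sk_roc_curve)

__all__ = [
    "ConfusionCounts", "MetricReport", "CurvePoints",
    "confusion", "accuracy", "precision", "recall", "f_value", "mcc",
    "roc_curve", "pr_curve", "auroc", "aupr", "evaluate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table (label 1 = positive)."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("empty confusion table")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricReport:
    """The seven-metric summary plus the underlying counts."""

    acc: float
    pre: float
    f_value: float
    recall: float
    mcc: float
    auroc: float
    aupr: float
    counts: ConfusionCounts
    n: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def __str__(self) -> str:
        c = self.counts
        lines = [
            f"{'metric':<8}{'value':>10}",
            f"{'ACC':<8}{self.acc:>10.4f}",
            f"{'PRE':<8}{self.pre:>10.4f}",
            f"{'F-value':<8}{self.f_value:>10.4f}",
            f"{'Recall':<8}{self.recall:>10.4f}",
            f"{'MCC':<8}{self.mcc:>10.4f}",
            f"{'auROC':<8}{self.auroc:>10.4f}",
            f"{'auPR':<8}{self.aupr:>10.4f}",
            "",
            f"confusion (n={self.n}): TP={c.TP} FP={c.FP} TN={c.TN} FN={c.FN}",
        ]
        return "\n".join(lines)


@dataclass
class CurvePoints:
    """An ordered operating curve: (FPR, TPR) for ROC, (recall, precision) for PR."""

    x: np.ndarray
    y: np.ndarray
    thresholds: np.ndarray
    kind: str

    def to_csv(self, path) -> None:
        header = {"roc": "fpr,tpr", "pr": "recall,precision"}[self.kind]
        np.savetxt(path, np.column_stack([self.x, self.y]), delimiter=",",
                   header=header, comments="")


def _as_binary(v) -> np.ndarray:
    v = np.asarray(v).astype(int)
    if not np.isin(v, (0, 1)).all():
        raise ValueError("labels/predictions must be binary (0/1)")
    return v


def confusion(labels, predicted) -> ConfusionCounts:
    """Count the 2x2 table from equal-length binary vectors."""
    y = _as_binary(labels)
    p = _as_binary(predicted)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    return ConfusionCounts(
        TP=int(np.sum((y == 1) & (p == 1))),
        FP=int(np.sum((y == 0) & (p == 1))),
        TN=int(np.sum((y == 0) & (p == 0))),
        FN=int(np.sum((y == 1) & (p == 0))),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"degenerate denominator in {name}; returning 0", stacklevel=3)
        return 0.0
    return num / den


def accuracy(c: ConfusionCounts) -> float:
    return _ratio(c.TP + c.TN, c.total, "accuracy")


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.TP, c.TP + c.FP, "precision")


def recall(c: ConfusionCounts) -> float:
    return _ratio(c.TP, c.TP + c.FN, "recall")


def f_value(c: ConfusionCounts) -> float:
    return _ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN, "f_value")


def mcc(c: ConfusionCounts) -> float:
    num = c.TP * c.TN - c.FN * c.FP
    den2 = float(c.TP + c.FN) * (c.TN + c.FP) * (c.TP + c.FP) * (c.TN + c.FN)
    if den2 == 0:
        warnings.warn("degenerate denominator in mcc; returning 0", stacklevel=2)
        return 0.0
    return num / np.sqrt(den2)


def _check_scores(labels, scores):
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    if y.min() == y.max():
        raise ValueError("need at least one positive and one negative label")
    return y, s


def roc_curve(labels, scores) -> CurvePoints:
    """ROC curve; tied scores are grouped into single threshold steps."""
    y, s = _check_scores(labels, scores)
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    return CurvePoints(x=fpr, y=tpr, thresholds=thr, kind="roc")


def pr_curve(labels, scores) -> CurvePoints:
    """Precision-recall curve ordered by increasing recall."""
    y, s = _check_scores(labels, scores)
    prec, rec, thr = precision_recall_curve(y, s)
    # sklearn returns decreasing recall; present increasing, thresholds aligned
    return CurvePoints(x=rec[::-1], y=prec[::-1], thresholds=thr[::-1], kind="pr")


def auroc(labels, scores) -> float:
    """Trapezoidal area under the ROC curve (= concordance probability)."""
    c = roc_curve(labels, scores)
    return float(auc(c.x, c.y))


def aupr(labels, scores) -> float:
    """Step-interpolated (average precision) area under the PR curve."""
    y, s = _check_scores(labels, scores)
    return float(average_precision_score(y, s))


def evaluate(labels, scores, threshold: float = 0.5) -> MetricReport:
    """Full seven-metric report from scores (class = score >= threshold)."""
    y, s = _check_scores(labels, scores)
    c = confusion(y, (s >= threshold).astype(int))
    return MetricReport(
        acc=accuracy(c), pre=precision(c), f_value=f_value(c), recall=recall(c),
        mcc=mcc(c), auroc=auroc(y, s), aupr=aupr(y, s), counts=c, n=c.total,
    )
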