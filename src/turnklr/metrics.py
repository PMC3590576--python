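"""Confusion-matrix quality measures and threshold-free ROC/AUC.

Per-residue β-turn prediction is evaluated with the field's standard
measures, with ``t`` the positive class:

* MCC  = (TP·TN − FP·FN) / √((TP+FN)(TN+FP)(TP+FP)(TN+FN))
* Q_total     = 100·(TP+TN)/N          (accuracy, %)
* Q_predicted = 100·TP/(TP+FP)         (precision, %)
* Q_observed  = 100·TP/(TP+FN)         (sensitivity/coverage, %)
* Specificity = 100·TN/(TN+FP)         (%)

Because ~25% of residues sit in turns, Q_total alone is a weak measure (an
all-negative predictor scores 75%); MCC is the headline number.  Ratios
with a zero denominator are reported as an explicit ``None`` sentinel,
never silently as 0.  AUC is computed on the raw (pre-smoothing)
probabilities since the smoothing rules are threshold-dependent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .formats import TURN_ALPHABET


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion counts must describe at least one residue")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            tn=self.tn + other.tn,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
        )


@dataclass
class MetricReport:
    """Derived measures; ``None`` marks an undefined (0/0) ratio."""

    mcc: Optional[float]
    q_total: Optional[float]
    q_predicted: Optional[float]
    q_observed: Optional[float]
    specificity: Optional[float]
    auc: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "mcc": self.mcc,
            "q_total": self.q_total,
            "q_predicted": self.q_predicted,
            "q_observed": self.q_observed,
            "specificity": self.specificity,
            "auc": self.auc,
        }


def confusion(pred_labels: str, true_labels: str) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with ``t`` as the positive class."""
    if len(pred_labels) != len(true_labels):
        raise ValueError(
            f"prediction length {len(pred_labels)} != truth length {len(true_labels)}"
        )
    for s in (pred_labels, true_labels):
        for ch in s:
            if ch not in TURN_ALPHABET:
                raise ValueError(f"illegal label {ch!r}")
    tp = tn = fp = fn = 0
    for p, t in zip(pred_labels, true_labels):
        if t == "t":
            if p == "t":
                tp += 1
            else:
                fn += 1
        else:
            if p == "t":
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def compute_metrics(cc: ConfusionCounts) -> MetricReport:
    tp, tn, fp, fn = cc.tp, cc.tn, cc.fp, cc.fn

    def ratio(num: float, den: float) -> Optional[float]:
        return None if den == 0 else 100.0 * num / den

    denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    mcc = None if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricReport(
        mcc=mcc,
        q_total=ratio(tp + tn, cc.total),
        q_predicted=ratio(tp, tp + fp),
        q_observed=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
    )


def roc_auc(
    probs: Sequence[float], true_labels: str
) -> Tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) from a sweep over unique probabilities, plus AUC.

    The curve includes (0,0) and (1,1); AUC is the trapezoid area.  Raises
    on single-class truth.
    """
    probs = np.asarray(probs, dtype=float)
    if len(probs) != len(true_labels):
        raise ValueError("probs and labels lengths differ")
    y = np.array([1 if c == "t" else 0 for c in true_labels])
    if y.all() or not y.any():
        raise ValueError("both classes must be present for ROC")
    fpr, tpr, _ = _roc_curve(y, probs)
    points = np.column_stack([fpr, tpr])
    return points, float(_trapezoid_auc(fpr, tpr))


def average_reports(reports: Sequence[MetricReport]) -> MetricReport:
    """Arithmetic mean of per-fold reports, field-wise over defined values."""
    if not reports:
        raise ValueError("no reports to average")

    def mean(values: List[Optional[float]]) -> Optional[float]:
        defined = [v for v in values if v is not None]
        return None if not defined else float(np.mean(defined))

    return MetricReport(
        mcc=mean([r.mcc for r in reports]),
        q_total=mean([r.q_total for r in reports]),
        q_predicted=mean([r.q_predicted for r in reports]),
        q_observed=mean([r.q_observed for r in reports]),
        specificity=mean([r.specificity for r in reports]),
        auc=mean([r.auc for r in reports]),
    )
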