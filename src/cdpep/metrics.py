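"""Confusion-matrix metrics, AUROC, and the evaluation split protocol.

Sensitivity, specificity and accuracy are reported in percent (matching
the field's tabulation style); F1, MCC and AUROC as fractions.  The split
protocol is a stratified 80:20 hold-out with five stratified folds over
the training portion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split

from .sequences import PeptideDataset


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    """Standard 2x2 counts; 1 is the positive class."""
    if len(labels) != len(predictions):
        raise ValueError(
            f"length mismatch: {len(labels)} labels vs {len(predictions)} predictions"
        )
    if len(labels) == 0:
        raise ValueError("need at least one item")
    tp = tn = fp = fn = 0
    for y, p in zip(labels, predictions):
        if y == 1:
            if p == 1:
                tp += 1
            else:
                fn += 1
        else:
            if p == 1:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp, tn, fp, fn)


@dataclass(frozen=True)
class MetricsReport:
    """Threshold-dependent metrics (percent) plus F1/MCC/AUROC (fractions)."""

    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    mcc: float
    auroc: Optional[float] = None


def compute_metrics(counts: ConfusionCounts, auroc: Optional[float] = None) -> MetricsReport:
    """Evaluate the closed-form confusion-matrix metrics.

    Sens = 100*TP/(TP+FN), Spec = 100*TN/(TN+FP), Acc = 100*(TP+TN)/total,
    F1 = 2TP/(2TP+FP+FN), MCC = (TP*TN - FP*FN)/sqrt(prod of marginals).
    Any metric with a zero denominator is defined as 0 (MCC convention for
    a degenerate marginal; likewise Sens/Spec/F1 on an absent class).
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    if counts.total == 0:
        raise ValueError("empty confusion matrix")
    sens = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    spec = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    acc = 100.0 * (tp + tn) / counts.total
    f1 = 2.0 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = ((tp * tn) - (fp * fn)) / denom if denom else 0.0
    return MetricsReport(sens, spec, acc, f1, mcc, auroc)


def mean_report(reports: Sequence[MetricsReport]) -> MetricsReport:
    """Unweighted mean of per-fold metric reports."""
    vals = {}
    for f in fields(MetricsReport):
        xs = [getattr(r, f.name) for r in reports]
        if any(x is None for x in xs):
            vals[f.name] = None
        else:
            vals[f.name] = float(np.mean(xs))
    return MetricsReport(**vals)


def auroc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) statistic.

    The probability that a randomly chosen positive outscores a randomly
    chosen negative, with ties counted one half; identical to trapezoidal
    integration of the ROC curve.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    rank_sum_pos = ranks[y == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class SplitPlan:
    """Stratified 80:20 hold-out plus five folds over the training ids."""

    train_ids: list[str]
    validation_ids: list[str]
    folds: list[list[str]]
    seed: int


def make_split(dataset: PeptideDataset, seed: int, n_folds: int = 5) -> SplitPlan:
    """Stratified shuffle into 80% train / 20% validation, then ``n_folds``
    stratified folds partitioning the training ids.  Deterministic given
    the seed; per-class fold sizes differ by at most one.
    """
    ids = np.array(dataset.ids())
    y = np.array(dataset.y())
    for cls in (0, 1):
        if (y == cls).sum() < n_folds:
            raise ValueError(f"need at least {n_folds} items per class")
    tr_idx, va_idx = train_test_split(
        np.arange(len(ids)), test_size=0.2, stratify=y, random_state=seed
    )
    tr_idx = np.sort(tr_idx)
    va_idx = np.sort(va_idx)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [
        ids[tr_idx[test]].tolist() for _, test in skf.split(tr_idx, y[tr_idx])
    ]
    return SplitPlan(ids[tr_idx].tolist(), ids[va_idx].tolist(), folds, seed)
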