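"""Empirical ROC curves, DeLong AUC inference and Youden cut-points.

The AUC is the trapezoidal area of the empirical curve, equal to the
Mann-Whitney two-sample statistic with ties counted one half.  DeLong's
method estimates the (co)variance of one or two correlated AUCs from
placement values — the per-subject proportions of opposite-class subjects
ranked below — giving a normal test for the paired difference of AUCs
measured on the same subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["RocCurve", "DeLongComparison", "roc_curve", "delong_variance",
           "delong_compare", "auc_ci", "youden_optimal"]


@dataclass(frozen=True)
class RocCurve:
    """Operating points (threshold, sensitivity, 1-specificity) in order of
    decreasing threshold, with trapezoidal AUC.  A subject is test-positive
    at a threshold when its score is >= that threshold; ties in score are
    grouped into a single operating point (a diagonal segment)."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


def _check_classes(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    return n_pos, n_neg


def roc_curve(scores, labels) -> RocCurve:
    """Empirical ROC curve of a score against a boolean label."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos, n_neg = _check_classes(labels)
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(
        thresholds=thr,
        sensitivity=tpr,
        one_minus_specificity=fpr,
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def _placements(scores: np.ndarray, labels: np.ndarray):
    """Placement values V10 (per positive) and V01 (per negative); their
    means both equal the AUC.  Midranks handle ties."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def delong_variance(scores, labels) -> tuple[float, float]:
    """(AUC, DeLong variance of the AUC) for one score."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _check_classes(labels)
    v10, v01 = _placements(scores, labels)
    auc = float(v10.mean())
    var = float(np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size)
    return auc, var


def auc_ci(scores, labels, ci_level: float = 0.95) -> tuple[float, float, float]:
    """AUC with a DeLong normal-approximation CI: (auc, lower, upper)."""
    auc, var = delong_variance(scores, labels)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    half = z * np.sqrt(var)
    return auc, max(auc - half, 0.0), min(auc + half, 1.0)


@dataclass(frozen=True)
class DeLongComparison:
    """Paired comparison of two AUCs measured on the same subjects."""

    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    covariance: float
    z: float
    p_value: float


def delong_compare(scores_a, scores_b, labels) -> DeLongComparison:
    """DeLong's test for the difference of two correlated AUCs.

    Scores must be paired on identical subjects; the two-sided p-value is
    from the normal approximation to the AUC difference.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not (scores_a.shape == scores_b.shape == labels.shape):
        raise ValueError("scores_a, scores_b and labels must have equal length")
    _check_classes(labels)
    va10, va01 = _placements(scores_a, labels)
    vb10, vb01 = _placements(scores_b, labels)
    m, n = va10.size, va01.size
    auc_a, auc_b = float(va10.mean()), float(vb10.mean())
    var_a = float(np.var(va10, ddof=1) / m + np.var(va01, ddof=1) / n)
    var_b = float(np.var(vb10, ddof=1) / m + np.var(vb01, ddof=1) / n)
    cov = float(
        np.cov(va10, vb10, ddof=1)[0, 1] / m + np.cov(va01, vb01, ddof=1)[0, 1] / n
    )
    var_diff = var_a + var_b - 2.0 * cov
    if var_diff <= 0.0:
        z, p = 0.0, 1.0
    else:
        z = (auc_a - auc_b) / np.sqrt(var_diff)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return DeLongComparison(
        auc_a=auc_a,
        auc_b=auc_b,
        var_a=var_a,
        var_b=var_b,
        covariance=cov,
        z=float(z),
        p_value=p,
    )


def youden_optimal(scores, labels) -> tuple[float, float]:
    """Cut-point maximising Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are the distinct score values (positive means
    score >= threshold); the smallest threshold achieving the maximal J is
    returned, favouring sensitivity on ties.
    """
    curve = roc_curve(scores, labels)
    j = curve.sensitivity - curve.one_minus_specificity
    finite = np.isfinite(curve.thresholds)
    j_max = j[finite].max()
    candidates = curve.thresholds[finite & (j >= j_max - 1e-12)]
    return float(candidates.min()), float(j_max)
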