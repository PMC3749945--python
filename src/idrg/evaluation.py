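"""Classifier benchmarking: ROC/AUC, Matthews correlation, threshold choice
with half-sample resampling, and rank-based group comparison.

Positive scores are the Rg/N^ν statistics of known disordered segments,
negative scores those of structured chains; a case is called positive when
its statistic is strictly greater than the threshold. The optimal threshold
is the grid point maximizing the mean MCC over repeated half-sample draws
of both classes (1000 repetitions by default, seeded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "EvalResult",
    "confusion_at",
    "mcc",
    "roc_auc",
    "resampled_mcc_curve",
    "choose_threshold",
    "evaluate_classifier",
    "rank_sum_compare",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def fdr(self) -> float:
        called = self.TP + self.FP
        return self.FP / called if called else 0.0

    @property
    def sensitivity(self) -> float:
        pos = self.TP + self.FN
        return self.TP / pos if pos else 0.0


def confusion_at(pos: Sequence[float], neg: Sequence[float], threshold: float) -> ConfusionCounts:
    """Confusion counts at a threshold; a case is called positive iff its
    score is strictly greater than the threshold."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    tp = int(np.count_nonzero(pos > threshold))
    fp = int(np.count_nonzero(neg > threshold))
    return ConfusionCounts(TP=tp, TN=neg.size - fp, FP=fp, FN=pos.size - tp)


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 by convention when any factor of
    the denominator vanishes."""
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def roc_auc(pos: Sequence[float], neg: Sequence[float]) -> tuple[list[tuple[float, float]], float]:
    """ROC curve over all distinct score thresholds and trapezoid AUC.

    Tied positive/negative scores advance TPR and FPR in one step, which
    makes the trapezoid AUC equal the Mann–Whitney statistic (ties counted
    half).
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    scores = np.unique(np.concatenate([pos, neg]))[::-1]
    points = [(0.0, 0.0)]
    for t in scores:
        tpr = np.count_nonzero(pos >= t) / pos.size
        fpr = np.count_nonzero(neg >= t) / neg.size
        points.append((float(fpr), float(tpr)))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return points, auc


def resampled_mcc_curve(
    pos: Sequence[float],
    neg: Sequence[float],
    grid: Sequence[float],
    n_reps: int = 1000,
    seed: int | None = None,
) -> list[tuple[float, float, float]]:
    """Mean ± sd of the MCC at each grid threshold over ``n_reps`` random
    half-samples of each class (drawn without replacement, seeded)."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("each class needs at least 2 members for half-sampling")
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    half_p, half_n = pos.size // 2, neg.size // 2
    mccs = np.empty((n_reps, grid.size))
    for rep in range(n_reps):
        p = rng.choice(pos, size=half_p, replace=False)
        n = rng.choice(neg, size=half_n, replace=False)
        for k, t in enumerate(grid):
            mccs[rep, k] = mcc(confusion_at(p, n, t))
    means = mccs.mean(axis=0)
    sds = mccs.std(axis=0, ddof=1)
    return [(float(t), float(m), float(s)) for t, m, s in zip(grid, means, sds)]


def choose_threshold(curve: list[tuple[float, float, float]]) -> tuple[float, float, float]:
    """Grid point with the highest mean MCC (lowest threshold on ties);
    returns (threshold, mean MCC, sd)."""
    best = max(curve, key=lambda row: (row[1], -row[0]))
    return best


@dataclass
class EvalResult:
    roc_points: list[tuple[float, float]]
    auc: float
    mcc_curve: list[tuple[float, float, float]]
    best_threshold: float
    best_mcc: float
    best_mcc_sd: float
    fdr: float
    sensitivity: float
    seed: int | None = None


def evaluate_classifier(
    pos: Sequence[float],
    neg: Sequence[float],
    grid: Sequence[float],
    n_reps: int = 1000,
    seed: int | None = None,
) -> EvalResult:
    """Full benchmark: ROC/AUC on the complete data, resampled MCC curve,
    threshold selection, and FDR/sensitivity at the chosen threshold
    re-evaluated on the complete data."""
    points, auc = roc_auc(pos, neg)
    curve = resampled_mcc_curve(pos, neg, grid, n_reps=n_reps, seed=seed)
    t, m, s = choose_threshold(curve)
    full = confusion_at(pos, neg, t)
    return EvalResult(
        roc_points=points,
        auc=auc,
        mcc_curve=curve,
        best_threshold=t,
        best_mcc=m,
        best_mcc_sd=s,
        fdr=full.fdr,
        sensitivity=full.sensitivity,
        seed=seed,
    )


def rank_sum_compare(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided two-sample rank-sum (Mann–Whitney) test.

    Exact enumeration when the combined sample is small (n ≤ 12) and
    tie-free; otherwise the normal approximation with tie correction.
    Returns (U statistic, p value).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
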