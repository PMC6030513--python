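"""ROC analysis, threshold calibration and screening-burden statistics.

Implements the evaluation toolkit for citation screening classifiers:
confusion counts at a threshold (a prediction is positive at score >=
threshold), sensitivity/specificity/precision, the number needed to
screen (NNS, the reciprocal of precision: how many algorithm-positive
articles must be read on average to find one true RCT), ROC curves with
trapezoid AUROC, DeLong normal-approximation AUROC confidence intervals,
adjusted-Wald confidence intervals for paired differences in proportions,
calibration of a score cutoff to a sensitivity or specificity floor, and
the screening-burden projection that translates a filter's sensitivity
and specificity into expected true/false positive counts at corpus scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import roc_curve as _sk_roc_curve, auc as _sk_auc

__all__ = [
    "ConfusionCounts",
    "OperatingPoint",
    "RocCurve",
    "BurdenTree",
    "UndefinedMetricError",
    "confusion_at",
    "metrics",
    "roc_and_auroc",
    "auroc_ci",
    "bootstrap_auroc",
    "paired_diff_ci",
    "calibrate_threshold",
    "screening_burden",
    "rank_by_score",
    "operating_point_table",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero (e.g. precision with no positives)."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class OperatingPoint:
    """A threshold with its error profile. ``nns`` is 1/precision."""

    threshold: float
    sensitivity: float
    specificity: float
    precision: float
    nns: float


@dataclass(frozen=True)
class RocCurve:
    """ROC triples ordered from the highest threshold (+inf) downward."""

    thresholds: np.ndarray
    sensitivity: np.ndarray  # true positive rate
    fpr: np.ndarray  # 1 - specificity


@dataclass(frozen=True)
class BurdenTree:
    """Projected screening burden of a filter at corpus scale."""

    total_articles: int
    n_rct: int
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def retrieved_total(self) -> int:
        return self.tp + self.fp

    @property
    def precision(self) -> float:
        if self.retrieved_total == 0:
            raise UndefinedMetricError("no articles retrieved; precision undefined")
        return self.tp / self.retrieved_total


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    return s, y


def confusion_at(scores, labels, threshold: float) -> ConfusionCounts:
    """2x2 counts with positive prediction at score >= threshold."""
    s, y = _check_scores_labels(scores, labels)
    pred = s >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
        tn=int(np.sum(~pred & (y == 0))),
    )


def metrics(c: ConfusionCounts, threshold: float = float("nan")) -> OperatingPoint:
    """Sensitivity, specificity, precision and NNS from a 2x2 table.

    Raises :class:`UndefinedMetricError` on any zero denominator rather
    than silently returning 0.
    """
    if c.n_pos == 0:
        raise UndefinedMetricError("no positives; sensitivity undefined")
    if c.n_neg == 0:
        raise UndefinedMetricError("no negatives; specificity undefined")
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("no predicted positives; precision undefined")
    precision = c.tp / (c.tp + c.fp)
    if precision == 0.0:
        raise UndefinedMetricError("zero precision; NNS undefined")
    return OperatingPoint(
        threshold=threshold,
        sensitivity=c.tp / c.n_pos,
        specificity=c.tn / c.n_neg,
        precision=precision,
        nns=1.0 / precision,
    )


def roc_and_auroc(scores, labels) -> tuple[RocCurve, float]:
    """ROC curve over all distinct thresholds plus trapezoid AUROC.

    Tied scores are grouped into a single threshold step; the curve runs
    from (0, 0) at threshold +inf to (1, 1) below the minimum score.
    """
    s, y = _check_scores_labels(scores, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    return RocCurve(thresholds=thr, sensitivity=tpr, fpr=fpr), float(_sk_auc(fpr, tpr))


# -- DeLong AUROC variance ---------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n)
    out[order] = ranks
    return out


def _delong_auc_var(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUROC and its DeLong structural-components variance."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m < 2 or n < 2:
        raise ValueError("need at least 2 members of each class")
    allx = np.concatenate([pos, neg])
    tx = _midrank(allx)
    tpos = _midrank(pos)
    tneg = _midrank(neg)
    auc = (tx[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tx[:m] - tpos) / n  # structural components of the positives
    v10 = 1.0 - (tx[m:] - tneg) / m  # and of the negatives
    var = np.var(v01, ddof=1) / m + np.var(v10, ddof=1) / n
    return float(auc), float(var)


def auroc_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong normal-approximation AUROC interval, truncated to [0, 1]."""
    s, y = _check_scores_labels(scores, labels)
    if np.unique(s).size == 1:
        raise ValueError("all scores tied; AUROC interval degenerate")
    auc, var = _delong_auc_var(s, y)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return (max(0.0, auc - half), min(1.0, auc + half))


def bootstrap_auroc(
    scores, labels, n_boot: int = 2000, level: float = 0.95, seed: int = 0
) -> tuple[float, float, tuple[float, float]]:
    """Stratified-bootstrap AUROC cross-check.

    Returns (mean bootstrap AUROC, bootstrap SE, percentile interval).
    """
    s, y = _check_scores_labels(scores, labels)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        pi = rng.choice(pos, size=len(pos), replace=True)
        ni = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([pi, ni])
        _, aucs[b] = roc_and_auroc(s[idx], y[idx])
    alpha = 1.0 - level
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(aucs.mean()), float(aucs.std(ddof=1)), (float(lo), float(hi))


def paired_diff_ci(
    discordant_b: int, discordant_c: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Adjusted-Wald interval for a paired difference in proportions.

    For matched pairs with discordant counts *b* and *c* out of *n*, adds
    0.5 to each discordant cell (and 1 to n), then applies the Wald
    formula for (b - c)/n; truncated to [-1, 1].
    """
    if discordant_b < 0 or discordant_c < 0 or n <= 0:
        raise ValueError("counts must be non-negative and n positive")
    if discordant_b + discordant_c > n:
        raise ValueError("discordant counts exceed n")
    b = discordant_b + 0.5
    c = discordant_c + 0.5
    n_adj = n + 1.0
    d = (b - c) / n_adj
    se = np.sqrt(b + c - (b - c) ** 2 / n_adj) / n_adj
    z = norm.ppf(0.5 + level / 2.0)
    return (max(-1.0, d - z * se), min(1.0, d + z * se))


def _operating_points(scores: np.ndarray, labels: np.ndarray):
    """Operating points at every distinct threshold plus a reject-all one."""
    uniq = np.unique(scores)[::-1]  # descending
    thresholds = np.concatenate([[np.inf], uniq])
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    for t in thresholds:
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        yield t, tp / n_pos, (n_neg - fp) / n_neg, tp, fp


def calibrate_threshold(
    scores,
    labels,
    target_sensitivity: float | None = None,
    target_specificity: float | None = None,
) -> OperatingPoint:
    """Choose the score cutoff matching a use-case operating target.

    With a sensitivity floor *s*: the largest threshold whose sensitivity
    is >= s (thus maximal specificity subject to the floor). With a
    specificity floor: the smallest threshold whose specificity is >= s
    (maximal sensitivity subject to the floor). Exactly one target must be
    given, in (0, 1].
    """
    if (target_sensitivity is None) == (target_specificity is None):
        raise ValueError("specify exactly one of target_sensitivity/target_specificity")
    target = target_sensitivity if target_sensitivity is not None else target_specificity
    if not 0.0 < target <= 1.0:
        raise ValueError("target must be in (0, 1]")
    s, y = _check_scores_labels(scores, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    best = None
    for t, sens, spec, tp, fp in _operating_points(s, y):
        if target_sensitivity is not None:
            # thresholds are visited in decreasing order; sensitivity only
            # grows, so the first hit is the largest qualifying threshold
            if sens >= target:
                best = (t, sens, spec, tp, fp)
                break
        else:
            # specificity only shrinks as the threshold drops; remember the
            # last (smallest) qualifying threshold
            if spec >= target:
                best = (t, sens, spec, tp, fp)
    if best is None:
        raise ValueError("no threshold attains the requested target")
    t, sens, spec, tp, fp = best
    if tp + fp > 0 and tp > 0:
        precision = tp / (tp + fp)
        nns = 1.0 / precision
    else:
        precision = float("nan")
        nns = float("nan")
    return OperatingPoint(
        threshold=float(t), sensitivity=sens, specificity=spec,
        precision=precision, nns=nns,
    )


def screening_burden(
    total_articles: int, n_rct: int, sensitivity: float, specificity: float
) -> BurdenTree:
    """Expected confusion counts of a filter applied to a whole corpus.

    True/false positives are the nearest integers to the expected counts:
    ``tp = round(sens * n_rct)``, ``fp = round((1 - spec) * n_non_rct)``.
    """
    if n_rct > total_articles:
        raise ValueError("n_rct cannot exceed total_articles")
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    n_non = total_articles - n_rct
    tp = round(sensitivity * n_rct)
    fp = round((1.0 - specificity) * n_non)
    return BurdenTree(
        total_articles=total_articles,
        n_rct=n_rct,
        tp=tp,
        fp=fp,
        fn=n_rct - tp,
        tn=n_non - fp,
    )


def rank_by_score(citations: Sequence, scores) -> list:
    """Citations in stable descending score order (ties keep input order)."""
    s = np.asarray(scores, dtype=float)
    if len(citations) != len(s):
        raise ValueError("citations and scores must have equal length")
    order = np.argsort(-s, kind="stable")
    return [citations[i] for i in order]


def operating_point_table(scores, labels) -> pd.DataFrame:
    """One row per distinct threshold: sensitivity, specificity, precision, NNS."""
    s, y = _check_scores_labels(scores, labels)
    rows = []
    for t, sens, spec, tp, fp in _operating_points(s, y):
        precision = tp / (tp + fp) if tp + fp > 0 else np.nan
        nns = 1.0 / precision if tp > 0 else np.nan
        rows.append(
            {
                "threshold": t,
                "sensitivity": sens,
                "specificity": spec,
                "precision": precision,
                "nns": nns,
            }
        )
    return pd.DataFrame(rows)
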