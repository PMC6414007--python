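"""Performance and distribution statistics.

Confusion-matrix metrics (sensitivity, specificity, predictive values,
F1, Matthews correlation), ROC curves with trapezoidal AUC, the optimum
ROC operating point, the Wilcoxon rank-sum test with common-language
effect size, and the distance-between-medians / overall-visible-spread
ratio used to compare feature distributions between classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import DegenerateInputError, ParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies; positives are wheeze events."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ParameterError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_metrics(c: ConfusionCounts) -> dict[str, float]:
    """SE, SP, PPV, NPV; a metric with zero denominator is NaN (missing)."""
    if c.total == 0:
        raise ParameterError("all confusion counts are zero")

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return {
        "SE": ratio(c.tp, c.tp + c.fn),
        "SP": ratio(c.tn, c.tn + c.fp),
        "PPV": ratio(c.tp, c.tp + c.fp),
        "NPV": ratio(c.tn, c.tn + c.fn),
    }


def f1_score(c: ConfusionCounts) -> float:
    """F1 = 2TP / (2TP + FP + FN); NaN when undefined."""
    den = 2 * c.tp + c.fp + c.fn
    return 2 * c.tp / den if den > 0 else float("nan")


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 by convention when any
    marginal sum is zero."""
    margins = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if margins == 0:
        logger.debug("MCC marginal sum zero; returning 0 by convention")
        return 0.0
    return ((c.tp * c.tn) - (c.fp * c.fn)) / float(np.sqrt(margins))


@dataclass
class ROCCurve:
    """(sensitivity, specificity) pairs along the threshold sweep,
    endpoints (0,1) and (1,0) included, in the oriented direction."""

    sensitivity: np.ndarray
    specificity: np.ndarray
    direction: str  # 'greater' means larger values indicate wheeze

    def points(self) -> np.ndarray:
        return np.column_stack([self.sensitivity, self.specificity])


def _check_two_class(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int(np.sum(labels))
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("both classes must be present")
    return n_pos, n_neg


def roc_and_auc(values: np.ndarray, labels: np.ndarray) -> tuple[ROCCurve, float]:
    """ROC curve and trapezoidal AUC for a scalar feature.

    ``labels`` is boolean (True = wheeze). The sweep is oriented so the
    AUC is >= 0.5; the chosen direction is recorded on the curve.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _check_two_class(labels)
    raw = rank_auc(values, labels)
    direction = "greater" if raw >= 0.5 else "less"
    oriented = values if direction == "greater" else -values
    fpr, tpr, _ = _sk_roc_curve(labels, oriented, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(sensitivity=tpr, specificity=1.0 - fpr, direction=direction), auc


def rank_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Unoriented AUC as the Mann-Whitney statistic U/(n1*n2), ties 1/2."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = _check_two_class(labels)
    ranks = stats.rankdata(values)
    u = float(np.sum(ranks[labels])) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def optimum_roc_point(curve: ROCCurve) -> tuple[float, float, float]:
    """(SE, SP, distance) of the curve point closest to (0, 1),
    i.e. minimising sqrt((1-SE)^2 + (1-SP)^2)."""
    se, sp = curve.sensitivity, curve.specificity
    if se.size == 0:
        raise ParameterError("empty ROC curve")
    dist = np.hypot(1.0 - se, 1.0 - sp)
    i = int(np.argmin(dist))
    return float(se[i]), float(sp[i]), float(dist[i])


@dataclass(frozen=True)
class RanksumResult:
    ranksum: float  # rank sum of the wheeze group
    p_value: float
    effect_size: float  # P(wheeze > normal) + 0.5 P(tie)


def ranksum_effect(wheeze_values: np.ndarray, normal_values: np.ndarray) -> RanksumResult:
    """Wilcoxon rank-sum test with common-language effect size.

    Exact p-value by enumeration for small samples without ties,
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    w = np.asarray(wheeze_values, dtype=float)
    n = np.asarray(normal_values, dtype=float)
    if w.size == 0 or n.size == 0:
        raise ParameterError("both groups must be non-empty")
    pooled = np.concatenate([w, n])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(w, n, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    effect = u1 / (w.size * n.size)
    ranksum = u1 + w.size * (w.size + 1) / 2.0
    return RanksumResult(ranksum=ranksum, p_value=float(res.pvalue), effect_size=effect)


@dataclass(frozen=True)
class BoxStats:
    """Tukey box-plot summary of one group."""

    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float


def box_stats(values: np.ndarray) -> BoxStats:
    """Quartiles by linear interpolation; whiskers at the furthest data
    point within 1.5 IQR of the quartiles."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ParameterError("box statistics need at least 4 values")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo = float(v[v >= q1 - 1.5 * iqr].min())
    hi = float(v[v <= q3 + 1.5 * iqr].max())
    return BoxStats(median=float(med), q1=float(q1), q3=float(q3),
                    whisker_lo=lo, whisker_hi=hi)


def dbm_ovs(wheeze_values: np.ndarray, normal_values: np.ndarray) -> float:
    """Distance between group medians over the overall visible spread
    (span of the box-plot whiskers across both groups)."""
    bw = box_stats(wheeze_values)
    bn = box_stats(normal_values)
    dbm = abs(bw.median - bn.median)
    ovs = max(bw.whisker_hi, bn.whisker_hi) - min(bw.whisker_lo, bn.whisker_lo)
    if ovs == 0:
        raise DegenerateInputError("overall visible spread is zero")
    return dbm / ovs
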