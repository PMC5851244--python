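"""ROC analysis and paired diagnostic-test comparison for ordinal scores.

Severity scores take a handful of integer values, so ties dominate and the
empirical AUROC must be the tie-corrected Mann-Whitney concordance

    AUC = P(S_pos > S_neg) + 0.5 * P(S_pos = S_neg)

estimated over all (non-survivor, survivor) pairs. Standard errors and the
paired two-score comparison use DeLong's structural-components (placement
value) estimator; ties receive 0.5 weight consistently. Sensitivity and
specificity are evaluated with the positive-call convention score >= cutoff,
and their paired comparison uses McNemar marginal-homogeneity tests within
each outcome class plus a joint weighted-least-squares statistic.

Grouped score-by-outcome count tables (the form in which published cohorts
usually arrive) are first-class inputs: every estimator has a grouped
entry point that agrees exactly with the expanded per-record computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.proportion import proportion_confint

from .errors import DegenerateInputError, PairingError

__all__ = [
    "GroupedScoreTable",
    "RocCurve",
    "AurocEstimate",
    "DiagnosticPerformance",
    "PairedComparison",
    "PairedSensSpecResult",
    "CiMethod",
    "AucCiMethod",
    "ComparisonMethod",
    "auroc_mann_whitney",
    "auroc_with_ci",
    "roc_from_grouped",
    "auroc_from_grouped",
    "delong_variance",
    "paired_delong_test",
    "sens_spec_at_cutoff",
    "sens_spec_from_grouped",
    "binomial_ci",
    "paired_sens_spec_test",
    "roc_curve",
]


class CiMethod(Enum):
    """Binomial proportion CI estimators."""

    WALD = "WALD"
    WILSON = "WILSON"
    EXACT = "EXACT"  # Clopper-Pearson


class AucCiMethod(Enum):
    DELONG = "DELONG"
    DELONG_LOGIT = "DELONG_LOGIT"
    BOOTSTRAP = "BOOTSTRAP"


class ComparisonMethod(Enum):
    DELONG_PAIRED = "DELONG_PAIRED"
    MCNEMAR = "MCNEMAR"
    WLS_JOINT = "WLS_JOINT"


@dataclass(frozen=True)
class GroupedScoreTable:
    """Counts of patients per score level, split by outcome class.

    ``counts_pos`` are non-survivors (the event class), ``counts_neg``
    survivors. Levels must be strictly increasing and each class must have
    at least one patient.
    """

    levels: tuple[float, ...]
    counts_pos: tuple[int, ...]
    counts_neg: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.levels) == len(self.counts_pos) == len(self.counts_neg)):
            raise ValueError("levels and both count vectors must have equal length")
        if any(np.diff(self.levels) <= 0):
            raise ValueError("levels must be strictly increasing")
        if any(c < 0 for c in self.counts_pos) or any(c < 0 for c in self.counts_neg):
            raise ValueError("counts must be non-negative")
        if sum(self.counts_pos) == 0 or sum(self.counts_neg) == 0:
            raise DegenerateInputError("each outcome class needs at least one patient")

    @property
    def n_pos(self) -> int:
        return int(sum(self.counts_pos))

    @property
    def n_neg(self) -> int:
        return int(sum(self.counts_neg))

    @property
    def n(self) -> int:
        return self.n_pos + self.n_neg


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve: (threshold, TPR, FPR) per distinct score value
    plus the (-inf -> 1,1) and (+inf -> 0,0) endpoints; positive call is
    score >= threshold, so both rates fall as the threshold rises."""

    points: tuple[tuple[float, float, float], ...]

    def area(self) -> float:
        """Trapezoidal area under the curve; equals the Mann-Whitney AUC."""
        # points are stored with ascending threshold, i.e. descending FPR;
        # reversing keeps tied-FPR points correctly paired with their TPR
        fpr = np.array([p[2] for p in self.points])[::-1]
        tpr = np.array([p[1] for p in self.points])[::-1]
        return float(np.trapezoid(tpr, fpr))


@dataclass(frozen=True)
class AurocEstimate:
    auc: float
    se: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    method: Optional[AucCiMethod] = None

    def __post_init__(self) -> None:
        assert 0.0 <= self.auc <= 1.0
        if self.ci_low is not None and self.ci_high is not None:
            assert self.ci_low <= self.auc + 1e-12 and self.auc - 1e-12 <= self.ci_high


@dataclass(frozen=True)
class DiagnosticPerformance:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    ci_method: CiMethod


@dataclass(frozen=True)
class PairedComparison:
    """Result of a paired two-test comparison: ``delta`` is statistic_a −
    statistic_b, antisymmetric under swapping the tests."""

    delta: float
    statistic: float
    p: float
    method: ComparisonMethod
    note: str = ""

    def __post_init__(self) -> None:
        assert 0.0 <= self.p <= 1.0 or math.isnan(self.p)


@dataclass(frozen=True)
class PairedSensSpecResult:
    sensitivity: PairedComparison
    specificity: PairedComparison
    joint: PairedComparison


def _as_arrays(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype == bool:
        y = y.astype(int)
    y = y.astype(int)
    if s.shape != y.shape or s.ndim != 1:
        raise PairingError("scores and labels must be 1-D and equal length")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise DegenerateInputError("need both outcome classes present")
    return s, y


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values, in original record order within each class.

    V10[i] = fraction of negatives strictly below positive i plus half the
    ties; V01[j] = fraction of positives strictly above negative j plus
    half the ties. Both means equal the Mann-Whitney AUC.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    neg_sorted = np.sort(neg)
    pos_sorted = np.sort(pos)
    below = np.searchsorted(neg_sorted, pos, side="left")
    below_eq = np.searchsorted(neg_sorted, pos, side="right")
    v10 = (below + 0.5 * (below_eq - below)) / n
    above = m - np.searchsorted(pos_sorted, neg, side="right")
    above_eq = m - np.searchsorted(pos_sorted, neg, side="left")
    v01 = (above + 0.5 * (above_eq - above)) / m
    return v10, v01


def auroc_mann_whitney(scores: Sequence[float], labels: Sequence[int]) -> AurocEstimate:
    """Tie-corrected Mann-Whitney AUROC point estimate.

    AUC = (# concordant (pos, neg) pairs + 0.5 * # tied pairs) / (n_pos * n_neg).
    Positive label = 1 = the event (non-survivor) class.
    """
    s, y = _as_arrays(scores, labels)
    pos = s[y == 1]
    neg_sorted = np.sort(s[y == 0])
    # exact integer pair counts keep this bit-identical to the grouped form
    below = np.searchsorted(neg_sorted, pos, side="left")
    below_eq = np.searchsorted(neg_sorted, pos, side="right")
    concordant = float(below.sum())
    ties = float((below_eq - below).sum())
    auc = (concordant + 0.5 * ties) / (len(pos) * len(neg_sorted))
    return AurocEstimate(auc=float(auc))


def _grouped_auc(counts_pos: np.ndarray, counts_neg: np.ndarray) -> float:
    cp = counts_pos.astype(float)
    cn = counts_neg.astype(float)
    cum_neg_below = np.concatenate(([0.0], np.cumsum(cn)))[:-1]
    concordant = float(np.dot(cp, cum_neg_below))
    ties = float(np.dot(cp, cn))
    return (concordant + 0.5 * ties) / (cp.sum() * cn.sum())


def auroc_from_grouped(table: GroupedScoreTable) -> AurocEstimate:
    """AUROC from a grouped score-by-outcome table.

    Identical to :func:`auroc_mann_whitney` on the expanded per-record
    representation, computed in closed form on the counts.
    """
    auc = _grouped_auc(np.array(table.counts_pos), np.array(table.counts_neg))
    return AurocEstimate(auc=auc)


def delong_variance(scores: Sequence[float], labels: Sequence[int]) -> float:
    """DeLong standard error of the Mann-Whitney AUC.

    var = S10/m + S01/n where S10, S01 are the sample variances (ddof=1) of
    the positive- and negative-class placement values. Requires >= 2 records
    in each class.
    """
    s, y = _as_arrays(scores, labels)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise DegenerateInputError("DeLong variance needs >= 2 records per class")
    v10, v01 = _placements(s, y)
    var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
    return float(np.sqrt(max(var, 0.0)))


def auroc_with_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    level: float = 0.95,
    method: AucCiMethod = AucCiMethod.DELONG,
) -> AurocEstimate:
    """AUROC with a DeLong Wald CI, optionally on the logit scale.

    The logit variant keeps the interval inside (0, 1) and is the better
    default near the boundaries; plain DeLong intervals are clipped.
    """
    s, y = _as_arrays(scores, labels)
    v10, v01 = _placements(s, y)
    auc = float(v10.mean())
    se = float(np.sqrt(max(v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01), 0.0)))
    z = stats.norm.ppf(0.5 + level / 2)
    if method is AucCiMethod.DELONG_LOGIT and 0 < auc < 1 and se > 0:
        logit = math.log(auc / (1 - auc))
        se_logit = se / (auc * (1 - auc))
        lo = 1 / (1 + math.exp(-(logit - z * se_logit)))
        hi = 1 / (1 + math.exp(-(logit + z * se_logit)))
    else:
        lo = max(0.0, auc - z * se)
        hi = min(1.0, auc + z * se)
    return AurocEstimate(auc=auc, se=se, ci_low=lo, ci_high=hi, method=method)


def paired_delong_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
) -> PairedComparison:
    """Two-sided DeLong test of AUC_a = AUC_b for two scores on the same
    patients.

    Uses the paired covariance of the placement values; delta = AUC_a −
    AUC_b. Identical score vectors give delta 0 and p = 1.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape:
        raise PairingError("score vectors must be defined on the same records")
    sa, y = _as_arrays(sa, labels)
    sb, _ = _as_arrays(sb, labels)

    va10, va01 = _placements(sa, y)
    vb10, vb01 = _placements(sb, y)
    auc_a = float(va10.mean())
    auc_b = float(vb10.mean())
    m, n = len(va10), len(va01)

    s10 = np.cov(np.vstack([va10, vb10]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = auc_a - auc_b

    if var_diff <= 1e-16:
        p = 1.0 if abs(delta) < 1e-12 else 0.0
        return PairedComparison(delta=delta, statistic=0.0 if p == 1.0 else math.inf,
                                p=p, method=ComparisonMethod.DELONG_PAIRED,
                                note="zero variance of the AUC difference")
    z = delta / math.sqrt(var_diff)
    p = float(2 * stats.norm.sf(abs(z)))
    return PairedComparison(delta=delta, statistic=float(z), p=min(p, 1.0),
                            method=ComparisonMethod.DELONG_PAIRED)


def binomial_ci(
    successes: int,
    trials: int,
    level: float = 0.95,
    method: CiMethod = CiMethod.WALD,
) -> tuple[float, float]:
    """Binomial proportion CI (Wald, Wilson, or exact Clopper-Pearson),
    clipped to [0, 1]."""
    if not (0 <= successes <= trials) or trials <= 0:
        raise ValueError(f"invalid counts: {successes}/{trials}")
    alpha = 1 - level
    sm_method = {CiMethod.WALD: "normal", CiMethod.WILSON: "wilson",
                 CiMethod.EXACT: "beta"}[method]
    lo, hi = proportion_confint(successes, trials, alpha=alpha, method=sm_method)
    return (float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1)))


def sens_spec_at_cutoff(
    scores: Sequence[float],
    labels: Sequence[int],
    cutoff: float,
    level: float = 0.95,
    ci_method: CiMethod = CiMethod.WALD,
) -> DiagnosticPerformance:
    """Sensitivity/specificity with positive call = score >= cutoff.

    Sensitivity = TP/(TP+FN) among the event class; specificity =
    TN/(TN+FP) among survivors; binomial CIs by the chosen method.
    """
    s, y = _as_arrays(scores, labels)
    calls = s >= cutoff
    tp = int(np.sum(calls & (y == 1)))
    fn = int(np.sum(~calls & (y == 1)))
    tn = int(np.sum(~calls & (y == 0)))
    fp = int(np.sum(calls & (y == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return DiagnosticPerformance(
        tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sens, specificity=spec,
        sens_ci=binomial_ci(tp, tp + fn, level, ci_method),
        spec_ci=binomial_ci(tn, tn + fp, level, ci_method),
        ci_method=ci_method,
    )


def sens_spec_from_grouped(
    table: GroupedScoreTable,
    cutoff: float,
    level: float = 0.95,
    ci_method: CiMethod = CiMethod.WALD,
) -> DiagnosticPerformance:
    """Grouped-table counterpart of :func:`sens_spec_at_cutoff`."""
    lv = np.array(table.levels)
    cp = np.array(table.counts_pos)
    cn = np.array(table.counts_neg)
    pos_call = lv >= cutoff
    tp = int(cp[pos_call].sum())
    fn = int(cp[~pos_call].sum())
    fp = int(cn[pos_call].sum())
    tn = int(cn[~pos_call].sum())
    return DiagnosticPerformance(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=tp / (tp + fn), specificity=tn / (tn + fp),
        sens_ci=binomial_ci(tp, tp + fn, level, ci_method),
        spec_ci=binomial_ci(tn, tn + fp, level, ci_method),
        ci_method=ci_method,
    )


def _mcnemar_comparison(calls_a: np.ndarray, calls_b: np.ndarray) -> PairedComparison:
    """Exact-binomial McNemar when discordant pairs < 25, else chi-square
    with continuity correction. ``calls_*`` are already oriented so that
    their means are the statistic being compared (positive calls among the
    diseased for sensitivity, negative calls among the non-diseased for
    specificity); delta = mean_a − mean_b."""
    b = int(np.sum(calls_a & ~calls_b))  # a hit, b miss
    c = int(np.sum(~calls_a & calls_b))
    n = len(calls_a)
    delta = float(np.sum(calls_a) - np.sum(calls_b)) / n if n else 0.0
    discordant = b + c
    if discordant == 0:
        return PairedComparison(delta=float(delta), statistic=0.0, p=1.0,
                                method=ComparisonMethod.MCNEMAR,
                                note="no discordant pairs")
    exact = discordant < 25
    table = np.array([[0, b], [c, 0]])
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return PairedComparison(delta=float(delta), statistic=float(res.statistic),
                            p=float(min(res.pvalue, 1.0)),
                            method=ComparisonMethod.MCNEMAR)


def paired_sens_spec_test(
    calls_a: Sequence[bool],
    calls_b: Sequence[bool],
    labels: Sequence[int],
) -> PairedSensSpecResult:
    """Paired comparison of two binary tests on the same patients.

    McNemar marginal-homogeneity tests within the diseased subset
    (sensitivities) and the non-diseased subset (specificities), plus a
    joint weighted-least-squares chi-square (2 df) combining both
    contrasts. The two strata are disjoint patients, so their contrast
    variances are independent and the joint statistic is the sum of the
    squared standardised contrasts.
    """
    a = np.asarray(calls_a, dtype=bool)
    b = np.asarray(calls_b, dtype=bool)
    y = np.asarray(labels).astype(int)
    if not (a.shape == b.shape == y.shape):
        raise PairingError("calls and labels must be aligned")
    if y.sum() == 0 or y.sum() == len(y):
        raise DegenerateInputError("need both outcome classes present")

    sens_cmp = _mcnemar_comparison(a[y == 1], b[y == 1])
    spec_cmp = _mcnemar_comparison(~a[y == 0], ~b[y == 0])

    chi2 = 0.0
    df = 0
    note_parts = []
    for subset_calls_a, subset_calls_b, name in (
        (a[y == 1], b[y == 1], "sensitivity"),
        (~a[y == 0], ~b[y == 0], "specificity"),
    ):
        d = int(np.sum(subset_calls_a & ~subset_calls_b))
        e = int(np.sum(~subset_calls_a & subset_calls_b))
        n_sub = len(subset_calls_a)
        if d + e > 0:
            # Wald variance of the paired proportion difference (b+c)/n^2
            chi2 += (d - e) ** 2 / (d + e)
            df += 1
        else:
            note_parts.append(f"no discordant pairs for {name}")
    if df == 0:
        joint = PairedComparison(delta=0.0, statistic=0.0, p=1.0,
                                 method=ComparisonMethod.WLS_JOINT,
                                 note="; ".join(note_parts) or "no discordant pairs")
    else:
        p_joint = float(stats.chi2.sf(chi2, df))
        joint = PairedComparison(
            delta=float(sens_cmp.delta + spec_cmp.delta),
            statistic=float(chi2), p=min(p_joint, 1.0),
            method=ComparisonMethod.WLS_JOINT, note="; ".join(note_parts))
    return PairedSensSpecResult(sensitivity=sens_cmp, specificity=spec_cmp, joint=joint)


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """Empirical ROC curve with one operating point per distinct score.

    The positive call is score >= threshold; the returned curve includes
    the (+inf -> 0,0) and (-inf -> 1,1) endpoints and its trapezoidal area
    equals the Mann-Whitney AUC (ties trace the diagonal segment).
    """
    s, y = _as_arrays(scores, labels)
    m = (y == 1).sum()
    n = (y == 0).sum()
    thresholds = np.unique(s)  # ascending
    points: list[tuple[float, float, float]] = [(math.inf, 0.0, 0.0)]
    for t in thresholds[::-1]:
        tpr = float(np.sum((s >= t) & (y == 1)) / m)
        fpr = float(np.sum((s >= t) & (y == 0)) / n)
        points.append((float(t), tpr, fpr))
    points.append((-math.inf, 1.0, 1.0))
    points.reverse()  # ascending threshold: (1,1) ... (0,0)
    return RocCurve(points=tuple(points))


def roc_from_grouped(table: GroupedScoreTable) -> RocCurve:
    """Grouped-table counterpart of :func:`roc_curve`."""
    lv = np.array(table.levels, dtype=float)
    cp = np.array(table.counts_pos, dtype=float)
    cn = np.array(table.counts_neg, dtype=float)
    m, n = cp.sum(), cn.sum()
    points: list[tuple[float, float, float]] = [(-math.inf, 1.0, 1.0)]
    # threshold at each level: calls = level >= t
    for i, t in enumerate(lv):
        tpr = float(cp[i:].sum() / m)
        fpr = float(cn[i:].sum() / n)
        points.append((float(t), tpr, fpr))
    points.append((math.inf, 0.0, 0.0))
    return RocCurve(points=tuple(points))
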