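"""Binary-classifier evaluation: ROC/AUC, Matthews correlation, ANOVA.

Labels are 0/1 (negative/positive); a sequence is predicted positive when
its score is >= the threshold.  AUC is the trapezoidal area under the
empirical ROC curve; the Matthews correlation coefficient follows the
standard definition with the convention that any zero factor in the
denominator yields MCC = 0 (both corners of ROC space then give 0).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn import metrics as _skm


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def P(self) -> int:
        return self.TP + self.FN

    @property
    def N(self) -> int:
        return self.TN + self.FP


@dataclasses.dataclass(frozen=True)
class ROCResult:
    """ROC curve with summary statistics.

    ``fpr``/``tpr`` run from (0, 0) to (1, 1) as the threshold decreases
    from +inf to -inf; ``thresholds`` aligns with the curve points.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    max_mcc: float
    threshold_at_max_mcc: float


def _validate(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.size == 0:
        raise ValueError("empty input")
    if s.shape != y.shape:
        raise ValueError("scores and labels must be aligned")
    y = y.astype(int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    return s, y


def confusion_at_threshold(scores, labels, t: float) -> ConfusionCounts:
    """Counts with the 'predicted positive iff score >= t' convention."""
    s, y = _validate(scores, labels)
    pred = s >= t
    return ConfusionCounts(
        TP=int(np.sum(pred & (y == 1))),
        FN=int(np.sum(~pred & (y == 1))),
        TN=int(np.sum(~pred & (y == 0))),
        FP=int(np.sum(pred & (y == 0))),
    )


def _require_both_classes(y: np.ndarray) -> None:
    if y.min() == y.max():
        raise ValueError("need at least one positive and one negative")


def roc_curve(scores, labels) -> ROCResult:
    """Empirical ROC curve plus AUC and the threshold-maximized MCC."""
    s, y = _validate(scores, labels)
    _require_both_classes(y)
    fpr, tpr, thr = _skm.roc_curve(y, s, drop_intermediate=False)
    a = float(np.trapezoid(tpr, fpr))
    mcc_best, t_best = max_mcc(s, y)
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=a,
                     max_mcc=mcc_best, threshold_at_max_mcc=t_best)


def auc(scores, labels) -> float:
    """Trapezoidal area under the empirical ROC curve.

    Equals the rank statistic P(score_pos > score_neg) + 1/2 P(tie).
    """
    s, y = _validate(scores, labels)
    _require_both_classes(y)
    fpr, tpr, _ = _skm.roc_curve(y, s, drop_intermediate=False)
    return float(np.trapezoid(tpr, fpr))


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 whenever a denominator factor is 0."""
    tp, fn, tn, fp = counts.TP, counts.FN, counts.TN, counts.FP
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _candidate_thresholds(s: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct scores, plus +/- infinity,
    in decreasing order."""
    u = np.unique(s)  # ascending
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate(([np.inf], mids[::-1], [-np.inf]))


def max_mcc(scores, labels) -> tuple[float, float]:
    """Maximum MCC over all classification thresholds.

    Thresholds midway between consecutive distinct scores (plus the two
    infinite corners) exhaust all distinct confusion tables; ties resolve
    to the highest threshold attaining the maximum.
    """
    s, y = _validate(scores, labels)
    _require_both_classes(y)
    thresholds = _candidate_thresholds(s)
    pos = np.sort(s[y == 1])
    neg = np.sort(s[y == 0])
    P, N = pos.size, neg.size
    # counts of scores >= t via searchsorted on the sorted arrays
    tp = P - np.searchsorted(pos, thresholds, side="left")
    fp = N - np.searchsorted(neg, thresholds, side="left")
    fn = P - tp
    tn = N - fp
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    with np.errstate(invalid="ignore"):
        vals = np.where(denom > 0, (tp * tn - fp * fn) / np.sqrt(np.where(denom > 0, denom, 1.0)), 0.0)
    i = int(np.argmax(vals))  # first index = highest threshold on ties
    return float(vals[i]), float(thresholds[i])


def mcc_dilution_check(
    fpr: float, tpr: float, P: int, N_sizes: Sequence[int]
) -> list[float]:
    """MCC at fixed sensitivity/false-alarm rate for growing negative sets.

    Illustrates that MCC -> 0 as the negative-set size grows even though
    TPR and FPR are held fixed, so MCC values from differently sized
    datasets are not directly comparable.
    """
    out = []
    for N in N_sizes:
        tp, fn = tpr * P, (1 - tpr) * P
        fp, tn = fpr * N, (1 - fpr) * N
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        out.append(0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom))
    return out


def compare_auc_distributions(*groups) -> tuple[float, float, float]:
    """One-way ANOVA across groups of AUC values: (F, p, eta^2).

    eta^2 = SS_between / SS_total is the fraction of variance explained by
    the grouping.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("each group needs at least two values")
    allv = np.concatenate(gs)
    grand = allv.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_total = float(np.sum((allv - grand) ** 2))
    if ss_total == 0.0:
        return 0.0, 1.0, 0.0
    f, p = stats.f_oneway(*gs)
    return float(f), float(p), float(ss_between / ss_total)


def ks_normality(values, min_n: int = 8) -> float:
    """Kolmogorov-Smirnov p-value against a normal with estimated moments.

    Parameters are the sample mean and (ddof=1) standard deviation, so the
    p-value is anti-conservative in the Lilliefors sense; it is used here
    only as a flag for choosing mean vs median summaries.
    """
    v = np.asarray(values, dtype=float)
    if v.size < min_n:
        raise ValueError(f"need at least {min_n} values, got {v.size}")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("constant input; normality test undefined")
    return float(stats.kstest(v, "norm", args=(v.mean(), sd)).pvalue)
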