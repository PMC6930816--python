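"""Validation battery: ROC/AUC with DeLong inference, Youden cutoff,
confusion metrics, paired McNemar tests, paired predictive-value Wald
comparison, and the logistic score-to-probability map.

Significance conventions: 0.05 for a single comparison, 0.0167 when the
same performance metric is tested across multiple score pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

ALPHA_SINGLE = 0.05
ALPHA_MULTIPLE = 0.0167

__all__ = [
    "ALPHA_SINGLE",
    "ALPHA_MULTIPLE",
    "OutcomeRecord",
    "RocResult",
    "CutoffMetrics",
    "PredictiveValueComparison",
    "DiagnosticComparison",
    "ProbabilityCurve",
    "roc",
    "auc_ci_and_compare",
    "youden_cutoff",
    "cutoff_metrics",
    "mcnemar",
    "compare_predictive_values",
    "fit_outcome_probability",
    "compare_scores",
]


# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class OutcomeRecord:
    """3-month functional outcome; mRS >= 3 (dependence or death) is
    unfavorable."""

    patient_id: str
    mrs_3month: int

    def __post_init__(self):
        if not 0 <= self.mrs_3month <= 6:
            raise ValueError(f"mRS must be in [0, 6], got {self.mrs_3month}")

    @property
    def unfavorable(self) -> bool:
        return self.mrs_3month >= 3

    @property
    def died(self) -> bool:
        return self.mrs_3month == 6


@dataclass(frozen=True)
class RocResult:
    name: str
    auc: float
    ci95: tuple[float, float]
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_pos: int
    n_neg: int
    window: Optional[int] = None

    @property
    def curve(self):
        return list(zip(self.fpr.tolist(), self.tpr.tolist(), self.thresholds.tolist()))


@dataclass(frozen=True)
class CutoffMetrics:
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    cc: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass(frozen=True)
class PredictiveValueComparison:
    rppv: float
    stat_ppv: float
    p_ppv: float
    rnpv: float
    stat_npv: float
    p_npv: float


@dataclass(frozen=True)
class DiagnosticComparison:
    name_a: str
    name_b: str
    auc_a: float
    auc_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    p_auc: float
    cutoff_a: float
    cutoff_b: float
    p_sensitivity: float
    p_specificity: float
    p_cc: float
    p_ppv: float
    p_npv: float
    alpha_single: float = ALPHA_SINGLE
    alpha_multiple: float = ALPHA_MULTIPLE


@dataclass(frozen=True)
class ProbabilityCurve:
    intercept: float
    slope: float
    grid: np.ndarray
    probability: np.ndarray
    penalized: bool = False

    def predict(self, score) -> np.ndarray:
        s = np.asarray(score, dtype=float)
        return 1.0 / (1.0 + np.exp(-(self.intercept + self.slope * s)))


# --------------------------------------------------------------------------
# helpers


def _as_arrays(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D vectors")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if y.all() or not y.any():
        raise ValueError("labels must contain at least one positive and one negative")
    return s, y


def _auc_midrank(scores: np.ndarray, labels: np.ndarray) -> float:
    # rank-sum (Mann-Whitney) form; equals the trapezoid AUC with
    # tied scores handled by mid-ranks
    r = stats.rankdata(scores)
    m = int(labels.sum())
    n = labels.size - m
    return (r[labels].sum() - m * (m + 1) / 2.0) / (m * n)


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    r_all = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v_pos = (r_all[:m] - r_pos) / n          # structural components per positive
    v_neg = 1.0 - (r_all[m:] - r_neg) / m    # per negative
    return auc, v_pos, v_neg


def _delong_var(v_pos_a, v_neg_a, v_pos_b=None, v_neg_b=None) -> float:
    if v_pos_b is None:
        v_pos_b, v_neg_b = v_pos_a, v_neg_a
    m, n = v_pos_a.size, v_neg_a.size
    cov_pos = np.cov(v_pos_a, v_pos_b)[0, 1] if m > 1 else 0.0
    cov_neg = np.cov(v_neg_a, v_neg_b)[0, 1] if n > 1 else 0.0
    return cov_pos / m + cov_neg / n


# --------------------------------------------------------------------------
# operations


def roc(scores, labels, name: str = "", window: Optional[int] = None) -> RocResult:
    """Empirical ROC curve and mid-rank AUC with a DeLong 95% CI."""
    s, y = _as_arrays(scores, labels)
    fpr, tpr, thr = _sk_roc_curve(y.astype(int), s, drop_intermediate=False)
    auc, v_pos, v_neg = _delong_components(s, y)
    var = _delong_var(v_pos, v_neg)
    half = stats.norm.ppf(0.975) * math.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return RocResult(
        name=name,
        auc=float(auc),
        ci95=ci,
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        n_pos=int(y.sum()),
        n_neg=int((~y).sum()),
        window=window,
    )


def auc_ci_and_compare(scores_a, scores_b, labels, name_a: str = "A", name_b: str = "B"):
    """Paired AUC comparison on the same patients (DeLong).

    Returns ``(ci_a, ci_b, p)`` where the CIs are 95% normal-approximation
    intervals and ``p`` is the two-sided p-value for a zero AUC
    difference.
    """
    a, y = _as_arrays(scores_a, labels)
    b, y2 = _as_arrays(scores_b, labels)
    if not np.array_equal(y, y2):  # pragma: no cover - same labels object
        raise ValueError("labels mismatch")
    auc_a, vpa, vna = _delong_components(a, y)
    auc_b, vpb, vnb = _delong_components(b, y)
    var_a = _delong_var(vpa, vna)
    var_b = _delong_var(vpb, vnb)
    if var_a <= 0 and np.ptp(a) == 0:
        raise ValueError(f"{name_a}: constant scores, AUC variance degenerate")
    if var_b <= 0 and np.ptp(b) == 0:
        raise ValueError(f"{name_b}: constant scores, AUC variance degenerate")
    cov = _delong_var(vpa, vna, vpb, vnb)
    z975 = stats.norm.ppf(0.975)
    ci_a = (max(0.0, auc_a - z975 * math.sqrt(max(var_a, 0))), min(1.0, auc_a + z975 * math.sqrt(max(var_a, 0))))
    ci_b = (max(0.0, auc_b - z975 * math.sqrt(max(var_b, 0))), min(1.0, auc_b + z975 * math.sqrt(max(var_b, 0))))
    var_diff = var_a + var_b - 2.0 * cov
    delta = auc_a - auc_b
    if var_diff <= 0:
        p = 1.0 if abs(delta) < 1e-12 else 0.0
    else:
        z = delta / math.sqrt(var_diff)
        p = 2.0 * stats.norm.sf(abs(z))
    return ci_a, ci_b, float(p)


def youden_cutoff(roc_result: RocResult) -> CutoffMetrics:
    """Operating point maximizing sensitivity + specificity - 1.

    The classification rule is ``score >= cutoff`` predicts unfavorable;
    ties are broken toward the smallest cutoff.
    """
    tpr, fpr, thr = roc_result.tpr, roc_result.fpr, roc_result.thresholds
    j = tpr - fpr
    best = np.flatnonzero(j >= j.max() - 1e-12)
    idx = best[np.argmin(thr[best])]
    return _metrics_from_rates(
        float(thr[idx]), float(tpr[idx]), float(fpr[idx]), roc_result.n_pos, roc_result.n_neg
    )


def _metrics_from_rates(cutoff, tpr, fpr, n_pos, n_neg) -> CutoffMetrics:
    tp = int(round(tpr * n_pos))
    fn = n_pos - tp
    fp = int(round(fpr * n_neg))
    tn = n_neg - fp
    return _metrics_from_counts(cutoff, tp, fp, tn, fn)


def _metrics_from_counts(cutoff, tp, fp, tn, fn) -> CutoffMetrics:
    def _ratio(num, den):
        return num / den if den else float("nan")

    return CutoffMetrics(
        cutoff=cutoff,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        cc=(tp + tn) / (tp + fp + tn + fn),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def cutoff_metrics(scores, labels, cutoff: float) -> CutoffMetrics:
    """Confusion metrics for the rule ``score >= cutoff``."""
    s, y = _as_arrays(scores, labels)
    pred = s >= cutoff
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))
    return _metrics_from_counts(float(cutoff), tp, fp, tn, fn)


def mcnemar(a_correct, b_correct) -> tuple[float, float]:
    """Paired McNemar test on two classifiers' correctness indicators.

    Returns the continuity-corrected chi-square statistic and a two-sided
    p-value: chi-square when the discordant count is >= 25, exact
    binomial otherwise. Zero discordant pairs give p = 1 by convention.
    """
    a = np.asarray(a_correct, dtype=bool)
    c_ = np.asarray(b_correct, dtype=bool)
    if a.shape != c_.shape or a.ndim != 1:
        raise ValueError("paired vectors must be equal-length 1-D")
    b = int(np.sum(a & ~c_))
    c = int(np.sum(~a & c_))
    nd = b + c
    if nd == 0:
        return 0.0, 1.0
    statistic = (abs(b - c) - 1) ** 2 / nd
    if nd >= 25:
        p = float(stats.chi2.sf(statistic, df=1))
    else:
        p = float(stats.binomtest(b, nd, 0.5).pvalue)
    return float(statistic), min(1.0, p)


def compare_predictive_values(pred_a, pred_b, labels) -> PredictiveValueComparison:
    """Wald tests on the log relative PPV and NPV of two paired binary
    predictions, with variances from the paired multinomial cell counts.
    """
    a = np.asarray(pred_a, dtype=bool)
    b = np.asarray(pred_b, dtype=bool)
    s, y = np.asarray(labels, dtype=bool), None
    if a.shape != b.shape or a.shape != s.shape or a.ndim != 1:
        raise ValueError("paired vectors must be equal-length 1-D")
    y = s
    n = a.size

    # 8 multinomial cells indexed (disease, pred_a, pred_b)
    counts = np.zeros((2, 2, 2), dtype=float)
    for d in (0, 1):
        for pa in (0, 1):
            for pb in (0, 1):
                counts[d, pa, pb] = np.sum((y == bool(d)) & (a == bool(pa)) & (b == bool(pb)))
    p_hat = counts / n

    def _wald(d_target: int, pred_target: int):
        # PPV: among pred==1 how often d==1; NPV: among pred==0, d==0
        s1 = np.zeros((2, 2, 2)); s1[d_target, pred_target, :] = 1          # d & A
        s2 = np.zeros((2, 2, 2)); s2[:, pred_target, :] = 1                 # A
        s3 = np.zeros((2, 2, 2)); s3[d_target, :, pred_target] = 1          # d & B
        s4 = np.zeros((2, 2, 2)); s4[:, :, pred_target] = 1                 # B
        label = "PPV" if pred_target == 1 else "NPV"
        sums = [float((m * p_hat).sum()) for m in (s1, s2, s3, s4)]
        if sums[1] == 0 or sums[3] == 0:
            raise ValueError(f"{label} undefined: a score predicts no "
                             f"{'positives' if pred_target else 'negatives'}")
        if sums[0] == 0 or sums[2] == 0:
            raise ValueError(f"{label} is zero for one score; log-relative {label} undefined")
        theta = math.log(sums[0]) - math.log(sums[1]) - math.log(sums[2]) + math.log(sums[3])
        g = s1 / sums[0] - s2 / sums[1] - s3 / sums[2] + s4 / sums[3]
        var = float((p_hat * g**2).sum()) / n
        if var <= 0:
            return math.exp(theta), 0.0, 1.0 if abs(theta) < 1e-12 else 0.0
        z = theta / math.sqrt(var)
        return math.exp(theta), float(z), float(2.0 * stats.norm.sf(abs(z)))

    rppv, z_ppv, p_ppv = _wald(1, 1)
    rnpv, z_npv, p_npv = _wald(0, 0)
    return PredictiveValueComparison(
        rppv=rppv, stat_ppv=z_ppv, p_ppv=p_ppv, rnpv=rnpv, stat_npv=z_npv, p_npv=p_npv
    )


def fit_outcome_probability(scores, labels, grid=None) -> ProbabilityCurve:
    """Univariate logistic map from score to P(unfavorable).

    Falls back to an L2-penalized fit when the maximum-likelihood fit is
    degenerate (complete separation), flagged via ``penalized``.
    """
    import statsmodels.api as sm

    s, y = _as_arrays(scores, labels)
    if grid is None:
        grid = np.arange(0, 45)
    grid = np.asarray(grid, dtype=float)
    X = sm.add_constant(s)
    intercept = slope = None
    penalized = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y.astype(float), X).fit(disp=0, maxiter=200)
        if np.all(np.isfinite(res.params)) and np.max(np.abs(res.params)) < 50:
            intercept, slope = float(res.params[0]), float(res.params[1])
    except Exception:
        pass
    if intercept is None:
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
        lr.fit(s.reshape(-1, 1), y.astype(int))
        intercept, slope = float(lr.intercept_[0]), float(lr.coef_[0][0])
        penalized = True
    prob = 1.0 / (1.0 + np.exp(-(intercept + slope * grid)))
    return ProbabilityCurve(
        intercept=intercept, slope=slope, grid=grid, probability=prob, penalized=penalized
    )


def compare_scores(
    scores_a, scores_b, labels, name_a: str = "A", name_b: str = "B", window: Optional[int] = None
) -> DiagnosticComparison:
    """Full paired battery for two scores on the same patients: DeLong
    AUC test plus McNemar (sensitivity, specificity, CC) and Wald
    (PPV, NPV) tests at each score's own Youden cutoff."""
    a, y = _as_arrays(scores_a, labels)
    b, _ = _as_arrays(scores_b, labels)
    roc_a = roc(a, y, name=name_a, window=window)
    roc_b = roc(b, y, name=name_b, window=window)
    ci_a, ci_b, p_auc = auc_ci_and_compare(a, b, y, name_a, name_b)
    cut_a = youden_cutoff(roc_a)
    cut_b = youden_cutoff(roc_b)
    pred_a = a >= cut_a.cutoff
    pred_b = b >= cut_b.cutoff
    correct_a = pred_a == y
    correct_b = pred_b == y
    _, p_sens = mcnemar(correct_a[y], correct_b[y])
    _, p_spec = mcnemar(correct_a[~y], correct_b[~y])
    _, p_cc = mcnemar(correct_a, correct_b)
    pv = compare_predictive_values(pred_a, pred_b, y)
    return DiagnosticComparison(
        name_a=name_a,
        name_b=name_b,
        auc_a=roc_a.auc,
        auc_b=roc_b.auc,
        ci_a=ci_a,
        ci_b=ci_b,
        p_auc=p_auc,
        cutoff_a=cut_a.cutoff,
        cutoff_b=cut_b.cutoff,
        p_sensitivity=p_sens,
        p_specificity=p_spec,
        p_cc=p_cc,
        p_ppv=pv.p_ppv,
        p_npv=pv.p_npv,
    )
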