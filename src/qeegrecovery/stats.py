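"""Outcome statistics for the prognostication analysis.

Mirrors the classical battery used for small two-arm animal studies:
a normality-gated two-group comparison (Lilliefors-corrected Kolmogorov-
Smirnov gate, Student's t when both arms look normal with homogeneous
variances, two-sided rank-sum otherwise), Spearman correlation with a
Fisher-z confidence interval, ROC/AUC for 96-h survival with a stratified
bootstrap interval, and Kaplan-Meier survival curves with a log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupCompareResult",
    "CorrResult",
    "ROCResult",
    "KMResult",
    "compare_groups",
    "spearman_ci",
    "roc_auc_ci",
    "km_logrank",
]


@dataclass
class GroupCompareResult:
    test_used: str              # "t" | "rank-sum"
    statistic: float
    p_value: float
    summary_a: str
    summary_b: str
    normal_a: bool
    normal_b: bool
    equal_var: bool


@dataclass
class CorrResult:
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    orientation: str
    p_value: float
    n_pos: int
    n_neg: int


@dataclass
class KMResult:
    survival_functions: dict            # group -> DataFrame(time, S)
    medians: dict                       # group -> float (inf if undefined)
    logrank_statistic: float
    logrank_p: float
    groups: list = field(default_factory=list)


def _summary(x: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{np.mean(x):.3g} +/- {np.std(x, ddof=1):.3g}"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.4g} [{q1:.4g}-{q3:.4g}]"


def _lilliefors_normal(x: np.ndarray, alpha: float) -> bool:
    """Kolmogorov-Smirnov normality gate with estimated parameters
    (Lilliefors correction, as statistics packages apply it)."""
    from statsmodels.stats.diagnostic import lilliefors

    if np.ptp(x) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = lilliefors(x, dist="norm")
    return bool(p > alpha)


def compare_groups(a, b, alpha: float = 0.05) -> GroupCompareResult:
    """Normality-gated two-group comparison, two-tailed.

    Student's t is used only when both groups pass the normality gate and an
    F-ratio test finds the variances homogeneous; otherwise the two-sided
    Wilcoxon rank-sum (Mann-Whitney) test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    normal_a = _lilliefors_normal(a, alpha)
    normal_b = _lilliefors_normal(b, alpha)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if min(va, vb) > 0:
        f_ratio = max(va, vb) / min(va, vb)
        dfn = (a.size if va >= vb else b.size) - 1
        dfd = (b.size if va >= vb else a.size) - 1
        p_var = 2.0 * min(sps.f.sf(f_ratio, dfn, dfd),
                          sps.f.cdf(f_ratio, dfn, dfd))
        equal_var = bool(p_var > alpha)
    else:
        equal_var = va == vb
    if normal_a and normal_b and equal_var:
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        test = "t"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        test = "rank-sum"
    return GroupCompareResult(
        test_used=test, statistic=float(stat), p_value=float(p),
        summary_a=_summary(a, normal_a), summary_b=_summary(b, normal_b),
        normal_a=normal_a, normal_b=normal_b, equal_var=equal_var)


def spearman_ci(x, y, conf_level: float = 0.95) -> CorrResult:
    """Spearman rank correlation (average ranks for ties) with a Fisher-z
    confidence interval using standard error 1/sqrt(n-3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    r, p = sps.spearmanr(x, y)
    n = x.size
    if abs(r) >= 1.0:
        return CorrResult(float(r), float(r), float(r), float(p), n)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zc = sps.norm.ppf(0.5 + conf_level / 2.0)
    return CorrResult(float(r), float(np.tanh(z - zc * se)),
                      float(np.tanh(z + zc * se)), float(p), n)


def roc_auc_ci(scores, survived, risk_direction: str = "higher_worse",
               n_bootstrap: int = 2000, seed: int = 0,
               conf_level: float = 0.95) -> ROCResult:
    """AUC for predicting 96-h death from a single feature.

    Scores are oriented so that higher values mean higher death risk
    (``higher_worse`` leaves onset times as-is; ``lower_worse`` negates,
    as appropriate for the TWA features where low values are ominous).
    The AUC equals the Mann-Whitney pair statistic with half-credit for
    ties; the confidence interval is a seeded stratified bootstrap.
    """
    scores = np.asarray(scores, dtype=float)
    survived = np.asarray(survived, dtype=bool)
    if scores.size != survived.size:
        raise ValueError("scores and labels must align")
    died = ~survived
    if died.all() or survived.all():
        raise ValueError("both outcome classes must be present")
    s = scores if risk_direction == "higher_worse" else -scores
    n_pos, n_neg = int(died.sum()), int(survived.sum())
    if min(n_pos, n_neg) < 5:
        warnings.warn(
            f"small outcome class (n={min(n_pos, n_neg)}); AUC and its "
            "bootstrap interval are unstable", stacklevel=2)

    def auc_of(sc, d):
        pos, neg = sc[d], sc[~d]
        greater = (pos[:, None] > neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        return (greater + 0.5 * ties) / (len(pos) * len(neg))

    auc = auc_of(s, died)
    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(died)
    idx_neg = np.flatnonzero(survived)
    boots = np.empty(n_bootstrap)
    for k in range(n_bootstrap):
        bp = rng.choice(idx_pos, size=n_pos, replace=True)
        bn = rng.choice(idx_neg, size=n_neg, replace=True)
        sc = np.concatenate([s[bp], s[bn]])
        d = np.zeros(n_pos + n_neg, dtype=bool)
        d[:n_pos] = True
        boots[k] = auc_of(sc, d)
    lo_q = (1 - conf_level) / 2
    ci = np.clip(np.quantile(boots, [lo_q, 1 - lo_q]), 0.0, 1.0)
    _, p = sps.mannwhitneyu(s[died], s[survived],
                            alternative="two-sided")
    return ROCResult(float(auc), float(ci[0]), float(ci[1]),
                     risk_direction, float(p), n_pos, n_neg)


def km_logrank(times_h, event_flags, groups) -> KMResult:
    """Kaplan-Meier product-limit curves per group with a two-group
    log-rank test (the test is skipped when only one group is present).

    ``event_flags`` is True for a death, False for censoring (survivors are
    censored at 96 h); the median is the first time the survival function
    drops to 0.5 or below (inf if it never does).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    times = np.asarray(times_h, dtype=float)
    events = np.asarray(event_flags, dtype=bool)
    groups = np.asarray(groups)
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    names = list(pd.unique(groups))
    surv, medians = {}, {}
    for g in names:
        mask = groups == g
        if mask.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time_h", "S"]
        surv[g] = sf
        # median = first time S(t) <= 0.5 (inf if S never reaches it)
        at_or_below = sf[sf["S"] <= 0.5 + 1e-12]
        medians[g] = (float(at_or_below["time_h"].iloc[0])
                      if len(at_or_below) else float("inf"))
    if len(names) == 2:
        m0 = groups == names[0]
        res = logrank_test(times[m0], times[~m0],
                           event_observed_A=events[m0],
                           event_observed_B=events[~m0])
        stat, p = float(res.test_statistic), float(res.p_value)
    else:
        stat, p = float("nan"), float("nan")
    return KMResult(survival_functions=surv, medians=medians,
                    logrank_statistic=stat, logrank_p=p, groups=names)
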