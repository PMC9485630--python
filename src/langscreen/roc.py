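"""ROC/AUC estimation and the paired comparisons used to validate screens.

AUC is the Mann-Whitney pair-counting estimator (ties count one half);
its variance and the paired AUC-difference test come from DeLong's
placement-value decomposition.  A stratified-bootstrap paired test and
McNemar's test for paired sensitivities/specificities complete the
toolbox, together with Welch's heteroscedastic one-way ANOVA used to
validate risk tiers against continuous reference scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AucResult",
    "GroupComparison",
    "PairedBinaryTest",
    "RocComparison",
    "auc",
    "bootstrap_paired_test",
    "delong_paired_test",
    "mcnemar_paired",
    "welch_anova",
]


@dataclass(frozen=True)
class AucResult:
    auc: float
    ci_low: float
    ci_high: float
    se: float
    ci_level: float = 0.95


@dataclass(frozen=True)
class RocComparison:
    auc1: float
    auc2: float
    delta_auc: float
    ci1: tuple[float, float]
    ci2: tuple[float, float]
    statistic: float
    p_value: float
    method: str
    n_boot: int | None = None
    seed: int | None = None


@dataclass(frozen=True)
class PairedBinaryTest:
    discordant_b: int
    discordant_c: int
    chi_square: float
    df: int
    p_value: float
    exact_p: float | None = None


@dataclass(frozen=True)
class GroupComparison:
    group_names: tuple
    means: tuple
    sds: tuple
    ns: tuple
    welch_f: float
    df1: int
    df2: float
    p_value: float
    eta_squared: float


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-D vectors")
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present")
    return s[y], s[~y]


def _placements(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values.

    ``v10[i]`` is the fraction of non-diseased scores below the i-th
    diseased score (ties half); ``v01[j]`` symmetric.  The means of both
    equal the Mann-Whitney AUC.
    """
    m, n = len(x), len(y)
    combined = np.concatenate([x, y])
    r_all = stats.rankdata(combined)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    v10 = (r_all[:m] - rx) / n
    v01 = 1.0 - (r_all[m:] - ry) / m
    return v10, v01


def auc(scores, labels, ci_level: float = 0.95) -> AucResult:
    """Mann-Whitney AUC with a DeLong normal-approximation CI."""
    x, y = _split(scores, labels)
    v10, v01 = _placements(x, y)
    a = float(v10.mean())
    var = (
        (np.var(v10, ddof=1) / len(x) if len(x) > 1 else 0.0)
        + (np.var(v01, ddof=1) / len(y) if len(y) > 1 else 0.0)
    )
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    return AucResult(
        auc=a,
        ci_low=float(np.clip(a - z * se, 0.0, 1.0)),
        ci_high=float(np.clip(a + z * se, 0.0, 1.0)),
        se=se,
        ci_level=ci_level,
    )


def delong_paired_test(scores_a, scores_b, labels, ci_level: float = 0.95) -> RocComparison:
    """DeLong's test for the AUC difference of two scores on the same children."""
    xa, ya = _split(scores_a, labels)
    xb, yb = _split(scores_b, labels)
    v10a, v01a = _placements(xa, ya)
    v10b, v01b = _placements(xb, yb)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = len(xa), len(ya)

    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_delta = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    delta = auc_a - auc_b
    if var_delta <= 0:
        z_stat, p = 0.0, 1.0
    else:
        z_stat = delta / np.sqrt(var_delta)
        p = 2.0 * stats.norm.sf(abs(z_stat))

    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    ci = []
    for a, v in ((auc_a, cov[0, 0]), (auc_b, cov[1, 1])):
        se = np.sqrt(max(v, 0.0))
        ci.append(
            (float(np.clip(a - z * se, 0.0, 1.0)), float(np.clip(a + z * se, 0.0, 1.0)))
        )
    return RocComparison(
        auc1=auc_a,
        auc2=auc_b,
        delta_auc=delta,
        ci1=ci[0],
        ci2=ci[1],
        statistic=float(z_stat),
        p_value=float(min(p, 1.0)),
        method="delong",
    )


def bootstrap_paired_test(
    scores_a, scores_b, labels, n_boot: int = 2000, seed: int | None = None
) -> RocComparison:
    """Stratified-bootstrap test for a paired AUC difference.

    Children are resampled with replacement within the diseased and
    non-diseased strata (so every replicate keeps both classes), the
    AUC difference is recomputed per replicate, and
    ``D = observed delta / SD(bootstrap deltas)`` is referred to a
    standard normal (two-sided).
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    if seed is None:
        raise ValueError("a seed is required for reproducible bootstrap inference")
    s_a = np.asarray(scores_a, dtype=float)
    s_b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(bool)
    xa, ya_ = _split(s_a, y)
    xb, yb_ = _split(s_b, y)
    res_a = auc(s_a, y)
    res_b = auc(s_b, y)
    delta = res_a.auc - res_b.auc

    rng = np.random.default_rng(seed)
    m, n = len(xa), len(ya_)
    deltas = np.empty(n_boot)
    for i in range(n_boot):
        di = rng.integers(0, m, m)
        hi = rng.integers(0, n, n)
        v10a, _ = _placements(xa[di], ya_[hi])
        v10b, _ = _placements(xb[di], yb_[hi])
        deltas[i] = v10a.mean() - v10b.mean()
    sd = float(np.std(deltas, ddof=1))
    if sd == 0.0:
        d_stat, p = 0.0, 1.0
    else:
        d_stat = delta / sd
        p = min(1.0, 2.0 * stats.norm.sf(abs(d_stat)))
    return RocComparison(
        auc1=res_a.auc,
        auc2=res_b.auc,
        delta_auc=delta,
        ci1=(res_a.ci_low, res_a.ci_high),
        ci2=(res_b.ci_low, res_b.ci_high),
        statistic=float(d_stat),
        p_value=float(p),
        method="bootstrap",
        n_boot=n_boot,
        seed=seed,
    )


def mcnemar_paired(correct_a, correct_b) -> PairedBinaryTest:
    """McNemar's test on paired binary indicators (no continuity correction).

    ``b`` counts pairs where screen A succeeds and B fails, ``c`` the
    reverse.  The exact two-sided binomial p-value is reported alongside
    the chi-square one whenever ``b + c < 25``.
    """
    a = np.asarray(correct_a).astype(bool)
    b_vec = np.asarray(correct_b).astype(bool)
    if a.shape != b_vec.shape or a.ndim != 1:
        raise ValueError("paired indicator vectors must be aligned 1-D")
    b = int(np.sum(a & ~b_vec))
    c = int(np.sum(~a & b_vec))
    if b + c == 0:
        raise ValueError("test undefined: no discordant pairs")
    chi2 = (b - c) ** 2 / (b + c)
    p = float(stats.chi2.sf(chi2, 1))
    exact = None
    if b + c < 25:
        exact = float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), b + c, 0.5)))
    return PairedBinaryTest(
        discordant_b=b,
        discordant_c=c,
        chi_square=float(chi2),
        df=1,
        p_value=p,
        exact_p=exact,
    )


def welch_anova(groups: dict | list, group_names=None) -> GroupComparison:
    """Welch's heteroscedastic one-way ANOVA with classical eta-squared.

    ``groups`` is a mapping name -> values or a list of value arrays.
    eta-squared is between-group over total sums of squares (unweighted,
    on the raw pooled data), reported alongside the Welch F which does
    the actual inference under unequal variances.
    """
    if isinstance(groups, dict):
        names = tuple(groups.keys())
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, dtype=float) for v in groups]
        names = tuple(group_names) if group_names else tuple(range(len(arrays)))
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least two groups")
    ns = np.array([len(a) for a in arrays])
    if (ns < 2).any():
        raise ValueError("every group needs at least two values")
    means = np.array([a.mean() for a in arrays])
    variances = np.array([a.var(ddof=1) for a in arrays])
    if (variances <= 0).any():
        raise ValueError("every group needs positive variance")

    w = ns / variances
    w_sum = w.sum()
    grand_w = (w * means).sum() / w_sum
    num = ((w * (means - grand_w) ** 2).sum()) / (k - 1)
    lam = ((1 - w / w_sum) ** 2 / (ns - 1)).sum()
    denom = 1.0 + 2.0 * (k - 2) / (k**2 - 1.0) * lam
    f_stat = num / denom
    df1 = k - 1
    df2 = (k**2 - 1.0) / (3.0 * lam)
    p = float(stats.f.sf(f_stat, df1, df2))

    pooled = np.concatenate(arrays)
    grand = pooled.mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_total = float(np.sum((pooled - grand) ** 2))
    eta2 = ss_between / ss_total if ss_total > 0 else 0.0
    return GroupComparison(
        group_names=names,
        means=tuple(float(m) for m in means),
        sds=tuple(float(np.sqrt(v)) for v in variances),
        ns=tuple(int(n) for n in ns),
        welch_f=float(f_stat),
        df1=df1,
        df2=float(df2),
        p_value=p,
        eta_squared=float(eta2),
    )
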