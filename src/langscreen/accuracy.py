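"""Confusion-matrix accuracy statistics, constrained cutoffs, risk tiers.

Conventions used throughout the package:

* a screen is **positive** iff ``score >= cutoff`` (higher score =
  higher risk), including exactly at the boundary;
* candidate cutoffs are the midpoints between adjacent distinct
  observed scores, plus minus/plus infinity, so results do not depend
  on arbitrary observed-value boundaries;
* proportion CIs are Clopper-Pearson (exact binomial), likelihood-ratio
  CIs use the log method (delta method on the log ratio).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "CutpointResult",
    "DiagnosticStats",
    "Estimate",
    "category_dlr",
    "compose_two_stage",
    "confusion_at",
    "cutoff_for_ppv",
    "cutoff_for_sensitivity",
    "diagnostic_stats",
    "stratify_risk",
]

RISK_TIERS = ("low", "moderate", "high")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 screen-by-outcome counts."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def diseased(self) -> int:
        return self.tp + self.fn

    @property
    def healthy(self) -> int:
        return self.fp + self.tn

    @property
    def positives(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class Estimate:
    """A point estimate with a CI; undefined statistics carry a reason."""

    value: float | None
    ci_low: float | None = None
    ci_high: float | None = None
    note: str | None = None

    def defined(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class DiagnosticStats:
    sensitivity: Estimate
    specificity: Estimate
    ppv: Estimate
    npv: Estimate
    dlr_pos: Estimate
    dlr_neg: Estimate
    fail_rate: float
    ci_level: float = 0.95


@dataclass(frozen=True)
class CutpointResult:
    cutoff: float
    stats: DiagnosticStats
    target_met: bool = True


def confusion_at(scores, labels, cutoff: float) -> ConfusionCounts:
    """Cross-classify ``score >= cutoff`` against the binary labels."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-D vectors")
    if len(s) == 0:
        raise ValueError("empty input")
    pos = s >= cutoff
    return ConfusionCounts(
        tp=int(np.sum(pos & y)),
        fp=int(np.sum(pos & ~y)),
        tn=int(np.sum(~pos & ~y)),
        fn=int(np.sum(~pos & y)),
    )


def _proportion(k: int, n: int, level: float, name: str) -> Estimate:
    if n == 0:
        return Estimate(None, note=f"{name} undefined: zero denominator")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return Estimate(k / n, low, high)


def _dlr(num_k, num_n, den_k, den_n, level: float, name: str) -> Estimate:
    """Ratio of two proportions with a log-method CI."""
    if num_n == 0 or den_n == 0:
        return Estimate(None, note=f"{name} undefined: zero denominator")
    if den_k == 0:
        return Estimate(
            float("inf") if num_k > 0 else None,
            note=f"{name} unbounded: denominator proportion is zero",
        )
    value = (num_k / num_n) / (den_k / den_n)
    if num_k == 0:
        return Estimate(0.0, note=f"{name} CI undefined: zero numerator count")
    z = stats.norm.ppf(0.5 + level / 2.0)
    se_log = np.sqrt(1 / num_k - 1 / num_n + 1 / den_k - 1 / den_n)
    return Estimate(
        float(value),
        float(value * np.exp(-z * se_log)),
        float(value * np.exp(z * se_log)),
    )


def diagnostic_stats(counts: ConfusionCounts, ci_level: float = 0.95) -> DiagnosticStats:
    """Se/Sp/PPV/NPV with Clopper-Pearson CIs; DLRs with log-method CIs."""
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    return DiagnosticStats(
        sensitivity=_proportion(counts.tp, counts.diseased, ci_level, "sensitivity"),
        specificity=_proportion(counts.tn, counts.healthy, ci_level, "specificity"),
        ppv=_proportion(counts.tp, counts.positives, ci_level, "PPV"),
        npv=_proportion(counts.tn, counts.tn + counts.fn, ci_level, "NPV"),
        dlr_pos=_dlr(
            counts.tp, counts.diseased, counts.fp, counts.healthy, ci_level, "DLR+"
        ),
        dlr_neg=_dlr(
            counts.fn, counts.diseased, counts.tn, counts.healthy, ci_level, "DLR-"
        ),
        fail_rate=counts.positives / counts.total,
        ci_level=ci_level,
    )


def category_dlr(
    tier_counts: dict[str, tuple[int, int]], ci_level: float = 0.95
) -> dict[str, Estimate]:
    """Stratum-specific likelihood ratios for multi-level screen results.

    ``tier_counts`` maps tier name -> (diseased, non-diseased) counts.
    The LR of a tier is (tier share of all diseased) / (tier share of
    all non-diseased).
    """
    diseased_total = sum(d for d, _ in tier_counts.values())
    healthy_total = sum(h for _, h in tier_counts.values())
    if diseased_total == 0 or healthy_total == 0:
        raise ValueError("overall diseased and non-diseased totals must be positive")
    out: dict[str, Estimate] = {}
    for tier, (d, h) in tier_counts.items():
        if d == 0 and h == 0:
            out[tier] = Estimate(None, note=f"tier '{tier}' empty")
        else:
            out[tier] = _dlr(d, diseased_total, h, healthy_total, ci_level, "DLR")
    return out


def _candidate_cutoffs(scores: np.ndarray) -> np.ndarray:
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise ValueError("degenerate score vector: all scores identical")
    mids = (uniq[1:] + uniq[:-1]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.all() or not labels.any():
        raise ValueError("both outcome classes must be present")


def cutoff_for_sensitivity(
    scores, labels, target_se: float, ci_level: float = 0.95
) -> CutpointResult:
    """Cutoff whose sensitivity is closest to ``target_se``.

    Ties on |Se - target| are broken by higher specificity, then by the
    higher cutoff (the more conservative screen).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    _check_two_classes(y)
    best = None
    for cut in _candidate_cutoffs(s):
        c = confusion_at(s, y, cut)
        se = c.tp / c.diseased
        sp = c.tn / c.healthy
        key = (-abs(se - target_se), sp, cut)
        if best is None or key > best[0]:
            best = (key, cut, c)
    _, cut, c = best
    return CutpointResult(float(cut), diagnostic_stats(c, ci_level), True)


def cutoff_for_ppv(
    scores, labels, target_ppv: float, ci_level: float = 0.95
) -> CutpointResult:
    """Cutoff maximizing sensitivity subject to ``PPV >= target_ppv``.

    Ties on sensitivity are broken by the lower cutoff.  If no cutoff
    reaches the target, the cutoff with maximal PPV is returned with
    ``target_met=False``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    _check_two_classes(y)
    best_feasible = None
    best_fallback = None
    for cut in _candidate_cutoffs(s):
        c = confusion_at(s, y, cut)
        if c.positives == 0:
            continue
        ppv = c.tp / c.positives
        se = c.tp / c.diseased
        if ppv >= target_ppv:
            key = (se, -cut)
            if best_feasible is None or key > best_feasible[0]:
                best_feasible = (key, cut, c)
        key = (ppv, se, -cut)
        if best_fallback is None or key > best_fallback[0]:
            best_fallback = (key, cut, c)
    if best_feasible is not None:
        _, cut, c = best_feasible
        return CutpointResult(float(cut), diagnostic_stats(c, ci_level), True)
    _, cut, c = best_fallback
    return CutpointResult(float(cut), diagnostic_stats(c, ci_level), False)


def compose_two_stage(stage1_prob, stage1_cutoff: float, stage2_prob) -> pd.DataFrame:
    """Compose the total two-stage screening score.

    A child fails stage 1 iff ``stage1_prob >= stage1_cutoff``.  The
    total score is the stage-1 probability for passes and the stage-2
    probability for failures; a missing stage-2 probability for a
    failure is an error, and stage-2 values supplied for passes are
    ignored (masked to missing in the output).
    """
    p1 = np.asarray(stage1_prob, dtype=float)
    p2 = np.asarray(stage2_prob, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("stage-1 and stage-2 probability vectors must align")
    fail = p1 >= stage1_cutoff
    missing = fail & ~np.isfinite(p2)
    if missing.any():
        raise ValueError(
            f"{int(missing.sum())} stage-1 failure(s) lack a stage-2 probability"
        )
    total = np.where(fail, p2, p1)
    return pd.DataFrame(
        {
            "stage1_prob": p1,
            "stage1_fail": fail,
            "stage2_prob": np.where(fail, p2, np.nan),
            "total_score": total,
        }
    )


def stratify_risk(
    total_score,
    cut_high: float,
    cut_moderate: float,
    labels=None,
    ci_level: float = 0.95,
) -> tuple[np.ndarray, pd.DataFrame | None]:
    """Assign low / moderate / high risk tiers from the total score.

    ``high`` iff ``total >= cut_high``; ``moderate`` iff
    ``cut_moderate <= total < cut_high``; else ``low``.  When outcome
    labels are given, a flow-style tier summary (counts, tier
    prevalence, stratum-specific likelihood ratios) is also returned.
    """
    if cut_high < cut_moderate:
        raise ValueError(
            f"cut_high ({cut_high}) must be >= cut_moderate ({cut_moderate})"
        )
    t = np.asarray(total_score, dtype=float)
    tiers = np.where(t >= cut_high, "high", np.where(t >= cut_moderate, "moderate", "low"))
    if labels is None:
        return tiers, None
    y = np.asarray(labels).astype(bool)
    counts = {
        tier: (int(np.sum((tiers == tier) & y)), int(np.sum((tiers == tier) & ~y)))
        for tier in RISK_TIERS
    }
    lrs = category_dlr(counts, ci_level)
    rows = []
    for tier in RISK_TIERS:
        d, h = counts[tier]
        n_tier = d + h
        rows.append(
            {
                "tier": tier,
                "n": n_tier,
                "sld": d,
                "no_sld": h,
                "tier_share": n_tier / len(t),
                "tier_prevalence": d / n_tier if n_tier else np.nan,
                "dlr": lrs[tier].value,
                "dlr_ci_low": lrs[tier].ci_low,
                "dlr_ci_high": lrs[tier].ci_high,
            }
        )
    return tiers, pd.DataFrame(rows)
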