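"""Confusion statistics, constrained cutoffs, composition and tiers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from langscreen import (
    ConfusionCounts,
    category_dlr,
    compose_two_stage,
    confusion_at,
    cutoff_for_ppv,
    cutoff_for_sensitivity,
    diagnostic_stats,
    stratify_risk,
)

# Flow counts of the published screen on its validation cohort
# (n=621, 70 SLD): stage-1 referral cutoff and the two-tier grading.
STAGE1_COUNTS = ConfusionCounts(tp=63, fp=161, tn=390, fn=7)
HIGH_TIER_COUNTS = ConfusionCounts(tp=20, fp=5, tn=546, fn=50)
MODERATE_PLUS_HIGH_COUNTS = ConfusionCounts(tp=52, fp=75, tn=476, fn=18)


class TestConfusionAt:
    def test_simple_split(self):
        c = confusion_at([0.9, 0.1], [1, 0], 0.5)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)

    def test_cutoff_above_max(self):
        c = confusion_at([0.2, 0.4, 0.3], [1, 0, 1], 0.9)
        assert c.tp == 0 and c.fp == 0 and c.total == 3

    def test_boundary_is_positive(self):
        c = confusion_at([0.5], [1], 0.5)
        assert c.tp == 1

    def test_matches_per_record_classification(self, rng):
        scores = rng.random(20)
        labels = rng.random(20) < 0.4
        cut = 0.35
        c = confusion_at(scores, labels, cut)
        expected = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for s, y in zip(scores, labels):
            key = ("t" if (s >= cut) == y else "f") + ("p" if s >= cut else "n")
            expected[key] += 1
        assert (c.tp, c.fp, c.tn, c.fn) == tuple(expected[k] for k in ("tp", "fp", "tn", "fn"))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_at([], [], 0.5)


class TestDiagnosticStats:
    def test_published_flow_statistics(self):
        high = diagnostic_stats(HIGH_TIER_COUNTS)
        assert high.ppv.value == pytest.approx(0.80, abs=1e-12)
        assert high.sensitivity.value == pytest.approx(20 / 70, abs=1e-12)
        both = diagnostic_stats(MODERATE_PLUS_HIGH_COUNTS)
        assert both.sensitivity.value == pytest.approx(0.743, abs=5e-4)
        assert both.specificity.value == pytest.approx(0.864, abs=5e-4)
        assert both.npv.value == pytest.approx(0.964, abs=5e-4)

    def test_stage1_referral_statistics(self):
        s = diagnostic_stats(STAGE1_COUNTS)
        assert s.sensitivity.value == pytest.approx(0.900, abs=1e-12)
        assert s.specificity.value == pytest.approx(0.708, abs=5e-4)
        assert s.ppv.value == pytest.approx(0.281, abs=5e-4)
        assert s.dlr_neg.value == pytest.approx(0.141, abs=5e-4)
        assert s.dlr_pos.value == pytest.approx(3.080, abs=5e-3)
        assert s.fail_rate == pytest.approx(224 / 621, abs=1e-12)

    def test_dlr_identities(self):
        s = diagnostic_stats(MODERATE_PLUS_HIGH_COUNTS)
        se, sp = s.sensitivity.value, s.specificity.value
        assert s.dlr_pos.value == pytest.approx(se / (1 - sp), abs=1e-12)
        assert s.dlr_neg.value == pytest.approx((1 - se) / sp, abs=1e-12)

    def test_ci_orientation_and_coverage_shape(self):
        s = diagnostic_stats(STAGE1_COUNTS)
        for est in (s.sensitivity, s.specificity, s.ppv, s.npv):
            assert est.ci_low <= est.value <= est.ci_high
        assert s.dlr_neg.ci_low < s.dlr_neg.value < s.dlr_neg.ci_high

    def test_zero_denominator_reported_not_nan(self):
        s = diagnostic_stats(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert s.ppv.value is None
        assert "undefined" in s.ppv.note

    def test_counts_reconstruct_integer_cells(self, rng):
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(1, 50, 4)
            c = ConfusionCounts(int(tp), int(fp), int(tn), int(fn))
            s = diagnostic_stats(c)
            assert s.sensitivity.value * c.diseased == pytest.approx(c.tp, abs=1e-9)
            assert s.specificity.value * c.healthy == pytest.approx(c.tn, abs=1e-9)


class TestCategoryDlr:
    def test_published_high_tier_value(self):
        lrs = category_dlr({"high": (20, 5), "moderate": (32, 70), "low": (18, 476)})
        assert lrs["high"].value == pytest.approx(31.486, abs=5e-3)

    def test_single_tier_is_unity(self):
        lrs = category_dlr({"all": (70, 551)})
        assert lrs["all"].value == pytest.approx(1.0, abs=1e-12)

    def test_three_tier_hand_arithmetic(self):
        lrs = category_dlr({"a": (10, 10), "b": (5, 40), "c": (5, 50)})
        assert lrs["a"].value == pytest.approx((10 / 20) / (10 / 100), abs=1e-12)
        assert lrs["b"].value == pytest.approx((5 / 20) / (40 / 100), abs=1e-12)
        assert lrs["c"].value == pytest.approx((5 / 20) / (50 / 100), abs=1e-12)

    def test_tier_shares_sum_to_one(self):
        counts = {"high": (20, 5), "moderate": (32, 70), "low": (18, 476)}
        d_tot = sum(d for d, _ in counts.values())
        h_tot = sum(h for _, h in counts.values())
        assert sum(d / d_tot for d, _ in counts.values()) == pytest.approx(1.0)
        assert sum(h / h_tot for _, h in counts.values()) == pytest.approx(1.0)

    def test_empty_tier_undefined(self):
        lrs = category_dlr({"a": (10, 10), "empty": (0, 0)})
        assert lrs["empty"].value is None


def _brute_force_candidates(scores):
    uniq = np.unique(scores)
    return np.concatenate(([-np.inf], (uniq[1:] + uniq[:-1]) / 2, [np.inf]))


class TestCutoffForSensitivity:
    def test_small_enumerated_example(self):
        """Se target 2/3: the Se=2/3, Sp=1 cutoff beats the Se=2/3, Sp=2/3 one."""
        scores = [0.9, 0.7, 0.3, 0.6, 0.2, 0.1]
        labels = [1, 1, 1, 0, 0, 0]
        res = cutoff_for_sensitivity(scores, labels, 2 / 3)
        assert 0.6 < res.cutoff < 0.7
        assert res.stats.sensitivity.value == pytest.approx(2 / 3)
        assert res.stats.specificity.value == 1.0

    def test_target_one_catches_all_diseased(self):
        scores = [0.9, 0.7, 0.3, 0.6, 0.2, 0.1]
        labels = [1, 1, 1, 0, 0, 0]
        res = cutoff_for_sensitivity(scores, labels, 1.0)
        assert res.stats.sensitivity.value == 1.0
        assert res.cutoff <= 0.3

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cutoff_for_sensitivity([0.5, 0.5, 0.5], [1, 0, 1], 0.9)

    def test_matches_bruteforce_on_random_fixture(self, rng):
        scores = rng.random(200)
        labels = rng.random(200) < 0.3
        res = cutoff_for_sensitivity(scores, labels, 0.9)
        best = None
        for cut in _brute_force_candidates(scores):
            c = confusion_at(scores, labels, cut)
            key = (-abs(c.tp / c.diseased - 0.9), c.tn / c.healthy, cut)
            if best is None or key > best[0]:
                best = (key, cut)
        assert res.cutoff == best[1]


class TestCutoffForPpv:
    def test_small_enumerated_example(self):
        scores = [0.9, 0.7, 0.3, 0.6, 0.2, 0.1]
        labels = [1, 1, 1, 0, 0, 0]
        res = cutoff_for_ppv(scores, labels, 1.0)
        assert 0.6 < res.cutoff < 0.7
        assert res.stats.ppv.value == 1.0
        assert res.stats.sensitivity.value == pytest.approx(2 / 3)

    def test_target_zero_everyone_positive(self):
        scores = [0.9, 0.7, 0.3, 0.6, 0.2, 0.1]
        labels = [1, 1, 1, 0, 0, 0]
        res = cutoff_for_ppv(scores, labels, 1e-9)
        assert np.isneginf(res.cutoff)
        assert res.stats.sensitivity.value == 1.0

    def test_unreachable_target_flagged(self):
        scores = [0.4, 0.6, 0.5, 0.7]
        labels = [1, 0, 1, 0]  # every positive set mixes in a healthy child
        res = cutoff_for_ppv(scores, labels, 0.99)
        assert res.target_met is False

    def test_matches_bruteforce_on_random_fixture(self, rng):
        labels = rng.random(200) < 0.3
        scores = np.clip(rng.random(200) * 0.6 + labels * 0.4, 0, 1)
        res = cutoff_for_ppv(scores, labels, 0.8)
        feasible = []
        for cut in _brute_force_candidates(scores):
            c = confusion_at(scores, labels, cut)
            if c.positives and c.tp / c.positives >= 0.8:
                feasible.append((c.tp / c.diseased, -cut, cut))
        assert feasible, "fixture should admit a feasible cutoff"
        assert res.cutoff == max(feasible)[2]


@settings(max_examples=120, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.floats(0.05, 0.95))
def test_constrained_searches_match_exhaustive_scan(seed, target):
    """Both constrained searches agree exactly with an exhaustive scan."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(20, 120))
    scores = np.round(rng.random(n), 2)  # coarse grid to force ties
    labels = rng.random(n) < 0.35
    if labels.all() or not labels.any() or np.unique(scores).size < 2:
        return
    res_se = cutoff_for_sensitivity(scores, labels, target)
    res_ppv = cutoff_for_ppv(scores, labels, target)
    best_se, best_ppv_feasible, best_ppv_fallback = None, None, None
    for cut in _brute_force_candidates(scores):
        c = confusion_at(scores, labels, cut)
        se = c.tp / c.diseased
        sp = c.tn / c.healthy
        key = (-abs(se - target), sp, cut)
        if best_se is None or key > best_se[0]:
            best_se = (key, cut)
        if c.positives:
            ppv = c.tp / c.positives
            if ppv >= target:
                k = (se, -cut)
                if best_ppv_feasible is None or k > best_ppv_feasible[0]:
                    best_ppv_feasible = (k, cut)
            k = (ppv, se, -cut)
            if best_ppv_fallback is None or k > best_ppv_fallback[0]:
                best_ppv_fallback = (k, cut)
    assert res_se.cutoff == best_se[1]
    expected_ppv = best_ppv_feasible or best_ppv_fallback
    assert res_ppv.cutoff == expected_ppv[1]
    assert res_ppv.target_met is (best_ppv_feasible is not None)


class TestComposeTwoStage:
    def test_pass_keeps_stage1_score(self):
        out = compose_two_stage([0.03], 0.05, [np.nan])
        assert not out["stage1_fail"].iloc[0]
        assert out["total_score"].iloc[0] == 0.03

    def test_fail_uses_stage2_score(self):
        out = compose_two_stage([0.30], 0.05, [0.55])
        assert out["stage1_fail"].iloc[0]
        assert out["total_score"].iloc[0] == 0.55

    def test_boundary_counts_as_failure(self):
        out = compose_two_stage([0.05], 0.05, [0.10])
        assert out["stage1_fail"].iloc[0]
        assert out["total_score"].iloc[0] == 0.10

    def test_missing_stage2_for_failure_rejected(self):
        with pytest.raises(ValueError, match="stage-2"):
            compose_two_stage([0.30], 0.05, [np.nan])

    def test_stage2_for_passes_masked(self):
        out = compose_two_stage([0.01, 0.3], 0.05, [0.9, 0.4])
        assert np.isnan(out["stage2_prob"].iloc[0])
        assert out["total_score"].tolist() == [0.01, 0.4]


class TestStratifyRisk:
    def test_published_tier_cutoffs(self):
        tiers, _ = stratify_risk([0.9, 0.3, 0.01], 0.594, 0.169)
        assert tiers.tolist() == ["high", "moderate", "low"]

    def test_equal_cutoffs_empty_moderate(self):
        tiers, _ = stratify_risk([0.9, 0.3, 0.01], 0.3, 0.3)
        assert "moderate" not in tiers

    def test_inverted_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            stratify_risk([0.5], 0.2, 0.4)

    def test_counts_match_bruteforce(self, rng):
        totals = rng.random(500)
        labels = rng.random(500) < 0.2
        tiers, summary = stratify_risk(totals, 0.6, 0.25, labels)
        expected = {
            "high": np.sum(totals >= 0.6),
            "moderate": np.sum((totals >= 0.25) & (totals < 0.6)),
            "low": np.sum(totals < 0.25),
        }
        got = dict(zip(summary["tier"], summary["n"]))
        assert got == {k: int(v) for k, v in expected.items()}
        assert summary["n"].sum() == 500
        assert summary["sld"].sum() == labels.sum()
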