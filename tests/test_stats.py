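import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

from myoasl.stats import (
    DegenerateTestError,
    cross_sectional_compare,
    filter_paired,
    holm_sidak,
    mpr,
    oneway_anova,
    paired_ttest,
    regional_summary,
)


def brute_paired_t(x, y):
    """Textbook paired t: t = mean(d) / (sd(d)/sqrt(n)), two-sided p."""
    d = np.asarray(x, float) - np.asarray(y, float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
    return t, 2 * t_dist.sf(abs(t), n - 1)


def brute_anova(groups):
    """Textbook one-way ANOVA from explicit sums of squares."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    dfb, dfw = len(groups) - 1, allv.size - len(groups)
    F = (ssb / dfb) / (ssw / dfw)
    return F, f_dist.sf(F, dfb, dfw)


def brute_holm_sidak(p):
    """Step-down Sidak by direct evaluation of the definition."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        adj = 1 - (1 - p[idx]) ** (m - rank)
        running = max(running, adj)
        out[idx] = min(1.0, running)
    return out


class TestPairedTTest:
    def test_identical_samples(self):
        t, p = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_matches_textbook_formula(self):
        x = np.array([2.0, 4.0, 6.0, 5.0, 3.0])
        y = np.array([1.0, 2.0, 3.0, 5.0, 4.0])
        t, p = paired_ttest(x, y)
        tb, pb = brute_paired_t(x, y)
        assert t == pytest.approx(tb, abs=1e-12)
        assert p == pytest.approx(pb, abs=1e-12)

    def test_sign_flip_negates_t_keeps_p(self):
        x = np.array([2.0, 4.0, 6.0])
        y = np.array([1.0, 2.0, 3.0])
        t1, p1 = paired_ttest(x, y)
        t2, p2 = paired_ttest(y, x)
        assert t2 == pytest.approx(-t1) and p2 == pytest.approx(p1)

    def test_constant_nonzero_differences_degenerate(self):
        with pytest.raises(DegenerateTestError):
            paired_ttest([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])


class TestOnewayAnova:
    def test_equal_group_means_give_zero_f(self):
        f, p = oneway_anova([[1.0, 2.0], [1.0, 2.0]])
        assert f == 0.0 and p == pytest.approx(1.0)

    def test_matches_hand_computed_sums_of_squares(self):
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]
        f, p = oneway_anova(groups)
        fb, pb = brute_anova(groups)
        assert f == pytest.approx(fb, abs=1e-12)
        assert p == pytest.approx(pb, abs=1e-12)

    @given(shift=st.floats(min_value=-100, max_value=100))
    def test_location_invariance(self, shift):
        groups = [np.array([1.0, 2.0, 4.0]), np.array([2.0, 5.0, 6.0]), np.array([0.5, 1.5])]
        f0, _ = oneway_anova(groups)
        f1, _ = oneway_anova([g + shift for g in groups])
        assert f1 == pytest.approx(f0, rel=1e-9, abs=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            oneway_anova([[1.0], [2.0, 3.0]])


class TestHolmSidak:
    def test_single_p_unchanged(self):
        assert holm_sidak([0.03]) == pytest.approx([0.03])

    def test_two_p_example(self):
        adj = holm_sidak([0.01, 0.04])
        assert adj[0] == pytest.approx(1 - 0.99**2, abs=1e-12)  # 0.0199
        assert adj[1] == pytest.approx(0.04, abs=1e-12)

    def test_matches_brute_force(self):
        p = np.array([0.2, 0.01, 0.8, 0.03, 0.001])
        assert holm_sidak(p) == pytest.approx(brute_holm_sidak(p), abs=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8))
    def test_adjusted_at_least_raw_and_order_invariant(self, pvals):
        p = np.asarray(pvals)
        adj = holm_sidak(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
        perm = np.argsort(p, kind="stable")[::-1]
        adj_perm = holm_sidak(p[perm])
        assert adj_perm == pytest.approx(adj[perm], abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_sidak([0.5, 1.2])


def toy_table():
    rows = []
    for i, (rest_inc, stress_inc) in enumerate([(True, True), (True, False), (False, True), (True, True)]):
        for cond, inc, mbf in (("rest", rest_inc, 1.0 + i), ("stress", stress_inc, 2.0 + i)):
            rows.append(
                {
                    "subject": "a",
                    "slice": "s1",
                    "segment": i + 1,
                    "region": "other",
                    "condition": cond,
                    "timepoint": "baseline",
                    "mbf": mbf,
                    "pn": 0.1,
                    "tsnr": 5.0,
                    "included": inc,
                }
            )
    return pd.DataFrame(rows)


class TestFilterPaired:
    def test_segment_excluded_in_either_condition_is_dropped(self):
        paired = filter_paired(toy_table(), "rest", "stress")
        assert paired.n_kept == 2 and paired.n_dropped == 2
        assert set(paired.keys["segment"]) == {1, 4}

    def test_all_included_all_kept(self):
        t = toy_table()
        t["included"] = True
        paired = filter_paired(t, "rest", "stress")
        assert paired.n_kept == 4 and paired.n_dropped == 0

    def test_counts_conserve_totals(self):
        paired = filter_paired(toy_table(), "rest", "stress")
        assert paired.n_kept + paired.n_dropped == 4


class TestMpr:
    def test_rest_equals_stress_gives_unity(self):
        out = mpr([1.0, 2.0], [1.0, 2.0])
        assert out.mean == pytest.approx(1.0) and out.sd == 0.0

    def test_simple_ratio(self):
        assert mpr([1.0], [1.5]).mean == pytest.approx(1.5)

    def test_nonpositive_rest_flagged_undefined(self):
        out = mpr([1.0, 0.0, -0.2], [1.5, 1.0, 1.0])
        assert out.n == 1 and out.n_undefined == 2
        assert np.isnan(out.ratios[1]) and np.isnan(out.ratios[2])


class TestRegionalSummary:
    def test_single_row_group(self):
        t = toy_table().iloc[[0]]
        s = regional_summary(t)
        assert s.loc[0, "mbf_mean"] == 1.0 and s.loc[0, "mbf_sd"] == 0.0 and s.loc[0, "n"] == 1

    def test_remote_pools_three_segments(self):
        rows = []
        for seg, region, v in [(4, "remote", 1.0), (5, "remote", 2.0), (6, "remote", 3.0)]:
            rows.append(
                {
                    "subject": "a", "slice": "s", "segment": seg, "region": region,
                    "condition": "rest", "timepoint": "baseline", "mbf": v,
                    "pn": 0.1, "tsnr": 5.0, "included": True,
                }
            )
        s = regional_summary(pd.DataFrame(rows))
        assert s.loc[0, "n"] == 3
        assert s.loc[0, "mbf_mean"] == pytest.approx(np.mean([1, 2, 3]))
        assert s.loc[0, "mbf_sd"] == pytest.approx(np.std([1, 2, 3], ddof=1))

    def test_excluded_rows_skipped_unless_requested(self):
        t = toy_table()
        inc = regional_summary(t)
        all_rows = regional_summary(t, use_all_rows=True)
        assert all_rows["n"].sum() == 8 and inc["n"].sum() == 6


def null_cross_table(rng, sizes={"baseline": 41, "day1_2": 9, "week1_2": 8, "week4": 4}):
    rows = []
    for tp, n in sizes.items():
        for i, v in enumerate(rng.normal(1.08, 0.62, n)):
            rows.append(
                {
                    "subject": f"s{i}", "slice": f"sl{i}", "segment": 2, "region": "infarct",
                    "condition": "rest", "timepoint": tp, "mbf": v, "pn": 0.1,
                    "tsnr": 5.0, "included": True,
                }
            )
    return pd.DataFrame(rows)


class TestCrossSectional:
    def test_structure_and_adjustment(self):
        rng = np.random.default_rng(0)
        res = cross_sectional_compare(null_cross_table(rng), "infarct")
        assert res.timepoints == ["baseline", "day1_2", "week1_2", "week4"]
        assert list(res.comparisons["timepoint"]) == ["day1_2", "week1_2", "week4"]
        assert np.all(res.comparisons["p_adjusted"] >= res.comparisons["p_raw"] - 1e-15)

    def test_large_effect_detected(self):
        rng = np.random.default_rng(1)
        t = null_cross_table(rng)
        t.loc[t["timepoint"] != "baseline", "mbf"] -= 0.9
        res = cross_sectional_compare(t, "infarct")
        assert res.anova_p < 0.05
        assert res.comparisons["significant"].all()
        assert (res.comparisons["mean_diff"] < 0).all()

    def test_type_one_error_near_nominal(self):
        # family-wise rejection rate of the full ANOVA + Holm-Sidak
        # procedure under the null, at the study's group sizes
        rng = np.random.default_rng(42)
        n, rej = 600, 0
        for _ in range(n):
            res = cross_sectional_compare(null_cross_table(rng), "infarct")
            rej += int(res.comparisons["significant"].any())
        assert abs(rej / n - 0.05) <= 0.02
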