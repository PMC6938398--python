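import numpy as np
import pytest

from burstlet.stats import (ancova_homogeneity, anova_tukey, compare_groups,
                            correlate, holm_adjust, remove_outliers)


class TestOutlierRule:
    def test_moderate_extreme_survives_three_sd(self):
        """(1,1,1,1,100): the outlier inflates the SD enough to keep itself.

        Oracle: mean 20.8, sample SD ~44.27, |100 - 20.8| = 79.2 < 3 SD.
        """
        kept, removed = remove_outliers([1, 1, 1, 1, 100])
        assert removed.size == 0
        assert kept.size == 5

    def test_identical_values_zero_sd_removes_nothing(self):
        kept, removed = remove_outliers([2.0, 2.0, 2.0, 2.0])
        assert removed.size == 0

    def test_true_outlier_removed(self):
        values = np.concatenate([np.zeros(50), [100.0]])
        kept, removed = remove_outliers(values + np.arange(51) * 1e-3)
        assert removed.size == 1
        assert removed[0] > 99

    def test_normal_tail_mass_near_quarter_percent(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(10_000)
        _, removed = remove_outliers(x)
        assert 0.0005 < removed.size / 10_000 < 0.006

    def test_single_pass_no_iteration(self):
        # after removing the big outlier the remainder would flag more
        # points on a second pass; the rule must not take it
        x = np.concatenate([np.random.default_rng(1).normal(0, 1, 100),
                            [50.0]])
        kept, removed = remove_outliers(x)
        assert removed.size == 1
        assert kept.size == 100

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            remove_outliers([1.0, 2.0])


class TestCompareGroups:
    def test_identical_groups_max_p(self):
        a = [1.0, 2.0, 3.0, 4.0]
        assert compare_groups(a, a, parametric=True).p_value == pytest.approx(1.0)
        assert compare_groups(a, a, parametric=False).p_value > 0.65

    def test_identical_paired_groups_t_zero(self):
        res = compare_groups([1, 2, 3], [1, 2, 3], paired=True, parametric=True)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_symmetry_in_group_order(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        assert compare_groups(a, b).p_value == pytest.approx(
            compare_groups(b, a).p_value)

    def test_gate_records_which_test_ran(self):
        rng = np.random.default_rng(3)
        res = compare_groups(rng.normal(0, 1, 20), rng.normal(0, 1, 20))
        assert res.test_name in ("t-test", "mann-whitney")
        assert len(res.normality_p) == 2

    def test_skewed_data_routes_to_mann_whitney(self):
        rng = np.random.default_rng(4)
        a = rng.lognormal(0, 2.0, 50)
        b = rng.lognormal(0.3, 2.0, 50)
        assert compare_groups(a, b).test_name == "mann-whitney"

    def test_mismatched_paired_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2, 3], [1, 2], paired=True)


class TestHolm:
    def test_matches_hand_applied_step_down(self):
        # ordered p: 0.01, 0.03, 0.04 -> multipliers 3, 2, 1 with monotone
        # enforcement: (0.03, 0.06, 0.06); only the first is significant
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.03, 0.06, 0.06])
        assert (adj < 0.05).tolist() == [True, False, False]

    def test_monotone_in_ordered_raw_p(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 20)
        adj = holm_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj <= 1.0)


class TestAnovaTukey:
    def test_identical_groups_omnibus_near_one(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = anova_tukey([g, g, g])
        assert res.p_omnibus > 0.99

    def test_separated_group_detected(self):
        rng = np.random.default_rng(6)
        res = anova_tukey([rng.normal(0, 1, 20), rng.normal(0, 1, 20),
                           rng.normal(3, 1, 20)])
        assert res.p_omnibus < 0.001
        worst = res.tukey.sort_values("p_adj").iloc[0]
        assert {worst["group1"], worst["group2"]} & {"g2"}
        assert res.holm["p_holm"].min() < 0.01

    def test_repeated_measures_variant(self):
        rng = np.random.default_rng(7)
        subject = rng.normal(0, 2, 10)
        groups = [subject + rng.normal(d, 0.5, 10) for d in (0.0, 0.2, 2.0)]
        res = anova_tukey(groups, repeated=True)
        assert res.repeated
        assert res.p_omnibus < 0.01

    def test_needs_three_groups(self):
        with pytest.raises(ValueError):
            anova_tukey([[1, 2], [3, 4]])


class TestCorrelate:
    def test_perfect_line(self):
        x = np.arange(10.0)
        res = correlate(x, 2 * x)
        assert res.r_squared == pytest.approx(1.0)
        assert res.p_slope < 1e-12
        assert res.slope == pytest.approx(2.0)

    def test_r_squared_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 1, 40)
        y = 0.5 * x + rng.normal(0, 0.1, 40)
        r1 = correlate(x, y).r_squared
        r2 = correlate(3 * x - 1, -2 * y + 5).r_squared
        assert r1 == pytest.approx(r2)

    def test_f_is_square_of_slope_t(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 1, 30)
        y = x + rng.normal(0, 0.3, 30)
        res = correlate(x, y)
        from scipy import stats as sps
        lr = sps.linregress(x, y)
        assert res.f_statistic == pytest.approx((lr.slope / lr.stderr) ** 2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAncova:
    def test_same_exact_line_gives_p_one(self):
        x = np.arange(12.0)
        y = 2 * x + 1
        labels = ["a"] * 6 + ["b"] * 6
        res = ancova_homogeneity(x, y, labels)
        assert res.p_homogeneity == pytest.approx(1.0)

    def test_different_slopes_detected(self):
        rng = np.random.default_rng(10)
        x = np.concatenate([rng.uniform(0, 1, 30), rng.uniform(0, 1, 30)])
        y = np.concatenate([rng.normal(0, 0.1, 30),
                            2 * x[30:] + rng.normal(0, 0.1, 30)])
        labels = ["flat"] * 30 + ["steep"] * 30
        res = ancova_homogeneity(x, y, labels)
        assert res.p_homogeneity < 1e-6
        assert res.test_name == "t"
        assert res.slopes["flat"] == pytest.approx(0.0, abs=0.2)
        assert res.slopes["steep"] == pytest.approx(2.0, abs=0.3)

    def test_three_groups_use_f_test(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 1, 45)
        y = x + rng.normal(0, 0.2, 45)
        labels = np.repeat(["a", "b", "c"], 15)
        res = ancova_homogeneity(x, y, labels)
        assert res.test_name == "F"
        assert 0 <= res.p_homogeneity <= 1

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            ancova_homogeneity([1, 2, 3, 4], [1, 2, 3, 4],
                               ["a", "a", "a", "b"])
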