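import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from muroct.stats import (
    LongitudinalTable,
    compare_groups,
    complete_cases,
    normality,
    rm_anova_oneway,
    rm_anova_twoway,
    stars,
    tukey_kramer,
    welch_from_summary,
)


class TestNormality:
    def test_gaussian_sample_passes(self):
        rng = np.random.default_rng(0)
        ok, res = normality(rng.standard_normal(200))
        assert ok and res.p >= 0.10

    def test_bimodal_sample_fails(self):
        ok, res = normality([1, 1, 1, 10, 10, 10])
        assert not ok and res.p < 0.10

    def test_zero_variance_is_not_normal(self):
        ok, res = normality([3.0, 3.0, 3.0, 3.0])
        assert not ok and res.p == 0.0

    def test_agrees_with_statsmodels_lilliefors_statistic(self):
        # the statistic (not the p) has a closed form; cross-check it
        from statsmodels.stats.diagnostic import lilliefors

        rng = np.random.default_rng(5)
        x = rng.normal(10, 2, size=60)
        d_sm, _ = lilliefors(x, dist="norm")
        _, res = normality(x)
        assert res.statistic == pytest.approx(d_sm, abs=1e-10)

    def test_type_one_error_close_to_ten_percent(self):
        # seeded null calibration at alpha = 0.10
        rng = np.random.default_rng(42)
        rejected = sum(
            not normality(rng.standard_normal(25), m=400, seed=1)[0]
            for _ in range(300)
        )
        assert rejected / 300 == pytest.approx(0.10, abs=0.04)


class TestCompareGroups:
    def test_identical_gaussianish_samples_give_p_one(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(30)
        res = compare_groups(a, a.copy())
        assert res.method == "welch-t"
        assert res.statistic == 0.0 and res.p == 1.0 and res.p_adj == 1.0

    def test_insufficient_data_result(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0])
        assert res.method == "insufficient-data"
        assert np.isnan(res.p)

    def test_nonnormal_samples_route_to_mann_whitney(self):
        a = np.array([1, 1, 1, 1, 10, 10, 10, 10.0])
        b = a + 0.5
        res = compare_groups(a, b)
        assert res.method == "mann-whitney"

    def test_bonferroni_dominance_and_cap(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal(20), rng.standard_normal(20) + 0.3
        r1 = compare_groups(a, b, m_comparisons=1)
        r8 = compare_groups(a, b, m_comparisons=8)
        assert r8.p == r1.p
        assert r8.p_adj >= r8.p
        assert r8.p_adj == min(1.0, 8 * r1.p)

    def test_published_trt_gap_significant_after_correction(self):
        # an 8 um group gap with SD ~3 at n=40/group survives even an m=8
        # correction at the 0.001 level (the published TRT contrast)
        rng = np.random.default_rng(3)
        a = rng.normal(209.85, 3.08, size=40)
        b = rng.normal(201.85, 3.47, size=40)
        res = compare_groups(a, b, m_comparisons=8)
        assert res.method == "welch-t"
        assert res.p_adj < 0.001
        assert res.stars == "***"

    def test_welch_null_pvalues_are_uniform(self):
        # 1000 seeded null replicates: KS distance from U(0,1) < 0.05
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(1000):
            a, b = rng.standard_normal(15), rng.standard_normal(15)
            t, p = sps.ttest_ind(a, b, equal_var=False)
            ps.append(p)
        d = sps.kstest(ps, "uniform").statistic
        assert d < 0.05


class TestWelchFromSummary:
    def test_equal_summaries_give_t0_p1(self):
        res = welch_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_agrees_with_raw_sample_welch(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(2, 1, 25), rng.normal(1.5, 2, 30)
        t, p = sps.ttest_ind(a, b, equal_var=False)
        res = welch_from_summary(
            a.mean(), a.std(ddof=1), 25, b.mean(), b.std(ddof=1), 30
        )
        assert res.statistic == pytest.approx(t, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-12)

    def test_published_16_month_trt_gap_below_0p001(self):
        # WT 199.17 (3.96) vs 3xTg-AD 194.98 (4.51) with the 16-month eye
        # counts (32+27 and 35+43)
        res = welch_from_summary(199.17, 3.96, 59, 194.98, 4.51, 78)
        assert res.p < 0.001

    def test_input_validation(self):
        with pytest.raises(ValueError):
            welch_from_summary(1, 0.0, 10, 2, 1.0, 10)
        with pytest.raises(ValueError):
            welch_from_summary(1, 1.0, 1, 2, 1.0, 10)


class TestCompleteCases:
    def _records(self):
        return pd.DataFrame(
            {
                "subject": ["a", "a", "a", "b", "b", "c", "c", "c"],
                "time": [1, 2, 3, 1, 3, 1, 2, 3],
                "value": [1.0, 2, 3, 4, 6, 7, 8, 9],
            }
        )

    def test_no_missing_data_is_identity(self):
        rec = self._records()[lambda d: d.subject != "b"]
        table, dropped = complete_cases(rec, times=[1, 2, 3])
        assert table.subjects == ["a", "c"] and dropped == []
        np.testing.assert_allclose(table.values, [[1, 2, 3], [7, 8, 9]])

    def test_dropout_pattern_counted_by_hand(self):
        table, dropped = complete_cases(self._records(), times=[1, 2, 3])
        assert table.subjects == ["a", "c"]
        assert dropped == ["b"]

    def test_fewer_requested_ages_keep_more_subjects(self):
        t_all, _ = complete_cases(self._records(), times=[1, 2, 3])
        t_sub, _ = complete_cases(self._records(), times=[1, 3])
        assert t_sub.n_subjects >= t_all.n_subjects
        assert t_sub.subjects == ["a", "b", "c"]

    def test_empty_result_is_error(self):
        rec = pd.DataFrame({"subject": ["a"], "time": [1], "value": [1.0]})
        with pytest.raises(ValueError):
            complete_cases(rec, times=[1, 2])


class TestRmAnovaOneway:
    def _table(self, n=8, k=4, effect=None, seed=6):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((n, k)) + rng.standard_normal((n, 1))
        if effect is not None:
            x = x + np.asarray(effect)
        return LongitudinalTable(x, list(range(n)), list(range(k)))

    def test_constant_over_time_gives_f0_p1(self):
        rng = np.random.default_rng(7)
        x = np.tile(rng.standard_normal((6, 1)), (1, 4))
        res = rm_anova_oneway(LongitudinalTable(x, list(range(6)), list(range(4))),
                              force="ranova")
        assert res.statistic == 0.0 and res.p == 1.0

    def test_f_matches_hand_computed_sums_of_squares(self):
        # 3 subjects x 3 times worked example, decomposed by hand
        x = np.array([[10.0, 12, 14], [11, 13, 14], [9, 11, 13]])
        grand = x.mean()
        ss_time = 3 * ((x.mean(0) - grand) ** 2).sum()
        ss_subj = 3 * ((x.mean(1) - grand) ** 2).sum()
        ss_err = ((x - grand) ** 2).sum() - ss_time - ss_subj
        f_hand = (ss_time / 2) / (ss_err / 4)
        res = rm_anova_oneway(
            LongitudinalTable(x, ["s1", "s2", "s3"], [1, 2, 3]), force="ranova"
        )
        assert res.statistic == pytest.approx(f_hand, rel=1e-12)
        assert res.df == (2, 4)

    def test_matches_pingouin(self):
        import pingouin as pg

        table = self._table(effect=[0, 0.4, 0.8, 0.2])
        res = rm_anova_oneway(table, force="ranova")
        aov = pg.rm_anova(data=table.to_long(), dv="value", within="time",
                          subject="subject", detailed=True)
        assert res.statistic == pytest.approx(aov.loc[0, "F"], rel=1e-9)
        assert res.p == pytest.approx(aov.loc[0, "p_unc"], rel=1e-9)

    def test_friedman_used_when_a_time_point_is_nonnormal(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((12, 3))
        x[:, 1] = np.repeat([0.0, 50.0], 6)  # grossly bimodal time point
        res = rm_anova_oneway(LongitudinalTable(x, list(range(12)), [1, 2, 3]))
        assert res.method == "friedman"

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(9)
        rej = 0
        n_rep = 400
        for _ in range(n_rep):
            x = rng.standard_normal((8, 4)) + rng.standard_normal((8, 1))
            res = rm_anova_oneway(
                LongitudinalTable(x, list(range(8)), list(range(4))),
                force="ranova",
            )
            rej += res.p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rej / n_rep - 0.05) <= 2.5 * se

    def test_incomplete_table_rejected_upstream(self):
        with pytest.raises(ValueError, match="missing"):
            LongitudinalTable(np.array([[1.0, np.nan]]), ["a"], [1, 2])


class TestRmAnovaTwoway:
    def test_identical_groups_give_null_group_effect(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((8, 4))
        t = LongitudinalTable(x, list(range(8)), [1, 2, 3, 4])
        t2 = LongitudinalTable(x.copy(), list(range(8)), [1, 2, 3, 4])
        res = rm_anova_twoway({"A": t, "B": t2})
        assert res["group"].statistic == pytest.approx(0.0, abs=1e-9)
        assert res["group"].p == pytest.approx(1.0, abs=1e-6)

    def test_constant_offset_gives_group_effect_without_interaction(self):
        rng = np.random.default_rng(11)
        base = rng.standard_normal((12, 4)) + 0.5 * rng.standard_normal((12, 1))
        t_a = LongitudinalTable(base, list(range(12)), [1, 2, 3, 4])
        t_b = LongitudinalTable(
            rng.standard_normal((12, 4)) + 0.5 * rng.standard_normal((12, 1)) + 3.0,
            list(range(12)), [1, 2, 3, 4],
        )
        res = rm_anova_twoway({"A": t_a, "B": t_b})
        assert res["group"].p < 0.001
        assert res["interaction"].p > 0.05

    def test_time_effect_agrees_with_oneway_on_pooled_copies(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal((10, 3)) + np.array([0.0, 0.6, 1.2])
        t1 = LongitudinalTable(x, [f"a{i}" for i in range(10)], [1, 2, 3])
        t2 = LongitudinalTable(x.copy(), [f"b{i}" for i in range(10)], [1, 2, 3])
        res2 = rm_anova_twoway({"A": t1, "B": t2})
        pooled = LongitudinalTable(
            np.vstack([x, x]), [f"s{i}" for i in range(20)], [1, 2, 3]
        )
        res1 = rm_anova_oneway(pooled, force="ranova")
        # identical copies: no interaction; the time effects share numerator
        # and error SS and differ only through the error df ((k-1)(N-2) in
        # the mixed design vs (k-1)(N-1) pooled)
        assert res2["interaction"].statistic == pytest.approx(0.0, abs=1e-9)
        df2_mixed = res2["time"].df[1]
        df2_pooled = res1.df[1]
        assert res2["time"].statistic == pytest.approx(
            res1.statistic * df2_mixed / df2_pooled, rel=1e-9
        )

    def test_single_group_is_error(self):
        t = LongitudinalTable(np.zeros((3, 2)), list("abc"), [1, 2])
        with pytest.raises(ValueError):
            rm_anova_twoway({"A": t})


class TestTukeyKramer:
    def test_diagonal_one_and_symmetric(self):
        rng = np.random.default_rng(13)
        t = LongitudinalTable(rng.standard_normal((8, 5)), list(range(8)),
                              list(range(5)))
        pm = tukey_kramer(t)
        a = pm.p.to_numpy()
        np.testing.assert_allclose(np.diag(a), 1.0)
        np.testing.assert_allclose(a, a.T)

    def test_two_time_points_reduce_to_paired_comparison(self):
        # with k=2 the studentized range on the RM error term equals the
        # paired t-test on the same error term (q = sqrt(2)|t|)
        rng = np.random.default_rng(14)
        x = rng.standard_normal((10, 2)) + np.array([0.0, 0.8])
        t = LongitudinalTable(x, list(range(10)), [1, 2])
        pm = tukey_kramer(t)
        tt = sps.ttest_rel(x[:, 0], x[:, 1])
        assert pm.p.iloc[0, 1] == pytest.approx(tt.pvalue, rel=1e-9)

    def test_familywise_error_controlled_under_null(self):
        rng = np.random.default_rng(15)
        n_rep, k = 400, 5
        fw = 0
        for _ in range(n_rep):
            x = rng.standard_normal((8, k)) + rng.standard_normal((8, 1))
            pm = tukey_kramer(
                LongitudinalTable(x, list(range(8)), list(range(k)))
            )
            a = pm.p.to_numpy()
            fw += (a[np.triu_indices(k, 1)] < 0.05).any()
        assert fw / n_rep <= 0.07

    def test_month1_drop_pattern_detected(self):
        # a 1-month level distinct from all later (stable) ages makes every
        # month-1 pair significant and no other pair
        rng = np.random.default_rng(16)
        level = np.array([8.0, 0, 0, 0, 0])
        x = rng.normal(0, 1.0, size=(20, 5)) + level + 2 * rng.standard_normal((20, 1))
        pm = tukey_kramer(LongitudinalTable(x, list(range(20)), [1, 2, 3, 4, 8]))
        a = pm.p.to_numpy()
        assert (a[0, 1:] < 0.001).all()
        off = a[np.triu_indices(5, 1)]
        assert (off < 0.05).sum() == 4  # only the four month-1 pairs

    def test_single_time_point_rejected(self):
        t = LongitudinalTable(np.zeros((4, 1)), list(range(4)), [1])
        with pytest.raises(ValueError):
            tukey_kramer(t)


def test_stars_thresholds():
    assert stars(0.2) == ""
    assert stars(0.04) == "*"
    assert stars(0.009) == "**"
    assert stars(0.0009) == "***"
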