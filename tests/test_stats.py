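import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from plinet.stats import (
    MatchingFailureError,
    ParticipantRecord,
    bonferroni,
    cem_match,
    chi_square_2x2,
    l1_imbalance,
    records_to_frame,
    required_sample_size,
    robust_regression,
    sturges_bins,
    two_sample_t,
    weighted_group_regression,
)


class TestTwoSampleT:
    def test_hand_worked_example(self):
        # pooled-variance oracle computed by hand:
        # a = [1,2,3], b = [4,5,6]: sp2 = 1, t = -3/sqrt(2/3), df = 4
        t, df, p = two_sample_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3 / np.sqrt(2 / 3))
        assert df == 4
        assert p == pytest.approx(2 * sps.t.cdf(t, 4))

    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 20)
        t, df, p = two_sample_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_one_lower_tail(self):
        a = [1.0, 1.1, 0.9, 1.2]
        b = [2.0, 2.1, 1.9, 2.2]
        t, df, p_one = two_sample_t(a, b, tail="one_lower")
        _, _, p_two = two_sample_t(a, b, tail="two")
        assert t < 0
        assert p_one == pytest.approx(p_two / 2)
        # the wrong-direction test is not significant
        _, _, p_rev = two_sample_t(b, a, tail="one_lower")
        assert p_rev > 0.9

    def test_identical_groups_t_zero(self):
        t, _, p = two_sample_t([1, 2, 3], [3, 2, 1])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_too_small_or_constant(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1, 2])
        with pytest.raises(ValueError, match="variance"):
            two_sample_t([1, 1, 1], [1, 1, 1])
        with pytest.raises(ValueError, match="tail"):
            two_sample_t([1, 2], [3, 4], tail="both")


class TestChiSquare:
    def test_cohort_sex_table(self):
        # 2x2 with marginal structure of a 14/6 vs 15/10 sex split
        chi2, p = chi_square_2x2([[14, 6], [15, 10]])
        ref_chi2, ref_p, _, _ = sps.chi2_contingency(
            [[14, 6], [15, 10]], correction=False
        )
        assert chi2 == pytest.approx(ref_chi2)
        assert p == pytest.approx(ref_p)
        assert chi2 == pytest.approx(0.49, abs=0.01)

    def test_independent_table_zero(self):
        chi2, p = chi_square_2x2([[10, 20], [20, 40]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_bad_tables(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            chi_square_2x2([[1, -1], [2, 3]])
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2([[0, 0], [2, 3]])


class TestSturgesBins:
    def test_bin_counts(self):
        # ceil(1 + log2 n): n=45 -> 7 bins, n=32 -> 6 bins
        assert len(sturges_bins(np.arange(45))) == 8
        assert len(sturges_bins(np.arange(32))) == 7

    def test_edges_span_range(self):
        edges = sturges_bins([2.0, 5.0, 11.0])
        assert edges[0] == 2.0 and edges[-1] == 11.0
        assert np.all(np.diff(edges) > 0)
        assert np.allclose(np.diff(edges), np.diff(edges)[0])

    def test_constant_sample(self):
        assert sturges_bins([3.0, 3.0]).tolist() == [3.0, 3.0]

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            sturges_bins([1.0, np.nan])
        with pytest.raises(ValueError):
            sturges_bins([])


class TestL1Imbalance:
    def test_identical_distributions_zero(self):
        v = [1.0, 2.0, 3.0, 4.0]
        assert l1_imbalance(v, v, [0, 2.5, 5]) == 0.0

    def test_disjoint_distributions_one(self):
        assert l1_imbalance([1, 1, 1], [4, 4], [0, 2.5, 5]) == 1.0

    def test_worked_example(self):
        # freq_a = (0.75, 0.25), freq_b = (0.25, 0.75) -> L1 = 0.5
        a = [1, 1, 1, 4]
        b = [1, 4, 4, 4]
        assert l1_imbalance(a, b, [0, 2.5, 5]) == pytest.approx(0.5)

    def test_weights_change_frequencies(self):
        a = [1, 4]
        b = [1, 4]
        assert l1_imbalance(a, b, [0, 2.5, 5], weights_a=[3, 1], weights_b=[1, 3]) == pytest.approx(0.5)

    def test_values_outside_bins_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            l1_imbalance([1, 10], [2, 3], [0, 2.5, 5])


def _cohort(n_a=20, n_b=25, shift=15.3, seed=0):
    rng = np.random.default_rng(seed)
    records = []
    for s in range(n_a + n_b):
        asd = s < n_a
        records.append(
            ParticipantRecord(
                subject_id=f"sub-{s:03d}",
                group="ASD-like" if asd else "TD-like",
                sex="M",
                age_months=72.0,
                mps=float(rng.normal(114.5 - (shift if asd else 0.0), 15.0)),
                ach=100.0,
                srs_t=float(rng.normal(69 if asd else 46, 8)),
                srs_awa=50.0,
                srs_cog=50.0,
                srs_com=50.0,
                srs_mot=50.0,
                srs_man=50.0,
                ados_sc=12.0 if asd else None,
                epoch_count=10,
            )
        )
    return records


class TestCemMatch:
    def test_weight_conventions(self):
        res = cem_match(_cohort())
        w = res.weights
        df = records_to_frame(_cohort())
        treated = df.set_index("subject_id")["group"] == "ASD-like"
        matched_t = w[treated & (w > 0)]
        assert np.all(matched_t == 1.0)
        # weighted control mass equals the matched control count
        assert w[~treated].sum() == pytest.approx(res.n_matched_control)
        assert res.n_matched_treated == int((w[treated] > 0).sum())

    def test_reduces_imbalance_on_shifted_cohorts(self):
        improved = 0
        for seed in range(25):
            res = cem_match(_cohort(seed=seed))
            assert res.l1_after <= res.l1_before + 1e-12
            improved += res.l1_after < res.l1_before
        assert improved == 25

    def test_within_stratum_frequencies_match(self):
        res = cem_match(_cohort(seed=1))
        df = records_to_frame(_cohort(seed=1)).set_index("subject_id")
        bins = sturges_bins(df["mps"].to_numpy())
        idx = np.clip(np.digitize(df["mps"], bins[1:-1]), 0, len(bins) - 2)
        for s in res.strata:
            in_s = df.index[idx == s]
            w_t = res.weights[in_s][df.loc[in_s, "group"] == "ASD-like"].sum()
            w_c = res.weights[in_s][df.loc[in_s, "group"] == "TD-like"].sum()
            # per-stratum weighted control mass proportional to treated mass
            assert w_c / res.n_matched_control == pytest.approx(
                w_t / res.n_matched_treated
            )

    def test_disjoint_groups_fail(self):
        records = _cohort(n_a=5, n_b=5, shift=0.0, seed=2)
        for r in records:
            r.mps = 50.0 if r.group == "ASD-like" else 150.0
        with pytest.raises(MatchingFailureError):
            cem_match(records, binning=np.array([0.0, 100.0, 200.0]))

    def test_missing_match_var_dropped(self):
        df = records_to_frame(_cohort(seed=3))
        df.loc[0, "mps"] = np.nan
        res = cem_match(df)
        assert df.loc[0, "subject_id"] not in res.weights.index


class TestRegressions:
    def test_wls_group_coefficient_is_weighted_mean_difference(self):
        rng = np.random.default_rng(4)
        g = np.repeat([0.0, 1.0], 20)
        y = 2.0 + 0.7 * g + rng.normal(0, 0.1, 40)
        w = rng.uniform(0.2, 2.0, 40)
        fit = weighted_group_regression(y, g, w)
        m1 = np.average(y[g == 1], weights=w[g == 1])
        m0 = np.average(y[g == 0], weights=w[g == 0])
        assert fit.coefficients["group"] == pytest.approx(m1 - m0)
        assert fit.weights_used

    def test_unit_weights_equal_ols(self):
        rng = np.random.default_rng(5)
        g = np.repeat([0.0, 1.0], 15)
        y = 1.0 - 0.4 * g + rng.normal(0, 0.3, 30)
        fit_w = weighted_group_regression(y, g, np.ones(30))
        fit_o = robust_regression(y, g, x_name="group")
        assert fit_w.coefficients["group"] == pytest.approx(
            fit_o.coefficients["group"]
        )

    def test_zero_weights_dropped(self):
        g = np.array([0, 0, 0, 1, 1, 1], float)
        y = np.array([1, 2, 3, 10, 11, 99], float)
        w = np.array([1, 1, 1, 1, 1, 0], float)
        fit = weighted_group_regression(y, g, w)
        assert fit.n_obs == 5
        assert fit.coefficients["group"] == pytest.approx(10.5 - 2.0)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ValueError):
            weighted_group_regression([1, 2, 3], [0, 0, 0], [1, 1, 1])
        with pytest.raises(ValueError):
            weighted_group_regression([1, 2, 3, 4], [0, 0, 1, 1], [1, 1, 0, 0])
        with pytest.raises(ValueError):
            robust_regression([1, 2, 3], [5, 5, 5])

    def test_robust_point_estimates_match_ols(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(40, 90, 50)
        y = 3.0 - 0.01 * x + rng.normal(0, 0.05, 50) * x / 40
        fit = robust_regression(y, x, x_name="srs")
        beta = np.polyfit(x, y, 1)[0]
        assert fit.coefficients["srs"] == pytest.approx(beta)
        assert fit.robust

    def test_hc1_widens_se_under_heteroscedasticity(self):
        # strong variance increase with x: HC1 SE should exceed classical SE
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        ratios = []
        for rep in range(30):
            x = np.linspace(0, 1, 200)
            y = x + rng.normal(0, 1e-3 + 3.0 * x**2, 200)
            robust_se = robust_regression(y, x).standard_errors["x"]
            classical = sm.OLS(y, sm.add_constant(pd.DataFrame({"x": x}))).fit()
            ratios.append(robust_se / classical.bse["x"])
        assert np.mean(ratios) > 1.1
        assert np.mean(np.array(ratios) > 1.0) > 0.9


class TestBonferroni:
    def test_strict_threshold(self):
        # alpha/m = 0.01 with m = 5: p exactly 0.01 is NOT significant
        out = bonferroni([0.009, 0.01, 0.011], m=5)
        assert out == [True, False, False]

    def test_default_m_is_family_size(self):
        assert bonferroni([0.02, 0.03]) == [True, False]  # threshold 0.025

    def test_m_smaller_than_family_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.01, 0.02, 0.03], m=2)


class TestRequiredSampleSize:
    def test_one_tailed_reference_value(self):
        assert required_sample_size(0.8, alpha=0.05, power=0.8, tail="one") == 21

    def test_two_tailed_reference_value(self):
        assert required_sample_size(0.8, alpha=0.05, power=0.8, tail="two") == 26

    def test_monotone_in_effect_size(self):
        ns = [required_sample_size(d) for d in (0.3, 0.5, 0.8, 1.2)]
        assert ns == sorted(ns, reverse=True)

    def test_returned_n_is_minimal(self):
        n = required_sample_size(0.5, tail="two")
        for m, expect in ((n, True), (n - 1, False)):
            df = 2 * m - 2
            crit = sps.t.isf(0.025, df)
            achieved = sps.nct.sf(crit, df, 0.5 * np.sqrt(m / 2))
            assert bool(achieved >= 0.8) == expect

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            required_sample_size(-0.2)
        with pytest.raises(ValueError):
            required_sample_size(0.8, alpha=1.2)
        with pytest.raises(ValueError):
            required_sample_size(0.8, tail="three")
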