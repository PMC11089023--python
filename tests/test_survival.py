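"""Survival machinery: KM, log-rank, Cox, time-dependent AUC, maxstat, calibration."""
import numpy as np
import pandas as pd
import pytest

from ecvrisk.survival import (
    SurvivalData,
    _standardized_logrank_grid,
    calibration_curve,
    fit_cox,
    horizon_classification_metrics,
    km_estimate,
    logrank_test,
    maxstat_cutpoint,
    time_dependent_auc,
    univariate_screen,
)
from ecvrisk.synthetic import WeibullBaseline, default_cohort_spec, generate_cohort


def brute_force_logrank(t1, e1, t2, e2):
    """O-E tabulation over risk sets, one event time at a time (oracle)."""
    t1, e1, t2, e2 = (np.asarray(a, dtype=float) for a in (t1, e1, t2, e2))
    times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    O = E = V = 0.0
    for u in times:
        n1 = np.sum(t1 >= u)
        n2 = np.sum(t2 >= u)
        d1 = np.sum((t1 == u) & (e1 == 1))
        d2 = np.sum((t2 == u) & (e2 == 1))
        n, d = n1 + n2, d1 + d2
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestKaplanMeier:
    def test_all_events_product_limit(self):
        km = km_estimate(SurvivalData([1.0, 2.0, 3.0], [1, 1, 1]))
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert km.median == 2.0

    def test_hand_computed_with_censoring(self):
        # subjects (1 event, 2 censored, 3 event): S(1)=2/3, S(3)=0
        km = km_estimate(SurvivalData([1.0, 2.0, 3.0], [1, 0, 1]))
        assert np.allclose(km.event_times, [1.0, 3.0])
        assert np.allclose(km.survival, [2 / 3, 0.0])

    def test_all_censored_flat_curve_median_not_reached(self):
        km = km_estimate(SurvivalData([1.0, 2.0, 3.0], [0, 0, 0]))
        assert not km.median_reached
        assert km.survival_at(2.5) == 1.0

    def test_no_censoring_equals_empirical_survivor_function(self, rng):
        t = rng.weibull(1.5, 300) * 8.0 + 1e-9
        km = km_estimate(SurvivalData(t, np.ones_like(t, dtype=int)))
        for u in km.event_times:
            assert km.survival_at(u) == pytest.approx(np.mean(t > u), abs=1e-12)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        d = SurvivalData([1.0, 2.0, 3.0], [1, 1, 1])
        chi2, p = logrank_test(d, d)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_example_matches_brute_force(self):
        t1, e1 = [1.0, 2.0, 3.0], [1, 1, 1]
        t2, e2 = [4.0, 5.0, 6.0], [1, 1, 1]
        chi2, _ = logrank_test(SurvivalData(t1, e1), SurvivalData(t2, e2))
        assert chi2 == pytest.approx(brute_force_logrank(t1, e1, t2, e2), rel=1e-9)

    def test_censored_example_matches_brute_force(self, rng):
        t1 = rng.exponential(5.0, 40) + 0.01
        t2 = rng.exponential(9.0, 40) + 0.01
        e1 = rng.integers(0, 2, 40)
        e2 = rng.integers(0, 2, 40)
        e1[0] = e2[0] = 1
        chi2, _ = logrank_test(SurvivalData(t1, e1), SurvivalData(t2, e2))
        assert chi2 == pytest.approx(brute_force_logrank(t1, e1, t2, e2), rel=1e-6)

    def test_label_swap_invariance(self, rng):
        a = SurvivalData(rng.exponential(5, 50) + 0.01, np.ones(50, dtype=int))
        b = SurvivalData(rng.exponential(8, 50) + 0.01, np.ones(50, dtype=int))
        assert logrank_test(a, b)[0] == pytest.approx(logrank_test(b, a)[0], rel=1e-12)

    def test_strong_effect_detected(self, rng):
        a = SurvivalData(rng.exponential(3.0, 500) + 1e-9, np.ones(500, dtype=int))
        b = SurvivalData(rng.exponential(9.0, 500) + 1e-9, np.ones(500, dtype=int))
        _, p = logrank_test(a, b)
        assert p < 0.001


class TestCox:
    def test_null_covariate_beta_near_zero(self, rng):
        n = 2000
        x = rng.integers(0, 2, n)
        t = rng.exponential(6.0, n) + 1e-9
        data = SurvivalData(t, np.ones(n, dtype=int), pd.DataFrame({"x": x}))
        fit = fit_cox(data)
        row = fit.summary.loc["x"]
        assert abs(row["beta"]) < 0.15
        assert row["ci_lower"] < 1.0 < row["ci_upper"]

    def test_true_hazard_ratio_two_recovered(self, rng):
        n = 5000
        x = rng.integers(0, 2, n)
        t = rng.exponential(1.0, n) / np.exp(np.log(2.0) * x) + 1e-9
        data = SurvivalData(t, np.ones(n, dtype=int), pd.DataFrame({"x": x}))
        assert fit_cox(data).hazard_ratios["x"] == pytest.approx(2.0, rel=0.08)

    def test_confidence_interval_coverage(self):
        """95 % CI covers a true HR of 2 in 93-97 % of 200 simulated cohorts."""
        beta = np.log(2.0)
        covered = 0
        for rep in range(200):
            r = np.random.default_rng(1000 + rep)
            x = r.integers(0, 2, 500)
            t = r.exponential(1.0, 500) / np.exp(beta * x) + 1e-9
            fit = fit_cox(SurvivalData(t, np.ones(500, dtype=int), pd.DataFrame({"x": x})))
            row = fit.summary.loc["x"]
            covered += row["ci_lower"] <= 2.0 <= row["ci_upper"]
        assert 0.93 <= covered / 200 <= 0.97

    def test_too_few_events_rejected(self):
        data = SurvivalData([1.0, 2.0], [1, 0], pd.DataFrame({"a": [0, 1], "b": [1, 0]}))
        with pytest.raises(ValueError, match="too few"):
            fit_cox(data)


class TestUnivariateScreen:
    def test_alpha_zero_retains_nothing(self, rng):
        n = 200
        df = pd.DataFrame({"x": rng.normal(size=n)})
        data = SurvivalData(rng.exponential(5, n) + 0.01, np.ones(n, dtype=int), df)
        retained, table, multi = univariate_screen(data, ["x"], alpha=0.0)
        assert retained == [] and multi is None
        assert "p" in table.columns

    def test_strong_covariate_retained(self, rng):
        n = 500
        x = rng.integers(0, 2, n)
        noise = rng.normal(size=n)
        t = rng.exponential(1.0, n) / np.exp(np.log(2.5) * x) + 1e-9
        data = SurvivalData(t, np.ones(n, dtype=int), pd.DataFrame({"x": x, "noise": noise}))
        retained, _, multi = univariate_screen(data, ["x", "noise"])
        assert "x" in retained
        assert multi is not None and "x" in multi.hazard_ratios

    def test_pure_noise_retention_near_alpha(self):
        """~5 % of null candidates pass the p < 0.05 screen on average."""
        r = np.random.default_rng(77)
        n, k = 800, 40
        t = r.exponential(5.0, n) + 1e-9
        df = pd.DataFrame({f"z{i}": r.normal(size=n) for i in range(k)})
        data = SurvivalData(t, np.ones(n, dtype=int), df)
        retained, _, _ = univariate_screen(data, list(df.columns))
        assert len(retained) <= 7  # Binomial(40, 0.05): P(>7) < 1e-3


class TestTimeDependentAUC:
    def test_perfectly_concordant_marker(self, rng):
        t = rng.exponential(6.0, 400) + 1e-9
        data = SurvivalData(t, np.ones(400, dtype=int))
        assert time_dependent_auc(-t, data, 6.0).auc == pytest.approx(1.0)

    def test_sign_flip_symmetry(self, rng):
        t = rng.exponential(6.0, 400) + 1e-9
        m = rng.normal(size=400)
        data = SurvivalData(t, np.ones(400, dtype=int))
        a = time_dependent_auc(m, data, 6.0).auc
        b = time_dependent_auc(-m, data, 6.0).auc
        assert a + b == pytest.approx(1.0, abs=1e-9)

    def test_independent_marker_near_half(self, rng):
        n = 2000
        t = rng.exponential(6.0, n) + 1e-9
        data = SurvivalData(t, np.ones(n, dtype=int))
        assert time_dependent_auc(rng.normal(size=n), data, 6.0).auc == pytest.approx(0.5, abs=0.03)

    def test_monotone_transform_invariance(self, rng):
        t = rng.exponential(6.0, 300) + 1e-9
        m = rng.normal(size=300)
        data = SurvivalData(t, np.ones(300, dtype=int))
        a = time_dependent_auc(m, data, 6.0).auc
        b = time_dependent_auc(np.exp(m / 3.0), data, 6.0).auc
        assert a == pytest.approx(b, abs=1e-9)

    def test_no_cases_before_horizon_rejected(self):
        data = SurvivalData([10.0, 12.0, 14.0], [1, 1, 1])
        with pytest.raises(ValueError, match="cases"):
            time_dependent_auc([1.0, 2.0, 3.0], data, 5.0)

    def test_matches_unweighted_auc_without_censoring(self, rng):
        """With no censoring the IPCW weights are 1 and the AUC reduces to the
        Mann-Whitney statistic of cases (T <= t) vs controls (T > t)."""
        from scipy.stats import mannwhitneyu

        n = 300
        t = rng.exponential(6.0, n) + 1e-9
        m = -t + rng.normal(0, 3.0, n)
        data = SurvivalData(t, np.ones(n, dtype=int))
        horizon = 6.0
        cases, controls = m[t <= horizon], m[t > horizon]
        u = mannwhitneyu(cases, controls, alternative="two-sided").statistic
        expected = u / (len(cases) * len(controls))
        assert time_dependent_auc(m, data, horizon).auc == pytest.approx(expected, abs=1e-9)


class TestMaxstat:
    @staticmethod
    def _changepoint_dataset(seed, n=300, hr=3.0):
        r = np.random.default_rng(seed)
        score = r.integers(0, 5, n).astype(float)
        lp = np.log(hr) * (score >= 2)
        t = r.exponential(8.0, n) * np.exp(-lp) + 1e-9
        return score, SurvivalData(t, np.ones(n, dtype=int))

    def test_known_changepoint_recovered(self):
        score, data = self._changepoint_dataset(seed=2)
        res = maxstat_cutpoint(score, data, n_perm=99, seed=0)
        assert res.cutpoint == 2.0
        assert res.p_value < 0.05

    def test_selected_statistic_is_maximal(self):
        score, data = self._changepoint_dataset(seed=3)
        res = maxstat_cutpoint(score, data, n_perm=0)
        assert res.statistic == res.statistics.max()
        assert res.statistic >= res.statistics.min()

    def test_constant_score_rejected(self):
        data = SurvivalData([1.0, 2.0, 3.0], [1, 1, 1])
        with pytest.raises(ValueError, match="constant"):
            maxstat_cutpoint([1.0, 1.0, 1.0], data, n_perm=0)

    def test_empty_quantile_window_rejected(self, rng):
        t = rng.exponential(5, 50) + 0.01
        data = SurvivalData(t, np.ones(50, dtype=int))
        score = np.r_[np.zeros(49), 1.0]  # only split leaves 98 % on one side
        with pytest.raises(ValueError, match="window"):
            maxstat_cutpoint(score, data, quantile_window=(0.4, 0.6), n_perm=0)

    def test_permutation_p_deterministic_given_seed(self):
        score, data = self._changepoint_dataset(seed=4, hr=1.2)
        a = maxstat_cutpoint(score, data, n_perm=99, seed=5)
        b = maxstat_cutpoint(score, data, n_perm=99, seed=5)
        assert a.p_value == b.p_value

    def test_grid_statistic_matches_lifelines_logrank(self, rng):
        t = rng.exponential(5.0, 80) + 0.01
        e = rng.integers(0, 2, 80)
        e[:5] = 1
        score = rng.normal(size=80)
        cut = float(np.median(score))
        z = _standardized_logrank_grid(t, e, (score > cut)[:, None])[0]
        grp = score > cut
        chi2, _ = logrank_test(
            SurvivalData(t[grp], e[grp]), SurvivalData(t[~grp], e[~grp])
        )
        assert z**2 == pytest.approx(chi2, rel=1e-9)


class TestCalibration:
    def test_uniform_prediction_single_bin_on_diagonal(self, rng):
        n = 200
        t = rng.exponential(8.0, n) + 1e-9
        data = SurvivalData(t, np.ones(n, dtype=int))
        marginal = float(km_estimate(data).survival_at(6.0))
        curve = calibration_curve(np.full(n, marginal), data, 6.0, n_boot=50, seed=1)
        assert len(curve) == 1
        assert curve.loc[0, "observed"] == pytest.approx(marginal, abs=1e-12)
        assert curve.loc[0, "mean_predicted"] == pytest.approx(marginal)

    def test_no_bootstrap_gives_point_estimates_only(self, rng):
        n = 120
        t = rng.exponential(8.0, n) + 1e-9
        data = SurvivalData(t, np.ones(n, dtype=int))
        curve = calibration_curve(rng.uniform(0, 1, n), data, 6.0, n_boot=0, seed=0)
        assert curve["ci_lower"].isna().all()

    def test_deterministic_given_seed(self, rng):
        n = 150
        t = rng.exponential(8.0, n) + 1e-9
        pred = rng.uniform(0, 1, n)
        data = SurvivalData(t, np.ones(n, dtype=int))
        a = calibration_curve(pred, data, 6.0, n_boot=40, seed=9)
        b = calibration_curve(pred, data, 6.0, n_boot=40, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_well_calibrated_model_tracks_diagonal(self):
        """True-model predictions put nearly all bins on the diagonal within CI."""
        inside = total = 0
        for rep in range(10):
            r = np.random.default_rng(300 + rep)
            n = 200
            lp = r.normal(0.0, 0.6, n)
            lam = np.exp(lp) / 8.0
            t = r.exponential(1.0, n) / lam + 1e-9
            pred = np.exp(-6.0 * lam)
            data = SurvivalData(t, np.ones(n, dtype=int))
            curve = calibration_curve(pred, data, 6.0, n_boot=80, n_bins=4, seed=rep)
            inside += int(
                ((curve["ci_lower"] <= curve["mean_predicted"]) & (curve["mean_predicted"] <= curve["ci_upper"])).sum()
            )
            total += len(curve)
        assert inside / total >= 0.85


class TestHorizonMetrics:
    def test_perfect_predictor_all_metrics_100(self, rng):
        n = 100
        t = rng.exponential(8.0, n) + 1e-9
        data = SurvivalData(t, np.ones(n, dtype=int))
        pred = (t > 6.0).astype(float)
        hm = horizon_classification_metrics(pred, 0.5, data, 6.0)
        for key in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            assert hm.metrics[key][0] == pytest.approx(100.0)

    def test_hand_computed_confusion_matrix(self):
        # TP=9, FN=3, FP=42, TN=49 -> sens 75.0 %, spec 53.8 %
        t = np.r_[np.full(12, 15.0), np.full(91, 5.0)]
        e = np.ones(103, dtype=int)
        pred = np.r_[np.ones(9), np.zeros(3), np.ones(42), np.zeros(49)]
        hm = horizon_classification_metrics(pred, 0.5, SurvivalData(t, e), 12.0)
        assert (hm.tp, hm.fn, hm.fp, hm.tn) == (9, 3, 42, 49)
        assert hm.metrics["sensitivity"][0] == pytest.approx(75.0, abs=0.05)
        assert hm.metrics["specificity"][0] == pytest.approx(53.8, abs=0.05)
        lo, hi = hm.metrics["sensitivity"][1:]
        assert lo < 75.0 < hi

    def test_zero_threshold_everything_predicted_positive(self, rng):
        n = 60
        t = rng.exponential(6.0, n) + 1e-9
        data = SurvivalData(t, np.ones(n, dtype=int))
        hm = horizon_classification_metrics(rng.uniform(0, 1, n), 0.0, data, 6.0)
        assert hm.fn == 0 and hm.tn == 0
        if hm.fp > 0:
            assert hm.metrics["specificity"][0] == 0.0
        assert hm.metrics["npv"] is None

    def test_censored_before_horizon_excluded(self):
        t = np.array([2.0, 4.0, 8.0, 9.0])
        e = np.array([0, 1, 0, 1])
        hm = horizon_classification_metrics(np.array([0.9, 0.1, 0.8, 0.7]), 0.5, SurvivalData(t, e), 6.0)
        assert hm.n_excluded == 1
        assert hm.tp + hm.fn + hm.fp + hm.tn == 3


class TestCohortIntegration:
    def test_published_coefficients_recovered_from_simulation(self):
        """Cohort simulated at the published multivariable log-hazards returns
        hazard ratios near (1.594, 0.941, 2.058, 1.612)."""
        df = generate_cohort(default_cohort_spec(5000, seed=42))
        data = SurvivalData.from_frame(
            df, covariate_cols=["ca199_nonresponse", "ecv_pct", "rim_enhancement", "fat_infiltration"]
        )
        hr = fit_cox(data).hazard_ratios
        assert hr["ca199_nonresponse"] == pytest.approx(1.594, rel=0.10)
        assert hr["ecv_pct"] == pytest.approx(0.941, rel=0.02)
        assert hr["rim_enhancement"] == pytest.approx(2.058, rel=0.10)
        assert hr["fat_infiltration"] == pytest.approx(1.612, rel=0.10)
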