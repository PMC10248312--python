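import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from riskcal import calibration as cal
from riskcal import synthetic_data as sd


def grid_search_fit(x, y, b0_range=(-8.0, 4.0), b1_range=(-0.6, 0.6), points=81, rounds=5):
    """Independent log-likelihood maximizer by nested grid refinement."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    b0_lo, b0_hi = b0_range
    b1_lo, b1_hi = b1_range
    best = (np.nan, np.nan)
    for _ in range(rounds):
        b0s = np.linspace(b0_lo, b0_hi, points)
        b1s = np.linspace(b1_lo, b1_hi, points)
        eta = b0s[:, None, None] + b1s[None, :, None] * x[None, None, :]
        ll = np.sum(y * eta - np.logaddexp(0.0, eta), axis=-1)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        best = (b0s[i], b1s[j])
        span0 = 3 * (b0s[1] - b0s[0])
        span1 = 3 * (b1s[1] - b1s[0])
        b0_lo, b0_hi = best[0] - span0, best[0] + span0
        b1_lo, b1_hi = best[1] - span1, best[1] + span1
    return best


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 22 + [0] * 361)
        fit = cal.fit_logistic(np.zeros_like(y, dtype=float), y)
        assert fit.b0 == pytest.approx(math.log(22 / 361), abs=1e-12)
        assert fit.b1 == 0.0

    def test_matches_grid_search_oracle(self):
        for seed in range(4):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 10, 50)
            y = (rng.random(50) < expit(-1.0 + 0.05 * x)).astype(int)
            if y.sum() in (0, 50):
                continue
            fit = cal.fit_logistic(x, y)
            g0, g1 = grid_search_fit(x, y)
            assert fit.b0 == pytest.approx(g0, abs=1e-4)
            assert fit.b1 == pytest.approx(g1, abs=1e-4)

    def test_recovers_generator_truth(self, spec):
        params = sd.default_params(n_subjects=10000, seed=21, follow_up_range=(6.0, 25.0))
        df = sd.cohort_to_frame(sd.generate_cohort(params, spec))
        fit = cal.fit_logistic(df.total_score.to_numpy(float), df.violent_event.to_numpy())
        # 5y events are a subset of the recorded flags; use the window instead
        from riskcal import cohort_stats as cs

        fw = cs.fixed_window_outcomes(df, "violent", 5.0)
        el = fw[fw.eligible]
        scores = df.set_index("subject_id").loc[el.subject_id, "total_score"].to_numpy(float)
        fit = cal.fit_logistic(scores, el.event.to_numpy())
        assert abs(fit.b0 - (-2.856)) < 3 * fit.se_b0
        assert abs(fit.b1 - 0.040) < 3 * fit.se_b1

    def test_separation_error(self):
        x = np.array([0, 1, 2, 3, 4, 10, 11, 12, 13, 14], float)
        y = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        with pytest.raises(cal.SeparationError):
            cal.fit_logistic(x, y)

    def test_small_n_error(self):
        with pytest.raises(cal.CalibrationError):
            cal.fit_logistic([1.0, 2.0, 3.0], [0, 1, 0])

    def test_wald_and_or_consistent(self, rng):
        x = rng.normal(0, 5, 500)
        y = (rng.random(500) < expit(-1 + 0.2 * x)).astype(int)
        fit = cal.fit_logistic(x, y)
        assert fit.odds_ratio == pytest.approx(math.exp(fit.b1))
        assert fit.wald == pytest.approx((fit.b1 / fit.se_b1) ** 2)
        assert fit.wald >= 0


class TestPredictRate:
    def test_symmetric_point(self):
        fit = cal.LogisticFit(0, 0, 1, 1, 0, 1, 1, (0, 0), True, 10, 5, -6.9, 1)
        assert cal.predict_rate(fit, 123.0) == pytest.approx(0.5)

    def test_printed_coefficients(self):
        fit = cal.LogisticFit(-2.856, 0.040, 0, 0, 0, 0, 1, (0, 0), True, 10, 5, 0, 1)
        assert cal.predict_rate(fit, 0) == pytest.approx(0.0544, abs=5e-4)

    def test_strictly_monotone_and_bounded(self):
        fit = cal.LogisticFit(-2.856, 0.040, 0, 0, 0, 0, 1, (0, 0), True, 10, 5, 0, 1)
        grid = np.arange(-34, 47)
        rates = cal.predict_rate(fit, grid)
        assert np.all(np.diff(rates) > 0)
        assert np.all((rates > 0) & (rates < 1))


class TestRecidivismCurve:
    def test_full_range_row_count(self):
        fit = cal.LogisticFit(-2.856, 0.040, 0, 0, 0, 0, 1, (0, 0), True, 10, 5, 0, 1)
        curve = cal.recidivism_curve(fit, (-34, 46))
        assert len(curve) == 81

    def test_matches_predict_pointwise(self):
        fit = cal.LogisticFit(-2.5, 0.03, 0, 0, 0, 0, 1, (0, 0), True, 10, 5, 0, 1)
        curve = cal.recidivism_curve(fit, (-5, 5))
        for _, row in curve.iterrows():
            assert row.rate == pytest.approx(cal.predict_rate(fit, row.score))

    def test_observed_scores_restriction(self):
        fit = cal.LogisticFit(-2.5, 0.03, 0, 0, 0, 0, 1, (0, 0), True, 10, 5, 0, 1)
        curve = cal.recidivism_curve(fit, scores=[3, 3, 7, -1])
        assert list(curve.score) == [-1.0, 3.0, 7.0]


class TestHosmerLemeshow:
    def test_zero_statistic_when_observed_equals_expected(self):
        probs, outcomes = [], []
        for k in range(1, 10):  # 9 groups of 10 with E = k exactly achieved
            probs.extend([k / 10] * 10)
            outcomes.extend([1] * k + [0] * (10 - k))
        res = cal.hosmer_lemeshow(probs, outcomes, n_groups=9)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 7
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_grouping_errors(self):
        with pytest.raises(cal.CalibrationError, match="degenerate"):
            cal.hosmer_lemeshow([0.3] * 20, [0, 1] * 10)

    def test_ties_share_groups(self):
        p = [0.1] * 15 + [0.5] * 15 + [0.9] * 10
        y = [0] * 15 + [1] * 15 + [1] * 10
        res = cal.hosmer_lemeshow(p, y, n_groups=10)
        assert len(res.groups) == 3
        assert res.groups.n.tolist() == [15, 15, 10]

    def test_permutation_invariance(self, rng):
        p = rng.uniform(0.05, 0.9, 200)
        y = (rng.random(200) < p).astype(int)
        base = cal.hosmer_lemeshow(p, y).statistic
        perm = rng.permutation(200)
        assert cal.hosmer_lemeshow(p[perm], y[perm]).statistic == pytest.approx(base)

    def test_well_specified_fit_usually_nonsignificant(self, spec):
        params = sd.default_params(n_subjects=3000, seed=22, follow_up_range=(6.0, 25.0))
        df = sd.cohort_to_frame(sd.generate_cohort(params, spec))
        fit = cal.fit_logistic(df.total_score.to_numpy(float), df.violent_event.to_numpy())
        probs = cal.predict_rate(fit, df.total_score.to_numpy(float))
        res = cal.hosmer_lemeshow(probs, df.violent_event.to_numpy())
        assert res.p_value > 0.05  # modal outcome for a well-specified model


class TestExpectedCounts:
    def test_printed_bin_nine(self):
        norms = cal.default_norms()
        assert cal.expected_counts(norms, {9: 27})[9] == pytest.approx(21.6)

    def test_printed_bin_six(self):
        norms = cal.default_norms()
        assert cal.expected_counts(norms, {6: 43})[6] == pytest.approx(15.91, abs=0.01)

    def test_zero_rate(self):
        norms = cal.NormsTable(rates={1: 0.0}, horizon=5.0)
        assert cal.expected_counts(norms, {1: 500})[1] == 0.0

    def test_missing_bin_errors(self):
        norms = cal.NormsTable(rates={1: 0.1}, horizon=5.0)
        with pytest.raises(cal.CalibrationError, match="no rate for bin"):
            cal.expected_counts(norms, {2: 10})


class TestEOIndex:
    def test_printed_bin_nine(self):
        res = cal.eo_index(21.6, 5)
        assert res.eo == pytest.approx(4.32)
        assert round(res.eo, 1) == 4.3

    def test_perfect_calibration_never_significant(self):
        res = cal.eo_index(13.0, 13)
        assert res.eo == pytest.approx(1.0)
        assert res.significant is False

    def test_ci_multiplier(self):
        res = cal.eo_index(101.4, 22)
        mult = math.exp(1.96 * math.sqrt(1 / 22))
        assert mult == pytest.approx(1.519, abs=1e-3)
        assert res.ci95[1] / res.eo == pytest.approx(mult)
        assert res.ci95[0] == pytest.approx(3.04, abs=0.01)

    def test_zero_observed_flagged(self):
        res = cal.eo_index(4.0, 0)
        assert res.eo is None and res.ci95 is None and res.significant is None
        assert res.expected == 4.0

    def test_scale_equivariance(self):
        a = cal.eo_index(10.0, 5)
        b = cal.eo_index(30.0, 15)
        assert a.eo == pytest.approx(b.eo)

    def test_ci_width_decreasing_in_observed(self):
        widths = []
        for o in (5, 20, 80):
            res = cal.eo_index(float(o), o)  # eo = 1 throughout
            widths.append(res.ci95[1] - res.ci95[0])
        assert widths[0] > widths[1] > widths[2]

    def test_ci_contains_point_estimate(self):
        for e, o in [(5.0, 2), (1.0, 10), (40.0, 9)]:
            res = cal.eo_index(e, o)
            assert res.ci95[0] <= res.eo <= res.ci95[1]


class TestCalibrationReport:
    def test_totals_are_sums(self, default_cohort_df):
        rep = cal.calibration_report(default_cohort_df, cal.default_norms(), "violent", 5.0)
        bins = rep[rep["bin"] != "total"]
        total = rep[rep["bin"] == "total"].iloc[0]
        assert total.expected == pytest.approx(bins.expected.sum())
        assert total.observed == bins.observed.sum()
        assert total.n == bins.n.sum()
        assert total.expected_rate == pytest.approx(total.expected / total.n)

    def test_zero_event_bins_kept_in_totals(self, spec):
        params = sd.default_params(n_subjects=150, seed=23, follow_up_range=(6.0, 10.0))
        df = sd.cohort_to_frame(sd.generate_cohort(params, spec))
        rep = cal.calibration_report(df, cal.default_norms(), "violent", 5.0)
        empty = rep[(rep["bin"] != "total") & (rep.observed == 0)]
        if not empty.empty:
            assert empty.eo.isna().all()
            total = rep[rep["bin"] == "total"].iloc[0]
            assert total.expected == pytest.approx(rep[rep["bin"] != "total"].expected.sum())

    def test_default_cohort_overprediction_direction(self, default_cohort_df):
        # printed norms against the lower-risk synthetic population: E/O > 1
        rep = cal.calibration_report(default_cohort_df, cal.default_norms(), "violent", 5.0)
        total = rep[rep["bin"] == "total"].iloc[0]
        assert total.eo > 1.0
        assert total.significant

    def test_missing_norm_bin_hard_error(self, default_cohort_df):
        norms = cal.NormsTable(rates={1: 0.1, 2: 0.2}, horizon=5.0)
        with pytest.raises(cal.CalibrationError, match="no rate for bin"):
            cal.calibration_report(default_cohort_df, norms, "violent", 5.0)

    def test_expected_override(self, default_cohort_df):
        rep0 = cal.calibration_report(default_cohort_df, cal.default_norms(), "violent", 5.0)
        rep1 = cal.calibration_report(
            default_cohort_df, cal.default_norms(), "violent", 5.0, expected_override={4: 6.7}
        )
        assert rep1[rep1["bin"] == 4].expected.iloc[0] == pytest.approx(6.7)
        assert rep1[rep1["bin"] == "total"].expected.iloc[0] != rep0[
            rep0["bin"] == "total"
        ].expected.iloc[0]


def test_norms_roundtrip(tmp_path):
    p = tmp_path / "norms.yaml"
    p.write_text("horizon: 5\noutcome: violent\nrates: {1: 0.08, 2: 0.09}\n")
    norms = cal.load_norms(p)
    assert norms.rate(1) == 0.08
    assert norms.horizon == 5.0


def test_norms_rate_validation():
    with pytest.raises(cal.CalibrationError):
        cal.NormsTable(rates={1: 1.5}, horizon=5.0)
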