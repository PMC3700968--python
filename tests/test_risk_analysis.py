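"""Risk statistics: running means, annual extremes, exceedance fractions,
bias correction, trends."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import frosthatch as fh
from frosthatch.risk_analysis import ThresholdSpec


def synthetic_daily(n_years=3, start="1978-07-01", cold_doy=200, amp=12.0):
    """A deterministic sinusoidal 10 cm series for statistic tests."""
    dates = pd.date_range(start, periods=n_years * 365, freq="D")
    t = 5.0 - amp * np.cos(2 * np.pi * (np.arange(len(dates)) - cold_doy) / 365.25)
    return pd.DataFrame({"date": dates, "t10cm_daily_mean": t})


class TestRunningMean:
    def test_simple_mean(self):
        out = fh.running_mean([1.0, 2.0, 3.0], 3)
        assert np.isnan(out[0]) and np.isnan(out[2])
        assert out[1] == pytest.approx(2.0)

    def test_constant_series(self):
        out = fh.running_mean(np.full(10, 4.2), 3)
        np.testing.assert_allclose(out[1:-1], 4.2)

    def test_smoothing_is_conservative(self):
        """A single -6 spike averages to -2: the running-mean minimum is
        warmer than the raw daily minimum."""
        out = fh.running_mean([0.0, -6.0, 0.0, 0.0], 3)
        np.testing.assert_allclose(out[1:3], [-2.0, -2.0])
        assert np.nanmin(out) > -6.0

    def test_window_validation(self):
        with pytest.raises(ValueError, match="odd"):
            fh.running_mean([1, 2, 3], 2)
        with pytest.raises(ValueError, match="exceeds"):
            fh.running_mean([1, 2], 5)


class TestAnnualExtremes:
    def test_complete_winter_year_count(self):
        # 3 calendar years contain exactly 2 complete Jul-Jun winters
        rec = fh.annual_extreme_minima(synthetic_daily(3, start="1978-01-01"))
        assert len(rec) == 2
        assert list(rec["winter_year_label"]) == [1979, 1980]

    def test_injected_cold_spell_dates_the_minimum(self):
        daily = synthetic_daily(3, start="1978-01-01")
        spell = pd.Timestamp("1979-01-20")
        mask = (daily["date"] >= spell) & (daily["date"] < spell + pd.Timedelta("5D"))
        daily.loc[mask, "t10cm_daily_mean"] -= 25.0
        rec = fh.annual_extreme_minima(daily)
        row = rec[rec["winter_year_label"] == 1979].iloc[0]
        assert abs((row["date_of_min"] - spell).days) <= 5

    def test_brute_force_recomputation(self, bare_run_3y):
        """Extreme records equal a brute-force loop over the raw daily file."""
        _, daily = bare_run_3y
        rec = fh.annual_extreme_minima(daily)
        t = daily["t10cm_daily_mean"].to_numpy()
        rm = np.full(t.size, np.nan)
        for i in range(1, t.size - 1):
            rm[i] = (t[i - 1] + t[i] + t[i + 1]) / 3.0
        dates = pd.DatetimeIndex(daily["date"])
        labels = np.where(dates.month >= 7, dates.year + 1, dates.year)
        for row in rec.itertuples():
            mask = labels == row.winter_year_label
            assert mask.sum() == 365
            expected = np.nanmin(rm[mask])
            assert row.extreme_min_t10 == pytest.approx(expected, abs=1e-12)

    def test_empty_input(self):
        out = fh.annual_extreme_minima(pd.DataFrame(columns=["date", "t10cm_daily_mean"]))
        assert len(out) == 0


class TestExceedance:
    def test_counting(self):
        rec = pd.DataFrame({"extreme_min_t10": [-4.0, -2.0, -5.0, -1.0]})
        assert fh.exceedance_frequency(rec, -3.5) == pytest.approx(0.5)

    def test_tie_counts_as_exceedance(self):
        rec = pd.DataFrame({"extreme_min_t10": [-3.5]})
        assert fh.exceedance_frequency(rec, ThresholdSpec("t", -3.5)) == 1.0

    def test_vacuous_threshold(self):
        rec = pd.DataFrame({"extreme_min_t10": [-4.0, -12.0]})
        assert fh.exceedance_frequency(rec, -100.0) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fh.exceedance_frequency(pd.DataFrame({"extreme_min_t10": []}), -3.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        vals=st.lists(st.floats(-15, 2), min_size=1, max_size=40),
        t1=st.floats(-10, 0),
        t2=st.floats(-10, 0),
    )
    def test_monotone_in_threshold(self, vals, t1, t2):
        rec = pd.DataFrame({"extreme_min_t10": vals})
        lo, hi = sorted([t1, t2])
        assert (fh.exceedance_frequency(rec, lo)
                <= fh.exceedance_frequency(rec, hi))


def records_with_mean(mean, n=5):
    return pd.DataFrame({"extreme_min_t10": np.full(n, mean)})


class TestResponseCurve:
    def test_ratio_arithmetic(self):
        sweep = {
            0.0: records_with_mean(-9.0),
            5.0: records_with_mean(-6.0),   # warming 3.0
            10.0: records_with_mean(-4.8),  # warming 4.2
            20.0: records_with_mean(-4.0),  # warming 5.0
        }
        rc = fh.response_curve(sweep).set_index("thickness_cm")
        assert rc.loc[5.0, "fraction_of_max"] == pytest.approx(0.60)
        assert rc.loc[10.0, "fraction_of_max"] == pytest.approx(0.84)
        assert rc.loc[20.0, "fraction_of_max"] == pytest.approx(1.0)

    def test_requires_bare_reference_and_two_members(self):
        with pytest.raises(ValueError, match="bare"):
            fh.response_curve({5.0: records_with_mean(-6.0),
                               10.0: records_with_mean(-5.0)})
        with pytest.raises(ValueError, match="two"):
            fh.response_curve({0.0: records_with_mean(-9.0),
                               5.0: records_with_mean(-6.0)})

    def test_zero_warming_reported_as_nan(self):
        sweep = {0.0: records_with_mean(-9.0), 5.0: records_with_mean(-9.0),
                 10.0: records_with_mean(-9.0)}
        rc = fh.response_curve(sweep)
        assert rc["fraction_of_max"].isna().all()


class TestBiasCorrection:
    def test_identity_fit(self):
        sim = np.linspace(-12, -2, 40)
        model = fh.fit_bias_correction(sim, sim)
        np.testing.assert_allclose(model.coefficients, (0.0, 1.0, 0.0), atol=1e-8)
        assert model.r_squared == pytest.approx(1.0)

    def test_exact_quadratic_recovery(self):
        sim = np.linspace(-12, -2, 40)
        obs = 0.02 * sim**2 + 1.15 * sim + 0.8
        model = fh.fit_bias_correction(sim, obs)
        np.testing.assert_allclose(model.coefficients, (0.02, 1.15, 0.8), atol=1e-6)
        np.testing.assert_allclose(fh.apply_bias_correction(model, sim), obs,
                                   atol=1e-6)

    def test_noisy_recovery_within_three_se(self):
        """Monte-Carlo over the pseudo-observation generator: recovered
        coefficients lie within 3 SE of the truth (replicate spread as the
        SE estimate)."""
        truth = (0.02, 1.15, 0.8)
        sim = np.linspace(-12, -2, 125)
        coefs = []
        for rep in range(200):
            obs = fh.make_pseudo_observations(sim, truth, 0.5, seed=1000 + rep)
            coefs.append(fh.fit_bias_correction(sim, obs).coefficients)
        coefs = np.array(coefs)
        se = coefs.std(axis=0, ddof=1) / np.sqrt(len(coefs))
        np.testing.assert_array_less(np.abs(coefs.mean(axis=0) - np.array(truth)),
                                     3 * se + 1e-12)

    def test_corrected_slope_near_unity(self):
        sim = np.linspace(-12, -2, 125)
        obs = fh.make_pseudo_observations(sim, (0.02, 1.15, 0.8), 0.4, seed=5)
        model = fh.fit_bias_correction(sim, obs)
        corrected = fh.apply_bias_correction(model, sim)
        slope = stats.linregress(corrected, obs).slope
        assert 0.9 <= slope <= 1.1

    def test_rank_order_preserved_across_sites(self):
        """Correction must not scramble cross-site ordering: rank
        correlation of corrected vs. raw simulated site means >= 0.95."""
        rng = np.random.default_rng(0)
        site_means = rng.uniform(-12, -2, 40)
        obs = fh.make_pseudo_observations(site_means, (0.02, 1.15, 0.8), 0.5, seed=9)
        model = fh.fit_bias_correction(site_means, obs)
        corrected = fh.apply_bias_correction(model, site_means)
        rho = stats.spearmanr(site_means, corrected).statistic
        assert rho >= 0.95

    def test_degenerate_sim_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fh.fit_bias_correction(np.full(10, -5.0), np.linspace(-6, -4, 10))

    def test_extrapolation_refused(self):
        sim = np.linspace(-10, -4, 20)
        model = fh.fit_bias_correction(sim, sim)
        with pytest.raises(ValueError, match="extrapolation"):
            fh.apply_bias_correction(model, np.array([-20.0]))


class TestLinearTrend:
    def test_exact_linear_data(self):
        years = np.arange(1978, 2008)
        vals = 0.05 * (years - 1978) - 7.0
        res = fh.linear_trend((years, vals))
        assert res.slope == pytest.approx(0.5)  # degC per decade
        assert res.p_value < 1e-12 and res.significant
        assert res.total_change == pytest.approx(0.05 * 29)

    def test_constant_series_not_significant(self):
        years = np.arange(1990, 2000)
        res = fh.linear_trend((years, np.full(10, -5.0)))
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert not res.significant

    def test_observed_scale_trend_recovery(self):
        """Monte-Carlo: a 0.88 degC/decade trend in 27-year noisy annual
        series is recovered within 3 SE of the replicate mean."""
        years = np.arange(1981, 2008)
        true_decadal = 0.88
        rng = np.random.default_rng(42)
        slopes = []
        for _ in range(500):
            vals = (true_decadal / 10.0) * (years - years[0]) - 8.0 \
                + rng.normal(0.0, 0.8, years.size)
            slopes.append(fh.linear_trend((years, vals)).slope)
        slopes = np.array(slopes)
        se = slopes.std(ddof=1) / np.sqrt(slopes.size)
        assert abs(slopes.mean() - true_decadal) < 3 * se

    def test_too_few_years_rejected(self):
        with pytest.raises(ValueError, match="3 years"):
            fh.linear_trend((np.array([2000, 2001]), np.array([1.0, 2.0])))


def test_risk_summary_schema(bare_run_3y):
    _, daily = bare_run_3y
    summary = fh.risk_summary(daily)
    assert summary["schema_version"] == 1
    assert summary["n_years"] == len(summary["annual_extremes"])
    assert set(summary["exceedance_fractions"]) == {"-3.5C", "-6C"}
    for v in summary["exceedance_fractions"].values():
        assert 0.0 <= v <= 1.0
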