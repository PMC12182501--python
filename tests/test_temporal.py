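import numpy as np
import pandas as pd
import pytest

from soilresp import (
    RespSeries,
    contribution_series,
    detrended_variability,
    seasonal_aggregate,
    seasonal_stats,
    trend,
)


def daily(values, start="2010-01-01"):
    idx = pd.date_range(start, periods=len(values), freq="D")
    return pd.Series(np.asarray(values, dtype=float), index=idx)


class TestSeasonalStats:
    def test_constant_series(self):
        s = daily(np.full(730, 2.5))
        st = seasonal_stats(s)
        assert st.amplitude == 0.0
        assert st.cv == 0.0

    def test_month_index_series(self):
        idx = pd.date_range("2010-01-01", "2010-12-31", freq="D")
        s = pd.Series(idx.month.to_numpy(dtype=float), index=idx)
        st = seasonal_stats(s)
        assert list(st.monthly_means) == list(range(1, 13))
        assert st.amplitude == 11.0

    def test_sinusoid_amplitude_within_binning_bias(self):
        idx = pd.date_range("2010-01-01", "2013-12-31", freq="D")
        doy = idx.dayofyear.to_numpy(dtype=float)
        A = 3.0
        s = pd.Series(10 + A * np.sin(2 * np.pi * (doy - 105) / 365), index=idx)
        st = seasonal_stats(s)
        assert st.amplitude == pytest.approx(2 * A, rel=0.02)

    def test_missing_month_raises(self):
        idx = pd.date_range("2010-01-01", "2010-10-31", freq="D")
        with pytest.raises(ValueError, match="months"):
            seasonal_stats(pd.Series(1.0, index=idx))

    def test_invariant_to_within_month_permutation(self):
        rng = np.random.default_rng(0)
        s = daily(rng.uniform(0, 2, 365))
        shuffled = s.copy()
        for m in range(1, 13):
            sel = s.index.month == m
            shuffled.loc[sel] = rng.permutation(s[sel].to_numpy())
        a, b = seasonal_stats(s), seasonal_stats(shuffled)
        pd.testing.assert_series_equal(a.monthly_means, b.monthly_means)


class TestSeasonalAggregate:
    def test_winter_indicator_series(self):
        idx = pd.date_range("2010-01-01", "2012-12-31", freq="D")
        vals = np.where(np.isin(idx.month, (12, 1, 2)), 1.0, 0.0)
        s = pd.Series(vals, index=idx)
        winter = seasonal_aggregate(s, "DJF")
        summer = seasonal_aggregate(s, "JJA")
        assert (winter == 1.0).all()
        assert (summer == 0.0).all()

    def test_december_belongs_to_next_years_winter(self):
        idx = pd.date_range("2010-12-01", "2011-02-28", freq="D")
        s = pd.Series(1.0, index=idx)
        winter = seasonal_aggregate(s, "DJF")
        assert list(winter.index) == [2011]

    def test_partial_first_winter_dropped_with_warning(self):
        # record starts in January: winter of the first year has no December
        idx = pd.date_range("2010-01-01", "2011-12-31", freq="D")
        s = pd.Series(1.0, index=idx)
        winter = seasonal_aggregate(s, "DJF", min_months=3)
        assert 2010 not in winter.index

    def test_21_year_record_gives_21_winters(self):
        idx = pd.date_range("2002-01-01", "2022-12-31", freq="D")
        s = pd.Series(1.0, index=idx)
        winter = seasonal_aggregate(s, "DJF")
        assert len(winter) == 21  # first winter partial (Jan+Feb only) but kept


class TestTrend:
    def test_exact_line(self):
        y = pd.Series(2.0 * np.arange(2002, 2012) + 3.0, index=range(2002, 2012))
        slope, p = trend(y)
        assert slope == pytest.approx(2.0, rel=1e-12)
        assert p < 1e-10

    def test_constant_series_has_zero_slope(self):
        y = pd.Series(5.0, index=range(2002, 2012))
        slope, _ = trend(y)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_needs_five_years(self):
        with pytest.raises(ValueError):
            trend(pd.Series([1.0, 2.0, 3.0], index=[2002, 2003, 2004]))


class TestDetrendedVariability:
    def test_perfect_line_has_zero_dsd(self):
        y = pd.Series(0.3 * np.arange(10) + 1.0, index=range(2002, 2012))
        dsd, _ = detrended_variability(y)
        assert dsd == pytest.approx(0.0, abs=1e-10)

    def test_hand_oracle_on_residual_pattern(self):
        # values = level 2 + residuals (-1, 1, -1, 1, 0); the oracle detrends
        # with an independent polyfit and takes the sample sd
        years = np.arange(2002, 2007)
        vals = 2.0 + np.array([-1.0, 1.0, -1.0, 1.0, 0.0])
        coef = np.polyfit(years, vals, 1)
        resid = vals - np.polyval(coef, years)
        expect_dsd = float(np.std(resid, ddof=1))
        expect_ncv = 100.0 * expect_dsd / vals.mean()
        dsd, ncv = detrended_variability(pd.Series(vals, index=years))
        assert dsd == pytest.approx(expect_dsd, rel=1e-10)
        assert ncv == pytest.approx(expect_ncv, rel=1e-10)

    def test_scaling_property(self):
        rng = np.random.default_rng(2)
        y = pd.Series(rng.uniform(1, 3, 12), index=range(2002, 2014))
        dsd1, ncv1 = detrended_variability(y)
        dsd2, ncv2 = detrended_variability(4.0 * y)
        assert dsd2 == pytest.approx(4.0 * dsd1, rel=1e-10)
        assert ncv2 == pytest.approx(ncv1, rel=1e-10)

    def test_trend_plus_residual_reconstructs_series(self):
        rng = np.random.default_rng(3)
        y = pd.Series(rng.uniform(1, 3, 10), index=np.arange(2002, 2012))
        x = y.index.to_numpy(dtype=float)
        from scipy.stats import linregress

        fit = linregress(x, y.to_numpy())
        recon = fit.intercept + fit.slope * x + (y.to_numpy() - fit.intercept - fit.slope * x)
        np.testing.assert_allclose(recon, y.to_numpy(), atol=1e-12)


class TestContributions:
    def test_fractions_sum_to_one(self):
        idx = pd.date_range("2010-01-01", "2012-12-31", freq="D")
        rng = np.random.default_rng(1)
        resp = RespSeries(
            pd.DataFrame(
                {"HR": rng.uniform(0.5, 2.0, len(idx)), "AR": rng.uniform(0.1, 1.5, len(idx))},
                index=idx,
            )
        )
        total = resp["hr_frac"] + resp["ar_frac"]
        np.testing.assert_allclose(total.dropna(), 1.0, atol=1e-12)

    def test_equal_components_show_no_seasonal_contrast(self):
        idx = pd.date_range("2010-01-01", "2013-12-31", freq="D")
        flux = 1.0 + 0.5 * np.sin(2 * np.pi * idx.dayofyear.to_numpy() / 365)
        resp = RespSeries(pd.DataFrame({"HR": flux, "AR": flux}, index=idx))
        table = contribution_series(resp)
        assert np.allclose(table["mean"], 0.5)
        jja = table[(table["fraction"] == "ar_frac") & (table["season"] == "JJA")]
        assert jja["p_summer_winter"].iloc[0] == pytest.approx(1.0)

    def test_stronger_ar_seasonality_raises_summer_ar_share(self):
        idx = pd.date_range("2010-01-01", "2014-12-31", freq="D")
        doy = idx.dayofyear.to_numpy(dtype=float)
        season = np.sin(2 * np.pi * (doy - 105) / 365)
        hr = 1.0 + 0.2 * season
        ar = 0.8 + 0.7 * season + 0.01  # much stronger seasonal swing
        resp = RespSeries(pd.DataFrame({"HR": hr, "AR": np.maximum(ar, 0.01)}, index=idx))
        table = contribution_series(resp)
        ar_rows = table[table["fraction"] == "ar_frac"].set_index("season")
        assert ar_rows.loc["JJA", "mean"] > ar_rows.loc["DJF", "mean"]
        assert ar_rows.loc["JJA", "p_summer_winter"] < 0.05

    def test_zero_sr_dates_excluded(self):
        idx = pd.date_range("2010-01-01", "2013-12-31", freq="D")
        hr = np.ones(len(idx))
        hr[5] = 0.0
        ar = np.ones(len(idx))
        ar[5] = 0.0
        resp = RespSeries(pd.DataFrame({"HR": hr, "AR": ar}, index=idx))
        assert np.isnan(resp["ar_frac"].iloc[5])
        table = contribution_series(resp)
        assert np.allclose(table["mean"], 0.5)
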