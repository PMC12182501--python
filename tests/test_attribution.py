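import numpy as np
import pandas as pd
import pytest

from soilresp import (
    ARParams,
    HRParams,
    SiteConfig,
    ar_closed_form,
    ar_partials,
    attribute_change,
    classify_enso_winters,
    driver_correlations,
    enso_composites,
    evaluate_hr,
    hr_partials,
)


def oni_series(djf_values, year=2011):
    """Monthly ONI covering one winter with the given (Dec, Jan, Feb) values."""
    months = [f"{year - 1}-12", f"{year}-01", f"{year}-02"]
    idx = pd.PeriodIndex(months, freq="M").to_timestamp()
    return pd.Series(djf_values, index=idx)


class TestAttribution:
    def test_linear_model_is_exactly_first_order(self):
        a = 0.7
        model = lambda T, M: a * T
        partials = lambda T, M: (a, 0.0)
        drivers = pd.DataFrame({"T": [10.0, 12.0, 9.0], "M": [30.0, 28.0, 35.0]},
                               index=[2002, 2003, 2004])
        res = attribute_change(model, partials, drivers, 2002)
        np.testing.assert_allclose(res.terms["M"], 0.0)
        np.testing.assert_allclose(res.residual, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.terms["T"], res.actual_change, atol=1e-12)
        assert res.relative_contributions["T"] == pytest.approx(100.0)

    def test_hr3_small_perturbations_nearly_first_order(self):
        p = HRParams("HR3", 0.11, 0.039, k_T=12.5, k_M=20.0)
        model = lambda T, M: evaluate_hr(p, 8.4, T, M)
        partials = lambda T, M: hr_partials(p, 8.4, T, M)
        T0, M0 = 18.0, 30.0
        drivers = pd.DataFrame(
            {"T": [T0, T0 * 1.01], "M": [M0, M0 * 1.01]}, index=[2002, 2003]
        )
        res = attribute_change(model, partials, drivers, 2002)
        rel = abs(res.residual[2003]) / abs(res.actual_change[2003])
        assert rel <= 0.05

    def test_residual_shrinks_quadratically(self):
        p = HRParams("HR3", 0.11, 0.039, k_T=12.5, k_M=20.0)
        model = lambda T, M: evaluate_hr(p, 8.4, T, M)
        partials = lambda T, M: hr_partials(p, 8.4, T, M)
        T0, M0 = 18.0, 30.0
        resid = {}
        for eps in (0.005, 0.01, 0.02):
            drivers = pd.DataFrame(
                {"T": [T0, T0 * (1 + eps)], "M": [M0, M0 * (1 + eps)]}, index=[0, 1]
            )
            res = attribute_change(model, partials, drivers, 0)
            resid[eps] = abs(res.residual[1])
        assert resid[0.01] / resid[0.005] == pytest.approx(4.0, rel=0.3)
        assert resid[0.02] / resid[0.01] == pytest.approx(4.0, rel=0.3)

    def test_single_active_driver_takes_full_contribution(self):
        site = SiteConfig("s", "ENF", SOC=8.4)
        arp = ARParams(2.0, 2.0)
        model = lambda T, FRB, GPP: ar_closed_form(site, arp, FRB * site.SLA / site.P_r_l, GPP, T)
        partials = lambda T, FRB, GPP: ar_partials(
            site, arp, FRB * site.SLA / site.P_r_l, GPP, T
        )
        drivers = pd.DataFrame(
            {"T": 15.0, "FRB": [0.30, 0.32, 0.35], "GPP": 6.0}, index=[2002, 2003, 2004]
        )
        res = attribute_change(model, partials, drivers, 2002)
        assert res.relative_contributions["FRB"] == pytest.approx(100.0)
        assert res.relative_contributions[["T", "GPP"]].sum() == pytest.approx(0.0)

    def test_missing_reference_year_raises(self):
        drivers = pd.DataFrame({"T": [1.0, 2.0]}, index=[2003, 2004])
        with pytest.raises(ValueError, match="reference"):
            attribute_change(lambda T: T, lambda T: (1.0,), drivers, 2002)


class TestDriverCorrelations:
    def test_identical_series_correlate_perfectly(self):
        y = pd.Series(np.arange(6, dtype=float) + 0.5, index=range(2002, 2008))
        out = driver_correlations({"HR": y}, {"T": y})
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_anticorrelated_construction(self):
        y = pd.Series(np.arange(8, dtype=float), index=range(2002, 2010))
        out = driver_correlations({"HR": y}, {"M": -2.0 * y + 1.0})
        assert out["r"].iloc[0] == pytest.approx(-1.0)

    def test_null_pairs_have_near_nominal_false_positive_rate(self):
        rng = np.random.default_rng(12345)
        hits, reps = 0, 200
        for _ in range(reps):
            a = pd.Series(rng.normal(size=15), index=range(15))
            b = pd.Series(rng.normal(size=15), index=range(15))
            out = driver_correlations({"y": a}, {"x": b})
            hits += out["p"].iloc[0] < 0.05
        assert 0.02 <= hits / reps <= 0.08

    def test_too_few_years_raises(self):
        y = pd.Series([1.0, 2.0], index=[2002, 2003])
        with pytest.raises(ValueError, match="paired years"):
            driver_correlations({"HR": y}, {"T": y})


class TestEnsoClassification:
    @pytest.mark.parametrize(
        "djf,expected",
        [((1.0, 1.2, 0.9), "El Niño"), ((-0.2, 0.1, 0.0), "neutral"),
         ((-0.6, -0.8, -0.5), "La Niña")],
    )
    def test_threshold_classification(self, djf, expected):
        labels = classify_enso_winters(oni_series(djf))
        assert labels[2011] == expected

    def test_winter_with_single_month_omitted(self):
        idx = pd.PeriodIndex(["2011-01"], freq="M").to_timestamp()
        labels = classify_enso_winters(pd.Series([1.5], index=idx))
        assert 2011 not in labels.index


class TestEnsoComposites:
    def test_flat_series_has_zero_relative_change(self):
        years = np.arange(2002, 2012)
        vals = pd.Series(1.0, index=years)
        labels = pd.Series("neutral", index=years)
        labels.iloc[:3] = "El Niño"
        per_year, per_class = enso_composites(vals, labels)
        np.testing.assert_allclose(per_year["relative_change_pct"], 0.0, atol=1e-10)

    def test_injected_el_nino_inflation_recovered_vs_neutral(self):
        years = np.arange(2002, 2023)
        labels = pd.Series("neutral", index=years)
        labels.iloc[::4] = "El Niño"
        vals = pd.Series(1.0, index=years)
        vals[labels == "El Niño"] *= 1.10
        _, per_class = enso_composites(vals, labels)
        row = per_class.set_index("label")
        assert row.loc["El Niño", "vs_neutral_pct"] == pytest.approx(10.0, abs=1e-8)
        # vs the all-year mean the effect is diluted by the inflated years
        n_el = (labels == "El Niño").sum()
        grand = (len(years) - n_el + 1.1 * n_el) / len(years)
        expected = 100.0 * (1.1 - grand) / grand
        assert row.loc["El Niño", "relative_change_pct"] == pytest.approx(expected, abs=1e-6)

    def test_invariant_to_added_linear_trend(self):
        years = np.arange(2002, 2023)
        rng = np.random.default_rng(9)
        vals = pd.Series(1.0 + rng.normal(0, 0.05, len(years)), index=years)
        labels = pd.Series("neutral", index=years)
        labels.iloc[::3] = "La Niña"
        _, a = enso_composites(vals, labels)
        _, b = enso_composites(vals + 0.07 * (years - years[0]), labels)
        np.testing.assert_allclose(
            a["anomaly"].to_numpy(), b["anomaly"].to_numpy(), atol=1e-8
        )

    def test_all_neutral_collapses_to_one_row(self):
        years = np.arange(2002, 2010)
        vals = pd.Series(np.linspace(1, 2, len(years)), index=years)
        labels = pd.Series("neutral", index=years)
        _, per_class = enso_composites(vals, labels)
        assert len(per_class) == 1
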