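"""Seasonal, interannual and contribution statistics of respiration series.

Aggregates simulated daily respiration to calendar-month climatologies,
meteorological-season (MAM/JJA/SON/DJF) per-year means, annual trends, and
detrended interannual variability:

* seasonal amplitude = max − min of the 12 climatological monthly means;
  C.V. = 100·sd/mean of those monthly means (percent);
* trend = OLS slope of per-year values on the year index with a two-sided
  t test;
* DSD = sample standard deviation of the residuals after removing the OLS
  linear trend; NCV = 100·DSD/mean of the original per-year values;
* the heterotrophic/autotrophic contribution fractions HR/SR and AR/SR,
  with a paired (by year) two-sided t test of summer vs winter means.

DJF winters are labelled by the January year: December 2010 belongs to
winter 2011.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RespSeries",
    "SeasonalStats",
    "InterannualStats",
    "SEASONS",
    "seasonal_stats",
    "seasonal_aggregate",
    "trend",
    "detrended_variability",
    "interannual_stats",
    "contribution_series",
]

SEASONS = {"MAM": (3, 4, 5), "JJA": (6, 7, 8), "SON": (9, 10, 11), "DJF": (12, 1, 2)}


class RespSeries:
    """Dated respiration components with derived totals and fractions.

    Wraps a DataFrame with DatetimeIndex and columns HR, AR (g C m⁻² day⁻¹);
    SR = HR + AR and the fractions hr_frac = HR/SR, ar_frac = AR/SR are
    derived on construction (fractions are NaN where SR = 0).
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if not isinstance(frame.index, pd.DatetimeIndex):
            raise TypeError("RespSeries requires a DatetimeIndex")
        for c in ("HR", "AR"):
            if c not in frame.columns:
                raise ValueError(f"missing column {c}")
            if (frame[c] < 0).any():
                raise ValueError(f"negative {c} flux")
        frame["SR"] = frame["HR"] + frame["AR"]
        with np.errstate(invalid="ignore", divide="ignore"):
            frame["hr_frac"] = np.where(frame["SR"] > 0, frame["HR"] / frame["SR"], np.nan)
            frame["ar_frac"] = np.where(frame["SR"] > 0, frame["AR"] / frame["SR"], np.nan)
        self.frame = frame.sort_index()

    def __len__(self) -> int:
        return len(self.frame)

    def __getitem__(self, col: str) -> pd.Series:
        return self.frame[col]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="date", float_format="%.6g")


@dataclass
class SeasonalStats:
    """Climatological monthly means with amplitude and C.V."""

    monthly_means: pd.Series  # indexed 1..12
    amplitude: float  # max - min of monthly means, series units
    cv: float  # 100·sd/mean of monthly means, percent


@dataclass
class InterannualStats:
    """Per-year means with trend and detrended variability."""

    annual_means: pd.Series  # indexed by year
    trend_slope: float
    trend_p: float
    DSD: float
    NCV: float


def seasonal_stats(series: pd.Series) -> SeasonalStats:
    """Calendar-month climatology of a dated series.

    Requires every calendar month to be represented at least once across
    the record (at least one full year of coverage).
    """
    if not isinstance(series.index, pd.DatetimeIndex):
        raise TypeError("series must have a DatetimeIndex")
    s = series.dropna()
    monthly = s.groupby(s.index.month).mean()
    missing = sorted(set(range(1, 13)) - set(monthly.index))
    if missing:
        raise ValueError(f"months with no data: {missing}")
    monthly = monthly.reindex(range(1, 13))
    amplitude = float(monthly.max() - monthly.min())
    mean = float(monthly.mean())
    sd = float(monthly.std(ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else 0.0 if sd == 0 else float("inf")
    return SeasonalStats(monthly_means=monthly, amplitude=amplitude, cv=cv)


def _season_year(idx: pd.DatetimeIndex, season: str) -> np.ndarray:
    # DJF is labelled by the January year
    years = idx.year.to_numpy()
    if season == "DJF":
        years = np.where(idx.month.to_numpy() == 12, years + 1, years)
    return years


def seasonal_aggregate(series: pd.Series, season: str, min_months: int = 2) -> pd.Series:
    """Per-year mean of a dated series over one meteorological season.

    Years covering fewer than ``min_months`` distinct months of the season
    are dropped with a warning (e.g. the first winter of a record, which has
    no preceding December).
    """
    if season not in SEASONS:
        raise ValueError(f"season must be one of {sorted(SEASONS)}")
    s = series.dropna()
    idx = s.index
    in_season = idx.month.isin(SEASONS[season])
    s = s[in_season]
    years = _season_year(s.index, season)
    df = pd.DataFrame({"value": s.to_numpy(), "year": years, "month": s.index.month})
    months_per_year = df.groupby("year")["month"].nunique()
    short = months_per_year[months_per_year < min_months].index.tolist()
    if short:
        warnings.warn(f"{season}: years {short} cover < {min_months} months, dropped",
                      stacklevel=2)
        df = df[~df["year"].isin(short)]
    out = df.groupby("year")["value"].mean()
    out.name = season
    return out


def trend(per_year: pd.Series) -> tuple[float, float]:
    """OLS trend of per-year values: (slope per year, two-sided p).

    The slope is in the series' native units per year; feed seasonal totals
    in g C m⁻² to obtain g C m⁻² year⁻². Requires at least 5 years.
    """
    y = per_year.dropna()
    if len(y) < 5:
        raise ValueError(f"need >= 5 years, got {len(y)}")
    res = stats.linregress(y.index.to_numpy(dtype=float), y.to_numpy(dtype=float))
    return float(res.slope), float(res.pvalue)


def detrended_variability(per_year: pd.Series) -> tuple[float, float]:
    """Detrended standard deviation (DSD) and normalized C.V. (NCV).

    Removes the OLS linear trend, takes the sample standard deviation
    (n − 1 denominator) of the residuals, and normalises by the mean of the
    original series: NCV = 100·DSD/mean (percent). Mean ≤ 0 raises.
    """
    y = per_year.dropna()
    if len(y) < 5:
        raise ValueError(f"need >= 5 years, got {len(y)}")
    x = y.index.to_numpy(dtype=float)
    vals = y.to_numpy(dtype=float)
    res = stats.linregress(x, vals)
    resid = vals - (res.intercept + res.slope * x)
    dsd = float(np.std(resid, ddof=1))
    mean = float(np.mean(vals))
    if mean <= 0:
        raise ValueError(f"NCV undefined for mean {mean} <= 0")
    return dsd, 100.0 * dsd / mean


def interannual_stats(per_year: pd.Series) -> InterannualStats:
    """Bundle trend and detrended variability for a per-year series."""
    slope, p = trend(per_year)
    dsd, ncv = detrended_variability(per_year)
    return InterannualStats(per_year, slope, p, dsd, ncv)


def contribution_series(resp: RespSeries) -> pd.DataFrame:
    """Seasonal HR/SR and AR/SR fraction summary with summer-winter test.

    Returns a tidy frame with one row per (fraction, season): the mean of
    per-year seasonal fraction means, the number of years, and — on the JJA
    and DJF rows — the two-sided paired t statistic/p-value comparing summer
    against winter across years paired by year. Dates with SR = 0 carry NaN
    fractions and are excluded.
    """
    rows = []
    per_season: dict[tuple[str, str], pd.Series] = {}
    for frac in ("hr_frac", "ar_frac"):
        for season in SEASONS:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                yearly = seasonal_aggregate(resp[frac], season)
            per_season[(frac, season)] = yearly
            rows.append(
                {"fraction": frac, "season": season,
                 "mean": float(yearly.mean()), "n_years": int(len(yearly))}
            )
    table = pd.DataFrame(rows)
    table["t_summer_winter"] = np.nan
    table["p_summer_winter"] = np.nan
    for frac in ("hr_frac", "ar_frac"):
        jja = per_season[(frac, "JJA")]
        djf = per_season[(frac, "DJF")]
        common = jja.index.intersection(djf.index)
        if len(common) >= 3:
            a, b = jja[common], djf[common]
            if np.allclose(a.to_numpy(), b.to_numpy()):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(a, b)
            sel = (table["fraction"] == frac) & table["season"].isin(["JJA", "DJF"])
            table.loc[sel, "t_summer_winter"] = float(t)
            table.loc[sel, "p_summer_winter"] = float(p)
    return table
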