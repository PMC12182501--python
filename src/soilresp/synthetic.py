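"""Synthetic forcing, ONI and observation generator with known-truth respiration.

Emulates the statistical structure of the subtropical-forest study setting:
seasonal sinusoidal soil temperature (summer-winter range 15-20 °C depending
on site archetype), weakly seasonal volumetric soil moisture, seasonal LAI
and GPP with optional multi-year greening trends, yearly AR(1) interannual
anomalies, ENSO-coupled winter temperature anomalies driven by a synthetic
Oceanic Niño Index, and biweekly chamber sampling with multiplicative
observation noise.

Three site archetypes mirror the study's calibration sites: an evergreen
broadleaf forest with high soil organic carbon (``EBF-N``, SOC
30.9 g kg⁻¹, seasonal soil-T range 18.1 °C) and two evergreen needleleaf
forests (``ENF-N``, SOC 22.7 g kg⁻¹, range 15.3 °C; ``ENF-S``, SOC
8.4 g kg⁻¹, range 20 °C), each carrying the site's heterotrophic-model
truth parameters (α, β).

Everything is seeded: identical scenario + seed gives identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ar import ARParams, SiteConfig, ar_closed_form
from .forcing import ForcingSeries, ObsSeries
from .hr import HRParams, evaluate_hr
from .temporal import RespSeries

__all__ = [
    "SiteScenario",
    "ARCHETYPES",
    "scenario_from_archetype",
    "generate_forcing",
    "generate_oni",
    "generate_truth",
    "sample_observations",
    "truth_models",
]

# Site archetypes: soil organic carbon and seasonal soil-temperature range
# follow the three calibration sites; seasonal means and the HR3 truth
# parameters (α, β, site order EBF-N / ENF-N / ENF-S) are the site-specific
# constants used for known-truth generation.
ARCHETYPES: dict[str, dict] = {
    "EBF-N": {"forest_type": "EBF", "SOC": 30.9, "T_mean": 17.0, "T_amplitude": 9.05,
              "alpha": 0.07, "beta": 0.0236},
    "ENF-N": {"forest_type": "ENF", "SOC": 22.7, "T_mean": 14.0, "T_amplitude": 7.65,
              "alpha": 0.03, "beta": 0.0594},
    "ENF-S": {"forest_type": "ENF", "SOC": 8.4, "T_mean": 18.0, "T_amplitude": 10.0,
              "alpha": 0.11, "beta": 0.039},
}


@dataclass(frozen=True)
class SiteScenario:
    """Full description of one synthetic site run.

    Seasonal cycles are sinusoids peaking in mid-July (phase day 105);
    interannual variability is a yearly AR(1) anomaly per driver with
    standard deviation ``anomaly_sd`` relative to the driver mean;
    ``enso_coupling`` adds °C of winter soil-temperature anomaly per °C of
    DJF ONI. ``lai_trend``/``gpp_trend`` are linear greening trends in
    driver units per year; GPP additionally co-varies with LAI and
    temperature deviations through a linear link.
    """

    archetype: str = "EBF-N"
    years: int = 21
    start_year: int = 2002
    seed: int = 20220101
    # soil temperature, °C
    T_mean: float = 17.0
    T_amplitude: float = 9.05
    # volumetric soil moisture, percent
    M_mean: float = 30.0
    M_amplitude: float = 8.0
    # leaf area index, m² m⁻²
    LAI_mean: float = 4.0
    LAI_amplitude: float = 1.0
    lai_trend: float = 0.0  # per year
    # gross primary productivity, g C m⁻² day⁻¹
    GPP_mean: float = 6.0
    GPP_amplitude: float = 4.0
    gpp_trend: float = 0.0  # per year
    gpp_lai_coef: float = 1.0  # g C m⁻² day⁻¹ per unit LAI deviation
    gpp_T_coef: float = 0.1  # g C m⁻² day⁻¹ per °C deviation
    # interannual structure
    anomaly_sd: float = 0.03  # relative to the driver mean
    anomaly_ar1: float = 0.4
    enso_coupling: float = 0.5  # °C soil-T per °C DJF ONI
    daily_noise: float = 0.01  # relative day-to-day white noise
    # observation process
    obs_interval_days: int = 14
    obs_noise_sd: float = 0.10  # relative, multiplicative
    # truth model constants
    SOC: float = 30.9
    forest_type: str = "EBF"
    alpha: float = 0.07
    beta: float = 0.0236
    delta: float = 2.0
    epsilon: float = 2.0

    def __post_init__(self) -> None:
        for name in ("T_amplitude", "M_amplitude", "LAI_amplitude", "GPP_amplitude",
                     "anomaly_sd", "obs_noise_sd", "daily_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.obs_interval_days < 1:
            raise ValueError("obs_interval_days must be >= 1")

    # deterministic seasonal maxima, used for the truth half-saturation constants
    @property
    def k_T(self) -> float:
        return (self.T_mean + self.T_amplitude) / 2.0

    @property
    def k_M(self) -> float:
        return (self.M_mean + self.M_amplitude) / 2.0


def scenario_from_archetype(name: str, **overrides) -> SiteScenario:
    """Build a scenario preloaded with one archetype's constants."""
    if name not in ARCHETYPES:
        raise KeyError(f"unknown archetype {name!r}; expected one of {sorted(ARCHETYPES)}")
    a = ARCHETYPES[name]
    base = dict(
        archetype=name,
        T_mean=a["T_mean"], T_amplitude=a["T_amplitude"],
        SOC=a["SOC"], forest_type=a["forest_type"],
        alpha=a["alpha"], beta=a["beta"],
    )
    base.update(overrides)
    return SiteScenario(**base)


def truth_models(scn: SiteScenario) -> tuple[SiteConfig, HRParams, ARParams]:
    """The site configuration and truth model parameters implied by a scenario."""
    site = SiteConfig(site_id=scn.archetype, forest_type=scn.forest_type, SOC=scn.SOC)
    hr = HRParams(variant="HR3", alpha=scn.alpha, beta=scn.beta,
                  k_T=scn.k_T, k_M=scn.k_M, provenance="truth")
    ar = ARParams(delta=scn.delta, epsilon=scn.epsilon, provenance="BPLUT")
    return site, hr, ar


_PHASE_DAY = 105.0  # sinusoid peaks near mid-July (day ~196)


def _seasonal(doy: np.ndarray, mean: float, amplitude: float) -> np.ndarray:
    return mean + amplitude * np.sin(2 * np.pi * (doy - _PHASE_DAY) / 365.0)


def _yearly_ar1(rng: np.random.Generator, n_years: int, sd: float, phi: float) -> np.ndarray:
    x = np.zeros(n_years)
    if sd == 0:
        return x
    innov_sd = sd * np.sqrt(max(1.0 - phi**2, 1e-12))
    x[0] = rng.normal(0.0, sd)
    for i in range(1, n_years):
        x[i] = phi * x[i - 1] + rng.normal(0.0, innov_sd)
    return x


def generate_oni(
    years: int, start_year: int, seed: int, phi: float = 0.9, sd: float = 0.7
) -> pd.Series:
    """Synthetic monthly ONI: 3-month running mean of an AR(1) oscillation.

    Covers December of ``start_year − 1`` through February after the last
    year so every study winter has a full DJF triple.
    """
    rng = np.random.default_rng(seed)
    months = pd.date_range(
        start=f"{start_year - 1}-10-01", end=f"{start_year + years - 1}-03-01", freq="MS"
    )
    innov_sd = sd * np.sqrt(max(1.0 - phi**2, 1e-12))
    raw = np.zeros(len(months))
    raw[0] = rng.normal(0.0, sd)
    for i in range(1, len(months)):
        raw[i] = phi * raw[i - 1] + rng.normal(0.0, innov_sd)
    smooth = pd.Series(raw, index=months).rolling(3, center=True, min_periods=1).mean()
    smooth.name = "oni"
    return smooth


def generate_forcing(
    scn: SiteScenario, oni: pd.Series | None = None
) -> tuple[ForcingSeries, pd.Series]:
    """Generate the daily driver series and the monthly ONI for a scenario.

    Each driver is seasonal mean + sinusoid + yearly AR(1) anomaly + daily
    white noise; soil temperature additionally carries an ENSO-coupled
    anomaly in DJF months (``enso_coupling`` × that winter's DJF-mean ONI).
    Moisture is clipped to [5, 60] %, LAI floored at 0.3 and GPP at 0. GPP
    co-varies with the LAI and temperature deviations from their pure
    seasonal cycles via the scenario's linear link.

    Returns (forcing, oni); a caller-supplied real ONI series replaces the
    synthetic one.
    """
    rng = np.random.default_rng(scn.seed)
    if oni is None:
        oni = generate_oni(scn.years, scn.start_year, seed=int(rng.integers(2**31)))
    dates = pd.date_range(
        start=f"{scn.start_year}-01-01", end=f"{scn.start_year + scn.years - 1}-12-31",
        freq="D",
    )
    doy = dates.dayofyear.to_numpy(dtype=float)
    year_idx = dates.year.to_numpy() - scn.start_year
    years_elapsed = year_idx.astype(float)

    anomalies = {
        name: _yearly_ar1(rng, scn.years, scn.anomaly_sd * abs(mean), scn.anomaly_ar1)
        for name, mean in (
            ("T", scn.T_mean), ("M", scn.M_mean), ("LAI", scn.LAI_mean), ("GPP", scn.GPP_mean),
        )
    }

    # winter soil-T anomaly from the DJF-mean ONI, labelled by the January year
    djf_oni = _djf_means(oni)
    winter_anom = np.zeros(len(dates))
    month = dates.month.to_numpy()
    winter_year = np.where(month == 12, dates.year.to_numpy() + 1, dates.year.to_numpy())
    in_djf = np.isin(month, (12, 1, 2))
    for wy, val in djf_oni.items():
        winter_anom[in_djf & (winter_year == wy)] = scn.enso_coupling * val

    def noise(mean: float) -> np.ndarray:
        if scn.daily_noise == 0:
            return np.zeros(len(dates))
        return rng.normal(0.0, scn.daily_noise * abs(mean), len(dates))

    T_seasonal = _seasonal(doy, scn.T_mean, scn.T_amplitude)
    T = T_seasonal + anomalies["T"][year_idx] + winter_anom + noise(scn.T_mean)

    M = _seasonal(doy, scn.M_mean, scn.M_amplitude) + anomalies["M"][year_idx] + noise(scn.M_mean)
    M = np.clip(M, 5.0, 60.0)

    LAI_seasonal = _seasonal(doy, scn.LAI_mean, scn.LAI_amplitude)
    LAI = (
        LAI_seasonal + scn.lai_trend * years_elapsed
        + anomalies["LAI"][year_idx] + noise(scn.LAI_mean)
    )
    LAI = np.maximum(LAI, 0.3)

    GPP_seasonal = _seasonal(doy, scn.GPP_mean, scn.GPP_amplitude)
    GPP = (
        GPP_seasonal + scn.gpp_trend * years_elapsed
        + scn.gpp_lai_coef * (LAI - LAI_seasonal)
        + scn.gpp_T_coef * (T - T_seasonal)
        + anomalies["GPP"][year_idx] + noise(scn.GPP_mean)
    )
    GPP = np.maximum(GPP, 0.0)

    frame = pd.DataFrame(
        {"soil_T": T, "soil_M": M, "LAI": LAI, "GPP": GPP}, index=dates
    )
    return ForcingSeries(frame, validate=False), oni


def _djf_means(oni: pd.Series) -> pd.Series:
    s = oni.dropna()
    sel = s[np.isin(s.index.month, (12, 1, 2))]
    wy = np.where(sel.index.month == 12, sel.index.year + 1, sel.index.year)
    return pd.Series(sel.to_numpy(), index=wy).groupby(level=0).mean()


def generate_truth(
    forcing: ForcingSeries,
    site: SiteConfig,
    hr: HRParams,
    ar: ARParams,
) -> RespSeries:
    """Pointwise known-truth respiration from the chosen HR and AR models."""
    T = forcing["soil_T"].to_numpy(dtype=float)
    M = forcing["soil_M"].to_numpy(dtype=float)
    LAI = forcing["LAI"].to_numpy(dtype=float)
    GPP = forcing["GPP"].to_numpy(dtype=float)
    HR = np.asarray(evaluate_hr(hr, site.SOC, T, M))
    AR = np.asarray(ar_closed_form(site, ar, LAI, GPP, T))
    return RespSeries(pd.DataFrame({"HR": HR, "AR": AR}, index=forcing.dates))


def sample_observations(
    truth: RespSeries,
    interval_days: int = 14,
    rel_noise_sd: float = 0.10,
    seed: int = 20220101,
) -> ObsSeries:
    """Chamber-style observations: subsample + multiplicative noise.

    Every ``interval_days``-th date of the truth series is observed;
    obs = truth·(1 + η), η ~ N(0, rel_noise_sd), truncated at zero. SR is
    formed as HR + AR after noising, so the HR ≤ SR consistency holds by
    construction.
    """
    if interval_days < 1:
        raise ValueError("interval_days must be >= 1")
    rng = np.random.default_rng(seed)
    sub = truth.frame.iloc[::interval_days]
    hr = sub["HR"].to_numpy(dtype=float)
    ar = sub["AR"].to_numpy(dtype=float)
    if rel_noise_sd > 0:
        hr = np.maximum(hr * (1.0 + rng.normal(0.0, rel_noise_sd, hr.size)), 0.0)
        ar = np.maximum(ar * (1.0 + rng.normal(0.0, rel_noise_sd, ar.size)), 0.0)
    frame = pd.DataFrame({"HR": hr, "AR": ar, "SR": hr + ar}, index=sub.index)
    return ObsSeries(frame)
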