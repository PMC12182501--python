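"""Reading, validation and alignment of forcing, observation and ONI series.

Forcing records carry the drivers the respiration models need — soil
temperature at 5 cm (°C), volumetric soil moisture at 5 cm (percent 0-100),
leaf area index (LAI, m² m⁻²), gross primary productivity (GPP,
g C m⁻² day⁻¹) and optionally precipitation (mm). Observation records carry
chamber fluxes (total soil respiration SR and/or its trenching-partitioned
components HR and AR, g C m⁻² day⁻¹).

Satellite-style drivers (land-surface temperature, surface soil moisture)
are converted to soil-level drivers via user-supplied linear maps; the
regression coefficients are site-specific configuration, not package
constants.

All containers are thin wrappers over pandas DataFrames indexed by calendar
date; aggregation elsewhere in the package is calendar-month based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ForcingSeries",
    "ObsSeries",
    "LinearDriverMap",
    "QCReport",
    "read_forcing",
    "read_observations",
    "read_oni",
    "qc_observations",
    "apply_driver_map",
    "interpolate_to_dates",
]

FORCING_FIELDS = ("soil_T", "soil_M", "LAI", "GPP")
OBS_FIELDS = ("SR", "HR", "AR")


@dataclass
class QCReport:
    """Record of rows rejected or flagged during validation."""

    n_input: int = 0
    n_kept: int = 0
    violations: list[str] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return self.n_input - self.n_kept

    def add(self, message: str) -> None:
        self.violations.append(message)


def _validate_forcing_frame(df: pd.DataFrame, report: QCReport | None = None) -> pd.DataFrame:
    """Drop rows violating forcing invariants; sort and deduplicate dates."""
    report = report if report is not None else QCReport()
    report.n_input = len(df)
    if not df.index.is_monotonic_increasing:
        warnings.warn("forcing dates not sorted; sorting ascending", stacklevel=3)
        df = df.sort_index()
    dup = df.index.duplicated(keep="first")
    if dup.any():
        for d in df.index[dup]:
            report.add(f"duplicate date {d.date()}: later record dropped")
        df = df[~dup]
    bad = pd.Series(False, index=df.index)
    checks = [
        ("soil_M", (df["soil_M"] < 0) | (df["soil_M"] > 100), "soil_M outside [0, 100]"),
        ("LAI", df["LAI"] < 0, "LAI < 0"),
        ("GPP", df["GPP"] < 0, "GPP < 0"),
    ]
    if "precip" in df.columns:
        checks.append(("precip", df["precip"] < 0, "precip < 0"))
    for col, mask, msg in checks:
        mask = mask.fillna(False)
        for d, v in df.loc[mask, col].items():
            report.add(f"{d.date()}: {msg} (value {v})")
        bad |= mask
    df = df[~bad]
    report.n_kept = len(df)
    return df


class ForcingSeries:
    """Dated driver records with validated invariants.

    Wraps a DataFrame with a DatetimeIndex and columns ``soil_T``,
    ``soil_M``, ``LAI``, ``GPP`` and optionally ``precip``. Construction
    validates: strictly increasing unique dates, soil_M in [0, 100],
    LAI ≥ 0, GPP ≥ 0. Violating rows are dropped and listed in ``qc``.
    """

    def __init__(self, frame: pd.DataFrame, qc: QCReport | None = None, validate: bool = True):
        frame = frame.copy()
        if not isinstance(frame.index, pd.DatetimeIndex):
            raise TypeError("ForcingSeries requires a DatetimeIndex")
        missing = [c for c in FORCING_FIELDS if c not in frame.columns]
        if missing:
            raise ValueError(f"missing forcing columns: {missing}")
        self.qc = qc if qc is not None else QCReport()
        self.frame = _validate_forcing_frame(frame, self.qc) if validate else frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.frame.index

    def __getitem__(self, col: str) -> pd.Series:
        return self.frame[col]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="date", float_format="%.6g")


class ObsSeries:
    """Dated chamber-flux observations (any of SR, HR, AR per record)."""

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if not isinstance(frame.index, pd.DatetimeIndex):
            raise TypeError("ObsSeries requires a DatetimeIndex")
        present = [c for c in OBS_FIELDS if c in frame.columns]
        if not present:
            raise ValueError(f"ObsSeries needs at least one of {OBS_FIELDS}")
        if not frame.index.is_monotonic_increasing:
            frame = frame.sort_index()
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.frame.index

    def __getitem__(self, col: str) -> pd.Series:
        return self.frame[col]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="date", float_format="%.6g")


@dataclass(frozen=True)
class LinearDriverMap:
    """Linear conversion from a source driver to a target driver.

    Used e.g. to map satellite land-surface temperature to 5 cm soil
    temperature via a site regression: target = slope·source + intercept.
    """

    slope: float
    intercept: float
    source_name: str = "source"
    target_name: str = "target"

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or not np.isfinite(self.intercept):
            raise ValueError("slope and intercept must be finite")

    def inverse(self) -> "LinearDriverMap":
        if self.slope == 0:
            raise ValueError("zero-slope map is not invertible")
        return LinearDriverMap(
            1.0 / self.slope, -self.intercept / self.slope,
            self.target_name, self.source_name,
        )


def apply_driver_map(series, m: LinearDriverMap):
    """Elementwise slope·x + intercept."""
    arr = np.asarray(series, dtype=float)
    out = m.slope * arr + m.intercept
    if isinstance(series, pd.Series):
        return pd.Series(out, index=series.index, name=m.target_name)
    return out if out.ndim else float(out)


def read_forcing(path, schema: dict[str, str] | None = None) -> ForcingSeries:
    """Read a delimited-text forcing file into a validated ForcingSeries.

    ``schema`` maps canonical names (``date``, ``soil_T``, ``soil_M``,
    ``LAI``, ``GPP``, ``precip``) to the file's column names; identity when
    omitted. Rows failing invariants are dropped and reported in the result's
    ``qc`` attribute with their dates.
    """
    schema = schema or {}
    df = pd.read_csv(path)
    rename = {v: k for k, v in schema.items()}
    df = df.rename(columns=rename)
    date_col = "date"
    if date_col not in df.columns:
        raise ValueError(f"missing 'date' column (schema: {schema})")
    missing = [c for c in FORCING_FIELDS if c not in df.columns]
    if missing:
        raise ValueError(f"missing forcing columns {missing} in {path}")
    try:
        df[date_col] = pd.to_datetime(df[date_col])
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable date in {path}: {exc}") from exc
    keep = [c for c in (*FORCING_FIELDS, "precip") if c in df.columns]
    return ForcingSeries(df.set_index(date_col)[keep])


def read_observations(path, schema: dict[str, str] | None = None) -> ObsSeries:
    """Read a delimited-text observation file (columns date + SR/HR/AR)."""
    schema = schema or {}
    df = pd.read_csv(path).rename(columns={v: k for k, v in schema.items()})
    if "date" not in df.columns:
        raise ValueError("missing 'date' column in observation file")
    df["date"] = pd.to_datetime(df["date"])
    keep = [c for c in OBS_FIELDS if c in df.columns]
    return ObsSeries(df.set_index("date")[keep])


def read_oni(path) -> pd.Series:
    """Read a monthly ONI file with columns (year-month, value).

    Returns a Series indexed by month-start timestamps, values in °C
    anomaly of the Niño-3.4 region (3-month running mean).
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("ONI file needs two columns: year-month, value")
    month_col, val_col = df.columns[:2]
    idx = pd.PeriodIndex(df[month_col].astype(str), freq="M").to_timestamp()
    return pd.Series(df[val_col].astype(float).values, index=idx, name="oni")


def qc_observations(obs: ObsSeries, rain_dates=()) -> tuple[ObsSeries, QCReport]:
    """Remove physically inconsistent and rain-affected observations.

    Drops records where HR exceeds SR (a trenching artifact: the partitioned
    component cannot exceed the total) and records collected on a rain date
    or the day immediately after. Idempotent; never adds records.
    """
    report = QCReport(n_input=len(obs))
    df = obs.frame
    bad = pd.Series(False, index=df.index)
    if "HR" in df.columns and "SR" in df.columns:
        viol = (df["HR"] > df["SR"]).fillna(False)
        for d in df.index[viol]:
            report.add(f"{d.date()}: HR > SR, removed")
        bad |= viol
    rain = {pd.Timestamp(d).normalize() for d in rain_dates}
    after = {d + pd.Timedelta(days=1) for d in rain}
    affected = rain | after
    if affected:
        on_rain = pd.Series([d.normalize() in affected for d in df.index], index=df.index)
        for d in df.index[on_rain & ~bad]:
            report.add(f"{d.date()}: on/after rainfall, removed")
        bad |= on_rain
    out = ObsSeries(df[~bad])
    report.n_kept = len(out)
    return out, report


def interpolate_to_dates(forcing: ForcingSeries, targets) -> ForcingSeries:
    """Linearly interpolate each driver to the target dates.

    Targets must lie within the forcing date span; extrapolation raises.
    Targets coinciding with source dates pass values through exactly.
    """
    targets = pd.DatetimeIndex(targets)
    src = forcing.frame
    lo, hi = src.index[0], src.index[-1]
    outside = (targets < lo) | (targets > hi)
    if outside.any():
        raise ValueError(
            f"targets outside forcing span [{lo.date()}, {hi.date()}]: "
            f"{[str(t.date()) for t in targets[outside]]}"
        )
    x = src.index.view("int64").astype(float)
    xt = targets.view("int64").astype(float)
    data = {c: np.interp(xt, x, src[c].to_numpy(dtype=float)) for c in src.columns}
    return ForcingSeries(pd.DataFrame(data, index=targets), validate=False)
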