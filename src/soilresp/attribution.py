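"""Driver attribution by first-order perturbation, correlations, and ENSO composites.

Interannual changes in modelled respiration relative to a reference year are
decomposed into driver contributions by a first-order (linear perturbation)
Taylor expansion: for each driver x_i, term_i(year) = ∂f/∂x_i |_ref ·
(x_i(year) − x_i(ref)), with the partials evaluated at the reference-year
driver state. The relative contribution of driver i is
100·mean_y|term_i(y)| / Σ_j mean_y|term_j(y)| and the first-order residual
(actual change minus the sum of terms) measures how nonlinear the response
was over the observed driver range.

ENSO winters are classified from the Oceanic Niño Index (ONI): a DJF-mean
ONI ≥ +0.5 °C marks El Niño, ≤ −0.5 °C La Niña, otherwise neutral
(thresholds configurable). Winter respiration composites per class are
formed on the linearly detrended series (grand mean added back) and
reported as relative changes against the detrended all-year mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AttributionResult",
    "attribute_change",
    "driver_correlations",
    "classify_enso_winters",
    "enso_composites",
]


@dataclass
class AttributionResult:
    """Per-year first-order decomposition of change relative to a reference year.

    ``terms`` has one column per driver (the Taylor terms, flux units) and
    one row per year; ``actual_change`` is the direct model difference;
    ``residual`` = actual − Σ terms; ``relative_contributions`` are percent
    shares per driver summing to 100.
    """

    reference_year: int
    terms: pd.DataFrame
    actual_change: pd.Series
    residual: pd.Series
    relative_contributions: pd.Series

    def __post_init__(self) -> None:
        total = float(self.relative_contributions.sum())
        if self.relative_contributions.notna().all() and abs(total - 100.0) > 0.1:
            raise ValueError(f"relative contributions sum to {total}, not 100")


def attribute_change(
    model: Callable[..., float],
    partials: Callable[..., Sequence[float]],
    drivers: pd.DataFrame,
    reference_year: int,
    contribution_method: Literal["mean_abs", "endpoint"] = "mean_abs",
) -> AttributionResult:
    """First-order attribution of per-year model change to its drivers.

    Parameters
    ----------
    model
        Callable taking the driver values (in ``drivers`` column order) and
        returning the modelled flux.
    partials
        Callable taking the same driver values and returning one partial
        derivative per driver, evaluated at that state.
    drivers
        One row per year (index = year), one column per driver, holding
        annual-mean driver states.
    reference_year
        Year whose driver state anchors the expansion; must be in the index.
    contribution_method
        ``"mean_abs"`` (default): share of mean |term| across years.
        ``"endpoint"``: share of |term| in the final year only.
    """
    if reference_year not in drivers.index:
        raise ValueError(f"reference year {reference_year} not in drivers")
    drivers = drivers.sort_index()
    if drivers.isna().any().any():
        missing = drivers.index[drivers.isna().any(axis=1)].tolist()
        raise ValueError(f"missing driver values for years {missing}")
    ref_state = drivers.loc[reference_year].to_numpy(dtype=float)
    grads = np.asarray(partials(*ref_state), dtype=float)
    if grads.size != drivers.shape[1]:
        raise ValueError("partials must return one derivative per driver column")
    deltas = drivers.to_numpy(dtype=float) - ref_state
    terms = pd.DataFrame(deltas * grads, index=drivers.index, columns=drivers.columns)
    f_ref = float(model(*ref_state))
    actual = pd.Series(
        [float(model(*row)) - f_ref for row in drivers.to_numpy(dtype=float)],
        index=drivers.index, name="actual_change",
    )
    residual = actual - terms.sum(axis=1)
    residual.name = "residual"
    others = terms.drop(index=reference_year)
    if contribution_method == "mean_abs":
        weights = others.abs().mean(axis=0)
    elif contribution_method == "endpoint":
        weights = others.iloc[-1].abs()
    else:
        raise ValueError(f"unknown contribution_method {contribution_method!r}")
    total = float(weights.sum())
    if total > 0:
        contrib = 100.0 * weights / total
    else:
        contrib = pd.Series(np.nan, index=weights.index)
    contrib.name = "relative_contribution_pct"
    return AttributionResult(
        reference_year=reference_year,
        terms=terms,
        actual_change=actual,
        residual=residual,
        relative_contributions=contrib,
    )


def driver_correlations(
    responses: dict[str, pd.Series],
    drivers: dict[str, pd.Series],
    min_n: int = 5,
) -> pd.DataFrame:
    """Pearson correlations between per-year responses and drivers.

    Each series is indexed by year; pairs are matched on common years.
    Returns a tidy frame (response, driver, r, p, n). p-values carry no
    multiplicity correction; the ``multiplicity_correction`` attribute of
    the returned frame records that.
    """
    rows = []
    for rname, r in responses.items():
        for dname, d in drivers.items():
            common = r.dropna().index.intersection(d.dropna().index)
            if len(common) < min_n:
                raise ValueError(
                    f"({rname}, {dname}): only {len(common)} paired years, need {min_n}"
                )
            rr, pp = stats.pearsonr(r[common], d[common])
            rows.append({"response": rname, "driver": dname,
                         "r": float(rr), "p": float(pp), "n": int(len(common))})
    out = pd.DataFrame(rows)
    out.attrs["multiplicity_correction"] = "none"
    return out


def classify_enso_winters(
    oni: pd.Series,
    threshold: float = 0.5,
    min_months: int = 2,
) -> pd.Series:
    """Classify each winter from monthly ONI values.

    Winters (DJF, labelled by the January year) with a DJF-mean ONI at or
    above ``+threshold`` are El Niño, at or below ``−threshold`` La Niña,
    otherwise neutral. Winters with fewer than ``min_months`` of the three
    DJF months present are omitted.
    """
    if not isinstance(oni.index, pd.DatetimeIndex):
        raise TypeError("ONI series must be indexed by month timestamps")
    s = oni.dropna()
    months = s.index.month
    djf = s[np.isin(months, (12, 1, 2))]
    years = np.where(djf.index.month == 12, djf.index.year + 1, djf.index.year)
    df = pd.DataFrame({"oni": djf.to_numpy(), "year": years, "month": djf.index.month})
    grouped = df.groupby("year")
    counts = grouped["month"].nunique()
    means = grouped["oni"].mean()[counts >= min_months]
    labels = pd.Series("neutral", index=means.index, name="enso")
    labels[means >= threshold] = "El Niño"
    labels[means <= -threshold] = "La Niña"
    return labels


def enso_composites(
    winter_values: pd.Series,
    labels: pd.Series,
    min_class_n: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Composite detrended winter respiration by ENSO class.

    The winter series is linearly detrended (OLS on year) and the grand
    mean added back, making composites insensitive to any secular trend.
    Returns:

    * ``per_year``: year, label, detrended value, and relative change (%)
      against the detrended all-year mean;
    * ``per_class``: class composite mean, its anomaly (composite minus the
      all-year detrended mean — the quantity invariant to any linear trend
      in the input), n, a low-n flag, the composite relative change vs the
      all-year detrended mean, and the relative change vs the neutral-class
      mean (NaN when no neutral winters).
    """
    y = winter_values.dropna()
    common = y.index.intersection(labels.index)
    y = y[common]
    lab = labels[common]
    if len(y) < 3:
        raise ValueError("need at least 3 labelled winters")
    x = y.index.to_numpy(dtype=float)
    vals = y.to_numpy(dtype=float)
    fit = stats.linregress(x, vals)
    detr = vals - (fit.intercept + fit.slope * x) + float(np.mean(vals))
    grand = float(np.mean(detr))
    rel = 100.0 * (detr - grand) / grand if grand != 0 else np.full_like(detr, np.nan)
    per_year = pd.DataFrame(
        {"label": lab.to_numpy(), "detrended": detr, "relative_change_pct": rel},
        index=y.index,
    )
    rows = []
    class_means = per_year.groupby("label")["detrended"].mean()
    neutral_mean = class_means.get("neutral", np.nan)
    for cls, grp in per_year.groupby("label"):
        m = float(grp["detrended"].mean())
        rows.append(
            {
                "label": cls,
                "n": int(len(grp)),
                "low_n": len(grp) < min_class_n,
                "composite_mean": m,
                "anomaly": m - grand,
                "relative_change_pct": float(grp["relative_change_pct"].mean()),
                "vs_neutral_pct": (
                    100.0 * (m - neutral_mean) / neutral_mean
                    if np.isfinite(neutral_mean) and neutral_mean != 0 else np.nan
                ),
            }
        )
    return per_year, pd.DataFrame(rows)
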