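"""Model evaluation statistics and AIC-based selection.

Candidate respiration models are compared on four statistics computed from
paired (observed, modelled) flux series — the coefficient of determination
of the regression through the origin with its significance, root mean
squared error (RMSE), normalized standard deviation (NSD = sd(model)/
sd(observation)) and the Akaike information criterion
AIC = 2k + n·ln(RSS/n) — plus a seasonality criterion, the slope of the
ordinary regression of observed on modelled rates (1 is ideal).

Ranking is by mean AIC across sites, tie-broken by mean RMSE and then by
mean |slope − 1|; the slope/NSD criteria are also exposed separately, since
a model with slightly worse AIC may still be preferred for seasonality.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FitReport", "aic", "evaluation_stats", "select_model"]


@dataclass
class FitReport:
    """Evaluation statistics for one (site, model) pairing."""

    r2_origin: float
    p_value: float
    slope: float
    RMSE: float
    NSD: float
    AIC: float
    n: int
    k: int

    def __post_init__(self) -> None:
        if self.RMSE < 0:
            raise ValueError("RMSE must be >= 0")


def aic(n: int, k: int, RSS: float) -> float:
    """Akaike information criterion, AIC = 2k + n·ln(RSS/n).

    ``RSS = 0`` (a perfect fit) returns −inf with a warning rather than
    raising, so degenerate noise-free fits still rank first.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if RSS < 0:
        raise ValueError("RSS must be >= 0")
    if RSS == 0:
        warnings.warn("RSS = 0: AIC is -inf (perfect fit)", stacklevel=2)
        return -math.inf
    return 2 * k + n * math.log(RSS / n)


def evaluation_stats(obs, mod, k: int = 0) -> FitReport:
    """Compute the evaluation statistics for paired observed/modelled fluxes.

    The origin regression fits obs ≈ b·mod with b = Σxy/Σx²; its uncentred
    R² = 1 − Σ(y − b·x)²/Σy², tested against the zero model with an F test
    on (1, n−1) degrees of freedom. ``slope`` is from the ordinary
    (intercept-included) regression of observed on modelled rates.
    RMSE = √(Σ(y−x)²/n); NSD = sd(mod)/sd(obs), sample standard deviations.
    """
    y = np.asarray(obs, dtype=float)
    x = np.asarray(mod, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("obs and mod must be 1-D of equal length")
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 paired values")
    sd_y = float(np.std(y, ddof=1))
    if sd_y == 0:
        raise ValueError("constant observations: NSD undefined")
    sxx = float(np.sum(x * x))
    b = float(np.sum(x * y)) / sxx if sxx > 0 else 0.0
    ss_res = float(np.sum((y - b * x) ** 2))
    ss_tot = float(np.sum(y * y))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if ss_res <= 0:
        p = 0.0
    else:
        f = (ss_tot - ss_res) / (ss_res / (n - 1))
        p = float(stats.f.sf(f, 1, n - 1))
    slope = float(stats.linregress(x, y).slope)
    rmse = float(np.sqrt(np.mean((y - x) ** 2)))
    nsd = float(np.std(x, ddof=1)) / sd_y
    rss = float(np.sum((y - x) ** 2))
    return FitReport(
        r2_origin=r2, p_value=p, slope=slope, RMSE=rmse, NSD=nsd,
        AIC=aic(n, k, rss), n=n, k=k,
    )


def select_model(
    candidates: dict[str, list[tuple[float, FitReport]]] | dict[str, list[FitReport]],
) -> tuple[pd.DataFrame, str]:
    """Rank candidate models across sites and pick the best.

    Parameters
    ----------
    candidates
        Mapping model name → list of per-site FitReports (optionally
        (weight, report) pairs; weights are ignored, reports averaged).

    Returns
    -------
    (table, chosen): a comparison DataFrame with one row per model carrying
    mean AIC, RMSE, |slope − 1|, NSD and R² across sites, sorted by the
    selection order AIC → RMSE → |slope − 1|; and the winning model name.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate models")
    rows = []
    for name, reports in candidates.items():
        reps = [r[1] if isinstance(r, tuple) else r for r in reports]
        if not reps:
            raise ValueError(f"candidate {name!r} has no site reports")
        rows.append(
            {
                "model": name,
                "n_sites": len(reps),
                "mean_AIC": float(np.mean([r.AIC for r in reps])),
                "mean_RMSE": float(np.mean([r.RMSE for r in reps])),
                "mean_abs_slope_err": float(np.mean([abs(r.slope - 1) for r in reps])),
                "mean_NSD": float(np.mean([r.NSD for r in reps])),
                "mean_r2_origin": float(np.mean([r.r2_origin for r in reps])),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["mean_AIC", "mean_RMSE", "mean_abs_slope_err"], kind="mergesort"
    )
    table = table.reset_index(drop=True)
    return table, str(table.loc[0, "model"])
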