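"""Heterotrophic respiration (HR) model formulations.

Three process-based formulations of soil heterotrophic respiration as a
function of soil organic carbon (SOC), soil temperature T at 5 cm (°C) and
volumetric soil moisture M at 5 cm (percent, 0-100):

* ``HR1``: SOC · (α + γ·M) · exp(β·T) — linear moisture modifier.
* ``HR2``: α · SOC · M/(M + k_M) · exp(β·T) — Michaelis–Menten moisture
  limitation.
* ``HR3``: α · SOC · min(T/(T + k_T), M/(M + k_M)) · exp(β·T) — Liebig-style
  limiting-factor form where the more limiting of the temperature and
  moisture saturation terms scales the flux.

The Michaelis–Menten half-saturation constants k_T and k_M are conventionally
set to half the record maximum of the corresponding driver (see
:func:`soilresp.calibrate.michaelis_constants`); α and β (and γ for HR1) are
fitted by least squares.

All evaluators are vectorised over T and M via numpy broadcasting; fluxes are
in g C m⁻² day⁻¹ (α carries the units that turn SOC in g kg⁻¹ into a flux).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = ["HRVariant", "HRParams", "evaluate_hr", "hr_partials"]

HRVariant = Literal["HR1", "HR2", "HR3"]

_VARIANTS = ("HR1", "HR2", "HR3")


@dataclass(frozen=True)
class HRParams:
    """Parameter set for one HR formulation.

    Parameters
    ----------
    variant
        One of ``"HR1"``, ``"HR2"``, ``"HR3"``.
    alpha
        Decomposition rate of unit SOC (≥ 0). Units absorb SOC (g kg⁻¹) so
        the flux lands in g C m⁻² day⁻¹.
    beta
        Temperature-response constant, °C⁻¹.
    gamma
        Moisture-response constant for HR1, per percent moisture. Ignored by
        HR2/HR3.
    k_T
        Michaelis–Menten half-saturation constant for temperature, °C
        (HR3 only; must be > 0 where used).
    k_M
        Michaelis–Menten half-saturation constant for moisture, percent
        (HR2/HR3; must be > 0 where used).
    provenance
        Free-form tag recording whether values were fitted or fixed.
    """

    variant: HRVariant
    alpha: float
    beta: float
    gamma: float = 0.0
    k_T: float = float("nan")
    k_M: float = float("nan")
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown HR variant {self.variant!r}; expected one of {_VARIANTS}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.variant in ("HR2", "HR3") and not (self.k_M > 0):
            raise ValueError(f"{self.variant} requires k_M > 0, got {self.k_M}")
        if self.variant == "HR3" and not (self.k_T > 0):
            raise ValueError(f"HR3 requires k_T > 0, got {self.k_T}")

    @property
    def free_names(self) -> tuple[str, ...]:
        """Names of the free (fitted) parameters for this variant."""
        return ("alpha", "gamma", "beta") if self.variant == "HR1" else ("alpha", "beta")

    def with_values(self, **kwargs: float) -> "HRParams":
        return replace(self, **kwargs)


def _moisture_factor(M: np.ndarray, k_M: float) -> np.ndarray:
    return M / (M + k_M)


def _temperature_factor(T: np.ndarray, k_T: float) -> np.ndarray:
    # Clamped to [0, 1]: field sites stay above freezing but synthetic
    # forcing may dip below 0 °C, and negative f_T would flip the flux sign.
    return np.clip(T / (T + k_T), 0.0, 1.0)


def evaluate_hr(params: HRParams, SOC: float, T, M) -> np.ndarray | float:
    """Evaluate heterotrophic respiration at (T, M) for a given SOC.

    Parameters
    ----------
    params
        Model parameters; ``params.variant`` picks the formulation.
    SOC
        Soil organic carbon concentration, g kg⁻¹ (≥ 0).
    T, M
        Soil temperature (°C) and volumetric moisture (percent), scalars or
        broadcastable arrays. M must be ≥ 0.

    Returns
    -------
    HR flux in g C m⁻² day⁻¹, same shape as the broadcast of T and M.
    """
    if SOC < 0:
        raise ValueError(f"SOC must be >= 0, got {SOC}")
    T = np.asarray(T, dtype=float)
    M = np.asarray(M, dtype=float)
    if np.any(M < 0):
        raise ValueError("soil moisture must be >= 0")
    expo = np.exp(params.beta * T)
    if params.variant == "HR1":
        out = SOC * (params.alpha + params.gamma * M) * expo
    elif params.variant == "HR2":
        out = params.alpha * SOC * _moisture_factor(M, params.k_M) * expo
    else:  # HR3
        f = np.minimum(_temperature_factor(T, params.k_T), _moisture_factor(M, params.k_M))
        out = params.alpha * SOC * f * expo
    return out if out.ndim else float(out)


def _analytic_partials(params: HRParams, SOC: float, T, M) -> tuple[np.ndarray, np.ndarray]:
    T = np.asarray(T, dtype=float)
    M = np.asarray(M, dtype=float)
    expo = np.exp(params.beta * T)
    if params.variant == "HR1":
        hr = SOC * (params.alpha + params.gamma * M) * expo
        dT = params.beta * hr
        dM = SOC * params.gamma * expo
        return dT, dM
    if params.variant == "HR2":
        fM = _moisture_factor(M, params.k_M)
        dT = params.beta * params.alpha * SOC * fM * expo
        dM = params.alpha * SOC * expo * params.k_M / (M + params.k_M) ** 2
        return dT, dM
    # HR3: derivative follows the active branch of the min; at the switch
    # point (f_T == f_M) the moisture branch is used by convention.
    fT = _temperature_factor(T, params.k_T)
    fM = _moisture_factor(M, params.k_M)
    t_active = fT < fM
    f = np.where(t_active, fT, fM)
    base = params.alpha * SOC * expo
    # within the clamp, d f_T/dT = k_T/(T+k_T)^2; outside [0,1] it is 0
    interior = (T / (T + params.k_T) > 0.0) & (T / (T + params.k_T) < 1.0)
    dfT = np.where(interior, params.k_T / (T + params.k_T) ** 2, 0.0)
    dT = base * (params.beta * f + np.where(t_active, dfT, 0.0))
    dM = np.where(t_active, 0.0, base * params.k_M / (M + params.k_M) ** 2)
    return np.asarray(dT, float), np.asarray(dM, float)


def _central_partials(
    params: HRParams, SOC: float, T, M, step: float
) -> tuple[np.ndarray, np.ndarray]:
    T = np.asarray(T, dtype=float)
    M = np.asarray(M, dtype=float)
    hT = step * np.maximum(1.0, np.abs(T))
    hM = step * np.maximum(1.0, np.abs(M))
    # keep M - hM >= 0 (domain boundary)
    hM = np.minimum(hM, np.where(M > 0, M, hM))
    dT = (evaluate_hr(params, SOC, T + hT, M) - evaluate_hr(params, SOC, T - hT, M)) / (2 * hT)
    with np.errstate(invalid="ignore"):
        dM = (evaluate_hr(params, SOC, T, M + hM) - evaluate_hr(params, SOC, T, M - hM)) / (2 * hM)
    return np.asarray(dT, float), np.asarray(dM, float)


def hr_partials(
    params: HRParams,
    SOC: float,
    T,
    M,
    method: Literal["analytic", "central_difference"] = "central_difference",
    step: float = 1e-6,
):
    """Partial derivatives (∂HR/∂T, ∂HR/∂M) at the state (T, M).

    ``analytic`` differentiates the closed form, using the active branch of
    the min in HR3 (moisture branch at the tie). ``central_difference`` uses
    symmetric differences with step ``step·max(1, |x|)`` per coordinate and
    is the default, since attribution by linear perturbation does not care
    how the derivative is obtained and the HR3 min is non-smooth.
    """
    if method == "analytic":
        dT, dM = _analytic_partials(params, SOC, T, M)
    elif method == "central_difference":
        dT, dM = _central_partials(params, SOC, T, M, step)
    else:
        raise ValueError(f"unknown method {method!r}")
    if dT.ndim == 0:
        return float(dT), float(dM)
    return dT, dM
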