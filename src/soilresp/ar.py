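"""Soil autotrophic respiration (AR) from fine-root maintenance and growth.

Soil autotrophic respiration is modelled as the sum of fine-root maintenance
respiration (Rm) and root growth respiration (Rg):

    AR  = Rm + Rg
    Rm  = P_rl · LAI/SLA · δ · ε^((T−20)/10)
    Rg  = g_f · P_rt · NPP,      NPP = GPP − TAR,     TAR = AR / P_rt

where P_rl is the fine root-to-leaf biomass ratio, SLA the specific leaf
area (m² per kg C), δ the maintenance respiration rate of fine-root biomass
at 20 °C, ε a Q10-like temperature-response base, g_f the growth-respiration
fraction of NPP (0.25 by default) and P_rt the fraction of NPP allocated to
roots (0.15 by default). Because TAR feeds back on NPP, AR appears on both
sides; solving the linear system gives the closed form

    AR = (1/(1+g_f))·Rm + (g_f/(1+g_f))·P_rt·GPP

which for the defaults reduces to AR = 0.8·Rm + 0.03·GPP. The 0.8 and 0.03
coefficients are always derived from g_f and P_rt, never hard-coded, so a
non-default allocation stays self-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "SiteConfig",
    "ARParams",
    "fine_root_biomass",
    "maintenance_respiration",
    "ar_closed_form",
    "ar_system_solve",
    "ar_partials",
    "ARSystemState",
    "BIOME_CONSTANTS",
]

# Biome constants keyed by forest type: fine root-to-leaf biomass ratio,
# specific leaf area (m² per kg C). Root allocation fraction P_rt = 0.15 and
# growth fraction 0.25 are biome-independent defaults.
BIOME_CONSTANTS: dict[str, dict[str, float]] = {
    "EBF": {"P_r_l": 1.1, "SLA": 25.9},
    "ENF": {"P_r_l": 1.2, "SLA": 14.1},
}


@dataclass(frozen=True)
class SiteConfig:
    """Site and biome constants.

    ``P_r_l`` and ``SLA`` default by ``forest_type`` (evergreen broadleaf EBF
    or evergreen needleleaf ENF); ``P_r_t`` is the root allocation fraction
    of NPP and ``growth_fraction`` the share of NPP spent as growth
    respiration.
    """

    site_id: str
    forest_type: Literal["EBF", "ENF"]
    SOC: float
    TN: float | None = None
    P_r_l: float | None = None
    SLA: float | None = None
    P_r_t: float = 0.15
    growth_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.forest_type not in BIOME_CONSTANTS:
            raise ValueError(f"forest_type must be one of {sorted(BIOME_CONSTANTS)}")
        if self.P_r_l is None:
            object.__setattr__(self, "P_r_l", BIOME_CONSTANTS[self.forest_type]["P_r_l"])
        if self.SLA is None:
            object.__setattr__(self, "SLA", BIOME_CONSTANTS[self.forest_type]["SLA"])
        if not self.P_r_l > 0:
            raise ValueError("P_r_l must be > 0")
        if not self.SLA > 0:
            raise ValueError("SLA must be > 0")
        if not 0 < self.P_r_t < 1:
            raise ValueError("P_r_t must be in (0, 1)")
        if self.SOC < 0:
            raise ValueError("SOC must be >= 0")


@dataclass(frozen=True)
class ARParams:
    """Maintenance-respiration parameters.

    ``delta`` is the maintenance respiration rate of fine-root biomass at
    20 °C in g C (kg C fine root)⁻¹ day⁻¹; ``epsilon`` the dimensionless
    temperature-response base (Q10-like). The shipped defaults δ=2, ε=2 are
    documented placeholders: site work must supply biome look-up-table
    (BPLUT) values or fit them.
    """

    delta: float = 2.0
    epsilon: float = 2.0
    provenance: Literal["BPLUT", "LM-fitted", "unspecified"] = "unspecified"

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be > 0")


def fine_root_biomass(site: SiteConfig, LAI, as_g: bool = False):
    """Fine root biomass FRB = P_rl · LAI / SLA.

    Returns kg C m⁻² by default; ``as_g=True`` returns g C m⁻² (×1000), the
    unit used for display and seasonal amplitudes.
    """
    index = LAI.index if isinstance(LAI, pd.Series) else None
    LAI = np.asarray(LAI, dtype=float)
    if np.any(LAI < 0):
        raise ValueError("LAI must be >= 0")
    frb = site.P_r_l * LAI / site.SLA
    if as_g:
        frb = frb * 1000.0
    if index is not None:
        return pd.Series(frb, index=index, name="FRB")
    return frb if frb.ndim else float(frb)


def _temp_response(ar: ARParams, T) -> np.ndarray:
    return np.power(ar.epsilon, (np.asarray(T, dtype=float) - 20.0) / 10.0)


def maintenance_respiration(site: SiteConfig, ar: ARParams, LAI, T):
    """Fine-root maintenance respiration Rm = FRB·δ·ε^((T−20)/10), g C m⁻² day⁻¹.

    δ carries units g C per kg C fine root per day, so FRB in kg C m⁻² puts
    Rm directly in g C m⁻² day⁻¹.
    """
    rm = fine_root_biomass(site, LAI) * ar.delta * _temp_response(ar, T)
    rm = np.asarray(rm, dtype=float)
    return rm if rm.ndim else float(rm)


def ar_closed_form(site: SiteConfig, ar: ARParams, LAI, GPP, T):
    """Closed-form AR = (1/(1+g_f))·Rm + (g_f/(1+g_f))·P_rt·GPP.

    With the default growth fraction 0.25 and P_rt = 0.15 this is
    AR = 0.8·Rm + 0.03·GPP.
    """
    GPP = np.asarray(GPP, dtype=float)
    if np.any(GPP < 0):
        raise ValueError("GPP must be >= 0")
    gf = site.growth_fraction
    rm_coef = 1.0 / (1.0 + gf)
    gpp_coef = gf / (1.0 + gf) * site.P_r_t
    out = rm_coef * maintenance_respiration(site, ar, LAI, T) + gpp_coef * GPP
    out = np.asarray(out, dtype=float)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ARSystemState:
    """Full solution of the maintenance/growth/allocation system."""

    AR: float | np.ndarray
    Rm: float | np.ndarray
    Rg: float | np.ndarray
    TAR: float | np.ndarray
    NPP: float | np.ndarray


def ar_system_solve(
    site: SiteConfig,
    ar: ARParams,
    LAI,
    GPP,
    T,
    tol: float = 1e-14,
    max_iter: int = 200,
) -> ARSystemState:
    """Solve AR = Rm + g_f·P_rt·(GPP − AR/P_rt) by fixed-point iteration.

    The iteration AR ← Rm + g_f·P_rt·GPP − g_f·AR contracts with factor
    g_f (< 1), so it converges geometrically from AR₀ = Rm; iteration stops
    when the update falls below ``tol`` in absolute value. This numeric
    route is kept deliberately independent of :func:`ar_closed_form` so the
    two can cross-check each other.

    Returns all intermediates; GPP = NPP + TAR holds by construction.
    """
    GPP = np.asarray(GPP, dtype=float)
    if np.any(GPP < 0):
        raise ValueError("GPP must be >= 0")
    rm = np.asarray(maintenance_respiration(site, ar, LAI, T), dtype=float)
    gf = site.growth_fraction
    const = rm + gf * site.P_r_t * GPP
    AR = rm.copy() if rm.ndim else np.array(rm, dtype=float)
    AR = np.broadcast_to(AR, np.broadcast_shapes(rm.shape, GPP.shape)).copy()
    for _ in range(max_iter):
        new = const - gf * AR
        if np.max(np.abs(new - AR)) <= tol:
            AR = new
            break
        AR = new
    TAR = AR / site.P_r_t
    NPP = GPP - TAR
    Rg = gf * site.P_r_t * NPP
    scalar = AR.ndim == 0
    unwrap = (lambda a: float(a)) if scalar else (lambda a: a)
    return ARSystemState(
        AR=unwrap(AR), Rm=unwrap(rm + 0.0), Rg=unwrap(np.asarray(Rg)),
        TAR=unwrap(np.asarray(TAR)), NPP=unwrap(np.asarray(NPP)),
    )


def ar_partials(
    site: SiteConfig,
    ar: ARParams,
    LAI,
    GPP,
    T,
    method: Literal["analytic", "central_difference"] = "analytic",
    step: float = 1e-6,
):
    """Partials (∂AR/∂T, ∂AR/∂FRB, ∂AR/∂GPP) of the closed form.

    Analytic values:
      ∂AR/∂GPP = (g_f/(1+g_f))·P_rt   (0.03 at defaults, state-independent)
      ∂AR/∂FRB = (1/(1+g_f))·δ·ε^((T−20)/10)
      ∂AR/∂T   = (1/(1+g_f))·Rm·ln(ε)/10
    """
    T = np.asarray(T, dtype=float)
    gf = site.growth_fraction
    rm_coef = 1.0 / (1.0 + gf)
    gpp_coef = gf / (1.0 + gf) * site.P_r_t
    if method == "analytic":
        rm = np.asarray(maintenance_respiration(site, ar, LAI, T), dtype=float)
        dT = rm_coef * rm * np.log(ar.epsilon) / 10.0
        dFRB = rm_coef * ar.delta * _temp_response(ar, T)
        dGPP = np.full_like(np.asarray(dT, dtype=float), gpp_coef)
    elif method == "central_difference":
        LAI = np.asarray(LAI, dtype=float)
        GPP = np.asarray(GPP, dtype=float)
        f = lambda lai, gpp, t: np.asarray(ar_closed_form(site, ar, lai, gpp, t), dtype=float)
        hT = step * np.maximum(1.0, np.abs(T))
        dT = (f(LAI, GPP, T + hT) - f(LAI, GPP, T - hT)) / (2 * hT)
        # FRB enters linearly through LAI: perturb LAI and rescale by dLAI/dFRB
        frb = np.asarray(fine_root_biomass(site, LAI), dtype=float)
        hF = step * np.maximum(1.0, np.abs(frb))
        dLAI_per_dFRB = site.SLA / site.P_r_l
        lai_hi = LAI + hF * dLAI_per_dFRB
        lai_lo = np.maximum(LAI - hF * dLAI_per_dFRB, 0.0)
        dFRB = (f(lai_hi, GPP, T) - f(lai_lo, GPP, T)) / (
            (lai_hi - lai_lo) / dLAI_per_dFRB
        )
        hG = step * np.maximum(1.0, np.abs(GPP))
        gpp_lo = np.maximum(GPP - hG, 0.0)
        dGPP = (f(LAI, GPP + hG, T) - f(LAI, gpp_lo, T)) / (GPP + hG - gpp_lo)
    else:
        raise ValueError(f"unknown method {method!r}")
    dT = np.asarray(dT, dtype=float)
    if dT.ndim == 0:
        return float(dT), float(dFRB), float(dGPP)
    return dT, np.asarray(dFRB, dtype=float), np.asarray(dGPP, dtype=float)
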