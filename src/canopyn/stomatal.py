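"""Coupled stomatal conductance, assimilation and transpiration.

The stomatal model is the Leuning modification of the Ball–Berry approach:

    gs_w = g0 + a1 · A / ((Cs − Γ*) · (1 + VPD/D0))

with Cs ≈ Ca (cuvette measurements; boundary-layer conductance neglected,
hook provided), Γ* the temperature-adjusted CO2 compensation point, and
gs_w floored at the residual conductance g0 whenever A ≤ 0.

At ambient CO2 the operating point is the intersection of the FvCB demand
curve A(Ci) with the diffusion supply A = (gs_w/1.6) · (Ca − Ci), where
gs_w itself depends on A.  The closure is solved as a one-dimensional root
on Ci with a bracketing method; the FvCB branch minimum is evaluated inside
the residual, so limitation switching needs no per-branch algebra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConvergenceError, DomainError, InputError
from .leaf_biochem import (
    KineticConstants,
    Limitation,
    PhotoParams25,
    adjust_photo_params,
    net_assimilation_at_ci,
)

__all__ = [
    "StomatalParams",
    "LeafEnvironment",
    "GasExchangeResult",
    "LeafDayResult",
    "stomatal_conductance",
    "solve_coupled_gas_exchange",
    "transpiration_rate",
    "daily_leaf_course",
]

#: Ratio of diffusivities of water vapour and CO2 through stomata.
GS_W_TO_C = 1.6

#: Default absolute tolerance on Ci for the coupled root (µmol mol⁻¹).
CI_TOL = 1e-6


@dataclass(frozen=True)
class StomatalParams:
    """Leuning stomatal parameters.

    ``g0``: residual conductance to water vapour (mol m⁻² s⁻¹);
    ``a1``: dimensionless sensitivity of gs to the assimilation signal;
    ``d0``: VPD shape parameter (kPa).  Defaults are standard C3 values;
    the calibrated species-specific values drop in via configuration.
    """

    g0: float = 0.02
    a1: float = 9.0
    d0: float = 1.5

    def __post_init__(self) -> None:
        if self.g0 < 0:
            raise DomainError(f"g0 must be >= 0, got {self.g0}")
        if self.a1 <= 0 or self.d0 <= 0:
            raise DomainError("a1 and d0 must be > 0")


@dataclass(frozen=True)
class LeafEnvironment:
    """Instantaneous drivers of one leaf."""

    ppfd: float          # µmol photon m⁻² s⁻¹
    tleaf: float         # °C
    vpd: float           # leaf-to-air vapour pressure deficit, kPa
    ca: float = 400.0    # ambient CO2, µmol mol⁻¹
    patm: float = 101.3  # atmospheric pressure, kPa

    def __post_init__(self) -> None:
        if self.ppfd < 0:
            raise DomainError(f"ppfd must be >= 0, got {self.ppfd}")
        if self.vpd < 0:
            raise DomainError(f"vpd must be >= 0, got {self.vpd}")
        if self.ca <= 0:
            raise DomainError(f"ca must be > 0, got {self.ca}")
        if not 80.0 <= self.patm <= 110.0:
            raise DomainError(f"patm must be in [80, 110] kPa, got {self.patm}")


@dataclass(frozen=True)
class GasExchangeResult:
    """One converged leaf gas-exchange operating point."""

    a_net: float         # µmol CO2 m⁻² s⁻¹
    ci: float            # µmol mol⁻¹
    gs_w: float          # mol H2O m⁻² s⁻¹
    e: float             # mmol H2O m⁻² s⁻¹
    limitation: Limitation
    residual: float      # supply − demand closure error, µmol m⁻² s⁻¹


def stomatal_conductance(
    a_net: float,
    cs: float,
    gamma: float,
    vpd: float,
    sp: StomatalParams,
) -> float:
    """Stomatal conductance to water vapour (mol m⁻² s⁻¹).

    Returns the residual conductance ``g0`` whenever the assimilation
    signal is non-positive (darkness, strong VPD suppression limit).
    """
    if cs <= gamma:
        raise DomainError(f"cs ({cs}) must exceed the compensation point ({gamma})")
    if a_net <= 0:
        return sp.g0
    return sp.g0 + sp.a1 * a_net / ((cs - gamma) * (1.0 + vpd / sp.d0))


def transpiration_rate(gs_w: float, vpd: float, patm: float) -> float:
    """Leaf transpiration (mmol H2O m⁻² s⁻¹) from the diffusion gradient.

    ``E = 1000 · gs_w · VPD / Patm``; linear in conductance and VPD.
    """
    if gs_w < 0 or vpd < 0 or patm <= 0:
        raise DomainError("gs_w and vpd must be >= 0, patm > 0")
    return 1000.0 * gs_w * vpd / patm


def solve_coupled_gas_exchange(
    env: LeafEnvironment,
    p25: PhotoParams25,
    kc: KineticConstants | None = None,
    sp: StomatalParams | None = None,
    ci_tol: float = CI_TOL,
) -> GasExchangeResult:
    """Solve the coupled A–Ci–gs system at ambient CO2.

    The returned (A, Ci, gs_w) jointly satisfy the FvCB demand curve, the
    Leuning stomatal equation and the diffusion closure
    ``A = (gs_w/1.6)(Ca − Ci)`` to within the solver tolerance.  When
    demand is non-positive even at Ci = Ca (dark or near-dark), gs is
    pinned to g0 and Ci follows the linear diffusion closure, rising above
    Ca as respiration exports CO2.
    """
    kc = kc or KineticConstants()
    sp = sp or StomatalParams()
    pt = adjust_photo_params(p25, kc, env.tleaf)
    ca = env.ca
    if ca <= pt.gamma_star:
        raise DomainError(
            f"ca ({ca}) must exceed gamma_star at tleaf ({pt.gamma_star:.2f})"
        )

    lo = pt.gamma_star + 1e-9 * max(1.0, pt.gamma_star)

    def demand(ci: float) -> float:
        return net_assimilation_at_ci(ci, pt, env.ppfd)[0]

    a_at_ca = demand(ca)
    if a_at_ca <= 0.0:
        # Demand cannot be positive anywhere in (Γ*, Ca]: respiration
        # regime.  gs = g0; Ci solves A(Ci) = (g0/1.6)(Ca − Ci), which for
        # A < 0 lies above Ca.
        if sp.g0 <= 0.0:
            raise ConvergenceError(
                "dark closure undefined with g0 = 0 (no diffusion path)",
                {"env": env, "a_at_ca": a_at_ca},
            )

        def f_dark(ci: float) -> float:
            return (sp.g0 / GS_W_TO_C) * (ca - ci) - demand(ci)

        hi = ca + GS_W_TO_C * (pt.rd + 1.0) / sp.g0 + 1.0
        ci = brentq(f_dark, lo, hi, xtol=ci_tol)
        a, lim = net_assimilation_at_ci(ci, pt, env.ppfd)
        gs = sp.g0
    else:
        def f(ci: float) -> float:
            a_ci = demand(ci)
            gs_ci = stomatal_conductance(a_ci, ca, pt.gamma_star, env.vpd, sp)
            return (gs_ci / GS_W_TO_C) * (ca - ci) - a_ci

        f_lo, f_hi = f(lo), f(ca)
        if f_lo < 0.0 or f_hi > 0.0:
            raise ConvergenceError(
                "supply/demand curves do not bracket a root on (gamma_star, ca]",
                {"f_lo": f_lo, "f_hi": f_hi, "env": env},
            )
        ci = brentq(f, lo, ca, xtol=ci_tol)
        a, lim = net_assimilation_at_ci(ci, pt, env.ppfd)
        gs = stomatal_conductance(a, ca, pt.gamma_star, env.vpd, sp)

    residual = (gs / GS_W_TO_C) * (ca - ci) - a
    return GasExchangeResult(
        a_net=a,
        ci=ci,
        gs_w=gs,
        e=transpiration_rate(gs, env.vpd, env.patm),
        limitation=lim,
        residual=residual,
    )


@dataclass(frozen=True)
class LeafDayResult:
    """Hourly leaf gas exchange plus daily integrals for one day."""

    steps: pd.DataFrame          # time_h, ppfd, tleaf, vpd, ca, a_net, ci, gs_w, e, limitation
    daily_a_mol: float           # mol CO2 m⁻² leaf d⁻¹
    daily_e_mol: float           # mol H2O m⁻² leaf d⁻¹


def daily_leaf_course(
    weather: pd.DataFrame,
    p25: PhotoParams25,
    kc: KineticConstants | None = None,
    sp: StomatalParams | None = None,
) -> LeafDayResult:
    """Run the coupled solver over a day of hourly weather for one leaf.

    ``weather`` follows the weather CSV schema (time_h, ppfd_umol_m2_s,
    tair_c, vpd_kpa, ca_umol_mol); leaf temperature is taken equal to air
    temperature.  Daily integrals use the trapezoid rule over time with
    µmol→mol (A) and mmol→mol (E) conversion.
    """
    from .io_fixtures import validate_weather  # local import avoids a cycle

    validate_weather(weather)
    if len(weather) < 2:
        raise InputError("weather must contain at least 2 records")

    rows = []
    for rec in weather.itertuples(index=False):
        env = LeafEnvironment(
            ppfd=rec.ppfd_umol_m2_s,
            tleaf=rec.tair_c,
            vpd=rec.vpd_kpa,
            ca=rec.ca_umol_mol,
        )
        res = solve_coupled_gas_exchange(env, p25, kc, sp)
        rows.append(
            {
                "time_h": rec.time_h,
                "ppfd": env.ppfd,
                "tleaf": env.tleaf,
                "vpd": env.vpd,
                "ca": env.ca,
                "a_net": res.a_net,
                "ci": res.ci,
                "gs_w": res.gs_w,
                "e": res.e,
                "limitation": res.limitation.value,
            }
        )
    steps = pd.DataFrame(rows)
    t_s = steps["time_h"].to_numpy() * 3600.0
    daily_a = float(np.trapezoid(steps["a_net"].to_numpy() * 1e-6, t_s))
    daily_e = float(np.trapezoid(steps["e"].to_numpy() * 1e-3, t_s))
    return LeafDayResult(steps=steps, daily_a_mol=daily_a, daily_e_mol=daily_e)
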