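"""Multilayer canopy: light extinction, N acclimation and flux upscaling.

The canopy is divided into ``n_strata`` horizontal layers of equal leaf
area (default 8).  Light attenuates through the leaf layers as a 1-D
turbid medium (Beer–Lambert) with a single extinction coefficient k, so
the relative irradiance at the cumulative-LAI midpoint Lᵢ of stratum i is
``exp(−k·Lᵢ)``; with a time-invariant k this instantaneous profile equals
the daily-integrated relative irradiance to which leaf N is assumed
acclimated.  Leaf-level PPFD within a stratum is the mean absorbed flux
per unit leaf area, ``k·I0·exp(−k·Lᵢ)``.

Each stratum carries its own leaf N (from the NNI-modulated light–N
profile) and hence its own FvCB capacities.  Hourly leaf fluxes are solved
per stratum with the coupled gas-exchange model, scaled by the stratum
leaf area and summed to ground-area fluxes; daily totals are trapezoid
integrals over the hourly course.  Leaf temperature is taken equal to air
temperature, and VPD and CO2 are uniform through the canopy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConvergenceError, InputError
from .leaf_biochem import KineticConstants, PhotoParams25
from .nitrogen import (
    NDistributionParams,
    kn_from_nni,
    leaf_nitrogen,
    nup_from_nni,
    photo_params_from_nitrogen,
)
from .stomatal import LeafEnvironment, StomatalParams, solve_coupled_gas_exchange

__all__ = [
    "CanopyStructure",
    "CanopyFluxSummary",
    "NniResponse",
    "build_canopy",
    "relative_irradiance_profile",
    "assign_canopy_nitrogen",
    "stratum_leaf_ppfd",
    "canopy_hourly_flux",
    "daily_canopy_assimilation",
    "nni_response",
]

#: Default Beer–Lambert extinction coefficient for a dense alfalfa canopy.
DEFAULT_K = 0.8

#: Relative closeness to the grid maximum that defines N saturation.
SATURATION_FRACTION = 0.98


@dataclass(frozen=True)
class CanopyStructure:
    """A horizontally homogeneous canopy discretized into strata.

    ``l_mid[i]`` is the cumulative LAI above the midpoint of stratum i
    (stratum 0 is the top); ``rel_irr`` the relative irradiance there.
    ``na`` and ``params25`` are filled by :func:`assign_canopy_nitrogen`.
    """

    lai: float
    n_strata: int
    k: float
    dlai: float
    l_mid: np.ndarray
    rel_irr: np.ndarray
    nni: float | None = None
    na: np.ndarray | None = None
    params25: tuple[PhotoParams25, ...] | None = None


def build_canopy(lai: float, n_strata: int = 8, k: float = DEFAULT_K) -> CanopyStructure:
    """Build a uniform canopy discretization.

    Leaf area is distributed homogeneously: Δlai = lai/n_strata and the
    midpoint cumulative LAI of stratum i (1-based, top first) is
    (i − 1/2)·Δlai.
    """
    if lai <= 0:
        raise InputError(f"lai must be > 0, got {lai}")
    if n_strata < 1:
        raise InputError(f"n_strata must be >= 1, got {n_strata}")
    if k <= 0:
        raise InputError(f"k must be > 0, got {k}")
    dlai = lai / n_strata
    l_mid = (np.arange(n_strata) + 0.5) * dlai
    return CanopyStructure(
        lai=lai,
        n_strata=n_strata,
        k=k,
        dlai=dlai,
        l_mid=l_mid,
        rel_irr=np.exp(-k * l_mid),
    )


def relative_irradiance_profile(canopy: CanopyStructure) -> np.ndarray:
    """Per-stratum relative irradiance ``exp(−k·Lᵢ)`` at the midpoints."""
    return np.exp(-canopy.k * canopy.l_mid)


def assign_canopy_nitrogen(
    canopy: CanopyStructure,
    nni: float,
    ndist: NDistributionParams | None = None,
) -> CanopyStructure:
    """Acclimate the canopy to its light profile at a given N status.

    Each stratum receives ``Na = leaf_nitrogen(rel_irr, NNI)`` and the
    corresponding 25 °C capacities from the Na regressions.
    """
    ndist = ndist or NDistributionParams()
    na = np.array([leaf_nitrogen(ri, nni, ndist) for ri in canopy.rel_irr])
    params = tuple(photo_params_from_nitrogen(v, ndist) for v in na)
    return replace(canopy, nni=nni, na=na, params25=params)


def stratum_leaf_ppfd(i0: float, l_mid: float, k: float) -> float:
    """Mean PPFD absorbed per unit leaf area at canopy depth ``l_mid``.

    In a turbid medium the flux absorbed by the layer at cumulative LAI L
    is ``k·I0·exp(−k·L)`` per unit leaf area.
    """
    if i0 < 0 or l_mid < 0 or k < 0:
        raise InputError("i0, l_mid and k must be >= 0")
    return k * i0 * float(np.exp(-k * l_mid))


def canopy_total_leaf_n(canopy: CanopyStructure) -> float:
    """Discretized total canopy leaf N (g N m⁻² ground); Σ Naᵢ·Δlaiᵢ."""
    if canopy.na is None:
        raise InputError("canopy has no nitrogen assigned")
    return float(np.sum(canopy.na) * canopy.dlai)


def canopy_hourly_flux(
    canopy: CanopyStructure,
    ppfd_above: float,
    tair: float,
    vpd: float,
    ca: float,
    kc: KineticConstants | None = None,
    sp: StomatalParams | None = None,
    patm: float = 101.3,
) -> tuple[float, float, pd.DataFrame]:
    """Ground-area canopy fluxes for one weather record.

    Solves the coupled leaf model in every stratum at its own leaf PPFD
    (shared tair/vpd/ca), scales by Δlai and sums.  Returns (A in µmol CO2
    m⁻² ground s⁻¹, E in mmol H2O m⁻² ground s⁻¹, per-stratum detail).
    """
    if canopy.params25 is None:
        raise InputError("canopy has no nitrogen assigned; call assign_canopy_nitrogen")
    rows = []
    a_tot = 0.0
    e_tot = 0.0
    for i in range(canopy.n_strata):
        q_leaf = stratum_leaf_ppfd(ppfd_above, float(canopy.l_mid[i]), canopy.k)
        env = LeafEnvironment(ppfd=q_leaf, tleaf=tair, vpd=vpd, ca=ca, patm=patm)
        try:
            res = solve_coupled_gas_exchange(env, canopy.params25[i], kc, sp)
        except ConvergenceError as err:
            err.state["stratum"] = i
            raise
        a_tot += res.a_net * canopy.dlai
        e_tot += res.e * canopy.dlai
        rows.append(
            {
                "stratum": i + 1,
                "ppfd_leaf": q_leaf,
                "a_net": res.a_net,
                "e": res.e,
                "ci": res.ci,
                "gs_w": res.gs_w,
                "limitation": res.limitation.value,
            }
        )
    return a_tot, e_tot, pd.DataFrame(rows)


@dataclass(frozen=True)
class CanopyFluxSummary:
    """Daily whole-canopy gas exchange and its hourly/stratum breakdown."""

    daily_a_mol: float           # mol CO2 m⁻² ground d⁻¹
    daily_e_mol: float           # mol H2O m⁻² ground d⁻¹
    hourly: pd.DataFrame         # time_h, a_net, e (ground-area totals)
    strata_hourly: pd.DataFrame  # time_h, stratum, ppfd_leaf, a_net, e, limitation


def daily_canopy_assimilation(
    canopy: CanopyStructure,
    weather: pd.DataFrame,
    kc: KineticConstants | None = None,
    sp: StomatalParams | None = None,
) -> CanopyFluxSummary:
    """Integrate hourly canopy fluxes over one day.

    Net photosynthesis is computed within each stratum and then summed to
    the whole canopy each hour; daily totals are trapezoid integrals of
    the hourly ground-area sums (µmol→mol for A, mmol→mol for E).
    """
    from .io_fixtures import validate_weather

    validate_weather(weather)
    if len(weather) < 2:
        raise InputError("weather must contain at least 2 records")

    hourly_rows = []
    detail_frames = []
    for rec in weather.itertuples(index=False):
        a, e, detail = canopy_hourly_flux(
            canopy, rec.ppfd_umol_m2_s, rec.tair_c, rec.vpd_kpa, rec.ca_umol_mol,
            kc, sp,
        )
        hourly_rows.append({"time_h": rec.time_h, "a_net": a, "e": e})
        detail.insert(0, "time_h", rec.time_h)
        detail_frames.append(detail)
    hourly = pd.DataFrame(hourly_rows)
    t_s = hourly["time_h"].to_numpy() * 3600.0
    daily_a = float(np.trapezoid(hourly["a_net"].to_numpy() * 1e-6, t_s))
    daily_e = float(np.trapezoid(hourly["e"].to_numpy() * 1e-3, t_s))
    return CanopyFluxSummary(
        daily_a_mol=daily_a,
        daily_e_mol=daily_e,
        hourly=hourly,
        strata_hourly=pd.concat(detail_frames, ignore_index=True),
    )


@dataclass(frozen=True)
class NniResponse:
    """Daily canopy assimilation across an NNI grid.

    ``normalized`` is relative to the value at NNI = 1; ``saturation_nni``
    is the smallest grid value whose daily assimilation is within 2 % of
    the grid maximum.
    """

    nni: np.ndarray
    daily_a: np.ndarray
    normalized: np.ndarray
    saturation_nni: float


def nni_response(
    lai: float,
    weather: pd.DataFrame,
    nni_grid,
    n_strata: int = 8,
    k: float = DEFAULT_K,
    ndist: NDistributionParams | None = None,
    kc: KineticConstants | None = None,
    sp: StomatalParams | None = None,
) -> NniResponse:
    """Daily canopy assimilation response to plant N status.

    Rebuilds the canopy N profile at every NNI on the grid, runs the full
    day, and locates the N-saturation point of the response curve.  The
    grid must be ascending, lie in (0, 2] and include 1.0 (the optimum,
    used for normalization).
    """
    grid = np.asarray(list(nni_grid), dtype=float)
    if grid.ndim != 1 or len(grid) < 2:
        raise InputError("nni_grid must be a 1-D sequence with >= 2 values")
    if np.any(np.diff(grid) <= 0):
        raise InputError("nni_grid must be strictly ascending")
    if grid[0] <= 0 or grid[-1] > 2.0:
        raise InputError("nni_grid values must lie in (0, 2]")
    i_opt = int(np.argmin(np.abs(grid - 1.0)))
    if abs(grid[i_opt] - 1.0) > 1e-9:
        raise InputError("nni_grid must include the value 1.0")

    template = build_canopy(lai, n_strata, k)
    daily = np.empty_like(grid)
    for i, nni in enumerate(grid):
        canopy = assign_canopy_nitrogen(template, float(nni), ndist)
        daily[i] = daily_canopy_assimilation(canopy, weather, kc, sp).daily_a_mol

    a_max = daily.max()
    saturated = grid[daily >= SATURATION_FRACTION * a_max]
    return NniResponse(
        nni=grid,
        daily_a=daily,
        normalized=daily / daily[i_opt],
        saturation_nni=float(saturated[0]),
    )
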