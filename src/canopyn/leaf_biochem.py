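"""Farquhar–von Caemmerer–Berry (FvCB) C3 photosynthesis core.

Net assimilation of a C3 leaf is modelled as the minimum of three potential
carboxylation rates — Rubisco-limited (Wc), RuBP-regeneration-limited (Wj)
and triose-phosphate-utilization-limited (Wp) — minus day respiration:

    A = min(Wc, Wj, Wp) − Rd

    Wc = Vcmax (Ci − Γ*) / (Ci + Kc (1 + O/Ko))
    Wj = J (Ci − Γ*) / (4 Ci + 8 Γ*)
    Wp = 3 TPU

with the electron transport rate J the smaller root of a non-rectangular
hyperbola in incident PPFD.  Capacity parameters (Vcmax, Jmax, TPU, Rd) are
given at the 25 °C reference and adjusted to leaf temperature with an
Arrhenius response, peaked for Jmax.  Kinetic constants default to the
Bernacchi et al. (2001) in-vivo values and are fully configurable.

Units: rates in µmol m⁻² s⁻¹, Ci/Kc/Γ* in µmol mol⁻¹, Ko and O in
mmol mol⁻¹, temperatures in °C, activation energies in J mol⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .errors import DomainError

R_GAS = 8.314  # universal gas constant, J mol⁻¹ K⁻¹
T_REF_K = 298.15  # 25 °C reference, K

__all__ = [
    "PhotoParams25",
    "KineticConstants",
    "PhotoParamsT",
    "Limitation",
    "arrhenius",
    "peaked_arrhenius",
    "temperature_adjust",
    "adjust_photo_params",
    "electron_transport_rate",
    "gross_limitation_rates",
    "net_assimilation_at_ci",
]


@dataclass(frozen=True)
class PhotoParams25:
    """Leaf photosynthetic capacities at the 25 °C reference temperature.

    Attributes
    ----------
    vcmax25 : float
        Maximum carboxylation rate (µmol CO2 m⁻² s⁻¹).
    jmax25 : float
        Maximum electron transport rate (µmol e⁻ m⁻² s⁻¹).
    tpu25 : float
        Triose-phosphate utilization rate (µmol m⁻² s⁻¹).
    rd25 : float
        Day respiration (µmol CO2 m⁻² s⁻¹).  Night respiration is taken
        equal to day respiration.

    ``jmax25 >= vcmax25`` is typical but deliberately not enforced: the
    values are data-driven (regressions on leaf N may produce any ratio).
    """

    vcmax25: float
    jmax25: float
    tpu25: float
    rd25: float

    def __post_init__(self) -> None:
        for name in ("vcmax25", "jmax25", "tpu25", "rd25"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class KineticConstants:
    """Rubisco kinetics, temperature responses and light-response shape.

    Defaults follow Bernacchi et al. (2001) for the Michaelis constants and
    compensation point, with a peaked Arrhenius for Jmax (de Pury &
    Farquhar-type Hd/ΔS) and TPU sharing the Jmax temperature response.
    Every value can be overridden from the run configuration.
    """

    kc25: float = 404.9        # µmol mol⁻¹
    ko25: float = 278.4        # mmol mol⁻¹
    gamma_star25: float = 42.75  # µmol mol⁻¹
    o2: float = 210.0          # mmol mol⁻¹
    ea_kc: float = 79430.0     # J mol⁻¹
    ea_ko: float = 36380.0
    ea_gamma_star: float = 37830.0
    ea_vcmax: float = 65330.0
    ea_rd: float = 46390.0
    ea_jmax: float = 43540.0
    hd_jmax: float = 152040.0  # deactivation enthalpy, J mol⁻¹
    ds_jmax: float = 495.0     # entropy term, J mol⁻¹ K⁻¹
    theta: float = 0.7         # J curvature (0 < θ < 1)
    alpha: float = 0.3         # apparent quantum yield, e⁻ per incident photon

    def __post_init__(self) -> None:
        positive = (
            "kc25", "ko25", "gamma_star25", "o2", "ea_kc", "ea_ko",
            "ea_gamma_star", "ea_vcmax", "ea_rd", "ea_jmax", "hd_jmax",
            "ds_jmax",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 < self.theta < 1.0:
            raise DomainError(f"theta must be in (0, 1), got {self.theta}")
        if not 0.0 < self.alpha < 0.5:
            raise DomainError(f"alpha must be in (0, 0.5), got {self.alpha}")


class Limitation(str, Enum):
    """Which FvCB branch was minimal in an assimilation evaluation."""

    RUBISCO = "rubisco"
    RUBP_REGENERATION = "rubp_regeneration"
    TPU = "tpu"


@dataclass(frozen=True)
class PhotoParamsT:
    """All leaf parameters evaluated at one leaf temperature.

    Produced by :func:`adjust_photo_params`; the bundle that the coupled
    gas-exchange solver and the canopy loop carry around.
    """

    vcmax: float
    jmax: float
    tpu: float
    rd: float
    kc: float
    ko: float
    gamma_star: float
    o2: float
    theta: float
    alpha: float
    tleaf: float


def _check_tleaf(tleaf: float) -> None:
    if not -5.0 <= tleaf <= 50.0:
        raise DomainError(f"tleaf must be within [-5, 50] degC, got {tleaf}")


def arrhenius(p25: float, ea: float, tleaf: float) -> float:
    """Arrhenius temperature scaling of a parameter given at 25 °C.

    ``p25 · exp(Ea (Tk − 298.15) / (298.15 · R · Tk))`` with Tk in kelvin.
    """
    _check_tleaf(tleaf)
    tk = tleaf + 273.15
    return p25 * math.exp(ea * (tk - T_REF_K) / (T_REF_K * R_GAS * tk))


def peaked_arrhenius(p25: float, ea: float, hd: float, ds: float, tleaf: float) -> float:
    """Peaked (deactivating) Arrhenius response, unimodal in temperature.

    The Arrhenius rise is damped by a high-temperature deactivation term
    with enthalpy ``hd`` and entropy ``ds``; the response is normalised to
    1 at 25 °C.
    """
    _check_tleaf(tleaf)
    tk = tleaf + 273.15
    num = 1.0 + math.exp((T_REF_K * ds - hd) / (T_REF_K * R_GAS))
    den = 1.0 + math.exp((tk * ds - hd) / (tk * R_GAS))
    return arrhenius(p25, ea, tleaf) * num / den


def temperature_adjust(
    p25: float,
    form: str,
    constants: KineticConstants,
    tleaf: float,
    ea: float | None = None,
) -> float:
    """Adjust a 25 °C parameter value to leaf temperature.

    Parameters
    ----------
    form : {"arrhenius", "peaked"}
        ``"arrhenius"`` uses ``ea`` (required); ``"peaked"`` uses the Jmax
        peaked-response block of ``constants`` (``ea`` overrides its Ea).
    """
    if form == "arrhenius":
        if ea is None:
            raise DomainError("arrhenius form requires an activation energy ea")
        return arrhenius(p25, ea, tleaf)
    if form == "peaked":
        return peaked_arrhenius(
            p25,
            constants.ea_jmax if ea is None else ea,
            constants.hd_jmax,
            constants.ds_jmax,
            tleaf,
        )
    raise DomainError(f"unknown temperature response form: {form!r}")


def adjust_photo_params(
    p25: PhotoParams25, constants: KineticConstants, tleaf: float
) -> PhotoParamsT:
    """Evaluate capacities and kinetic constants at one leaf temperature.

    Vcmax and Rd follow plain Arrhenius responses; Jmax a peaked Arrhenius;
    TPU is scaled with the Jmax response (both are regeneration-side
    capacities).  Kc, Ko and Γ* use their own activation energies.
    """
    _check_tleaf(tleaf)
    jmax_scale = peaked_arrhenius(
        1.0, constants.ea_jmax, constants.hd_jmax, constants.ds_jmax, tleaf
    )
    return PhotoParamsT(
        vcmax=arrhenius(p25.vcmax25, constants.ea_vcmax, tleaf),
        jmax=p25.jmax25 * jmax_scale,
        tpu=p25.tpu25 * jmax_scale,
        rd=arrhenius(p25.rd25, constants.ea_rd, tleaf),
        kc=arrhenius(constants.kc25, constants.ea_kc, tleaf),
        ko=arrhenius(constants.ko25, constants.ea_ko, tleaf),
        gamma_star=arrhenius(constants.gamma_star25, constants.ea_gamma_star, tleaf),
        o2=constants.o2,
        theta=constants.theta,
        alpha=constants.alpha,
        tleaf=tleaf,
    )


def electron_transport_rate(
    ppfd: float, jmax_t: float, theta: float, alpha: float
) -> float:
    """Electron transport rate J from the non-rectangular hyperbola.

    Smaller root of ``θJ² − (αQ + Jmax)J + αQ·Jmax = 0``; satisfies
    ``0 ≤ J ≤ min(αQ, Jmax)``.  A degenerate ``θ → 0`` collapses to the
    rectangular hyperbola ``αQ·Jmax / (αQ + Jmax)``.
    """
    if ppfd < 0:
        raise DomainError(f"ppfd must be >= 0, got {ppfd}")
    i2 = alpha * ppfd
    if i2 == 0.0 or jmax_t == 0.0:
        return 0.0
    if theta < 1e-9:
        return i2 * jmax_t / (i2 + jmax_t)
    b = i2 + jmax_t
    disc = b * b - 4.0 * theta * i2 * jmax_t
    return (b - math.sqrt(max(disc, 0.0))) / (2.0 * theta)


def gross_limitation_rates(
    ci: float,
    vcmax_t: float,
    j: float,
    tpu_t: float,
    kc_t: float,
    ko_t: float,
    gamma_star_t: float,
    o2: float,
) -> tuple[float, float, float]:
    """The three potential gross carboxylation rates (Wc, Wj, Wp) at Ci.

    Wp is constant in Ci; Wc and Wj are zero at Ci = Γ* and increase with
    Ci above it.
    """
    if ci <= 0:
        raise DomainError(f"ci must be > 0, got {ci}")
    wc = vcmax_t * (ci - gamma_star_t) / (ci + kc_t * (1.0 + o2 / ko_t))
    wj = j * (ci - gamma_star_t) / (4.0 * ci + 8.0 * gamma_star_t)
    wp = 3.0 * tpu_t
    return wc, wj, wp


_BRANCH_ORDER = (Limitation.RUBISCO, Limitation.RUBP_REGENERATION, Limitation.TPU)


def net_assimilation_at_ci(
    ci: float, pt: PhotoParamsT, ppfd: float
) -> tuple[float, Limitation]:
    """Net assimilation A = min(Wc, Wj, Wp) − Rd at a given internal CO2.

    Returns the rate and the limiting branch; ties break in the order
    rubisco < rubp_regeneration < tpu.  The minimum is a hard switch (no
    hyperbolic smoothing), which keeps the limitation state diagnosable.
    """
    j = electron_transport_rate(ppfd, pt.jmax, pt.theta, pt.alpha)
    rates = gross_limitation_rates(
        ci, pt.vcmax, j, pt.tpu, pt.kc, pt.ko, pt.gamma_star, pt.o2
    )
    idx = min(range(3), key=lambda i: rates[i])
    return rates[idx] - pt.rd, _BRANCH_ORDER[idx]
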