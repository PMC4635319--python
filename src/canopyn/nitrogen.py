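"""Plant nitrogen status and within-canopy leaf-N allocation.

Three empirical layers link soil-independent plant N status to leaf
photosynthetic capacity:

1. **Critical N dilution curve** — the minimum plant N concentration
   sustaining maximal growth declines allometrically with standing biomass,
   ``Nc = 4.8 · W^−0.33`` for alfalfa (W in t DM ha⁻¹, Nc in g N per
   100 g DM), with the conventional plateau Nc = 4.8 below 1 t ha⁻¹.  The
   nitrogen nutrition index is ``NNI = Nm / Nc``: 1 is optimal, below 1 the
   intensity of deficiency is 1 − NNI.

2. **Light–N profile** — leaf N per unit area declines with relative
   irradiance as ``Na = Nup · (I/I0)^kN``, where Nup anchors the profile at
   the fully lit canopy top and the allocation coefficient kN (< 1 in
   practice) makes N fall more slowly than light.  Both parameters respond
   linearly to NNI: ``Nup = Nup_opt + a2·(NNI − 1)`` and
   ``kN = kN_opt + a3·(NNI − 1)``.  The default calibration for alfalfa is
   a2 = 2.15, Nup_opt = 2.17 g N m⁻², a3 = 0, kN_opt = 0.25.

3. **Na → capacity regressions** — Vcmax25, Jmax25, TPU25 and Rd25 are
   linear in Na, independent of the N acquisition mode (mineral
   assimilation vs symbiotic fixation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .errors import DomainError
from .leaf_biochem import PhotoParams25

logger = logging.getLogger("canopyn.nitrogen")

__all__ = [
    "PlantNStatus",
    "NDistributionParams",
    "critical_nitrogen",
    "nitrogen_nutrition_index",
    "nup_from_nni",
    "kn_from_nni",
    "leaf_nitrogen",
    "photo_params_from_nitrogen",
    "canopy_leaf_n_integral",
]

#: Upper clamp for kN; the profile exponent stays strictly below 1
#: (observed allocation is always less than proportional to light).
_KN_MAX = 1.0 - 1e-9


@dataclass(frozen=True)
class PlantNStatus:
    """Whole-plant N status: biomass, N concentration and the derived NNI.

    ``w`` is aboveground dry biomass (t DM ha⁻¹), ``nm`` the actual plant N
    concentration (g N per 100 g DM), ``nni`` the nitrogen nutrition index.
    """

    w: float
    nm: float
    nni: float

    @classmethod
    def from_biomass(cls, w: float, nm: float) -> "PlantNStatus":
        return cls(w=w, nm=nm, nni=nitrogen_nutrition_index(nm, w))

    def __post_init__(self) -> None:
        for name in ("w", "nm", "nni"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class NDistributionParams:
    """Calibration of the N-profile model and the Na → capacity mapping.

    Profile block: ``nup_opt`` (g N m⁻², top-leaf N at NNI = 1), ``a2``
    (slope of Nup vs NNI), ``kn_opt`` (allocation coefficient at NNI = 1),
    ``a3`` (slope of kN vs NNI, 0 for alfalfa).  Regression block: slope
    and intercept of each 25 °C capacity against Na.
    """

    nup_opt: float = 2.17
    a2: float = 2.15
    kn_opt: float = 0.25
    a3: float = 0.0
    vcmax_slope: float = 53.03
    vcmax_intercept: float = -14.74
    jmax_slope: float = 90.91
    jmax_intercept: float = -13.83
    tpu_slope: float = 6.72
    tpu_intercept: float = -0.72
    rd_slope: float = 0.69
    rd_intercept: float = -0.005

    def __post_init__(self) -> None:
        if self.nup_opt <= 0:
            raise DomainError(f"nup_opt must be > 0, got {self.nup_opt}")
        if not 0.0 <= self.kn_opt < 1.0:
            raise DomainError(f"kn_opt must be in [0, 1), got {self.kn_opt}")


def critical_nitrogen(w: float) -> float:
    """Critical plant N concentration (g N 100 g⁻¹ DM) at biomass ``w``.

    ``4.8 · w^−0.33`` for w ≥ 1 t DM ha⁻¹; below 1 t ha⁻¹ the curve is
    held at its 4.8 plateau, following standard dilution-curve practice.
    """
    if w <= 0:
        raise DomainError(f"biomass w must be > 0, got {w}")
    if w < 1.0:
        return 4.8
    return 4.8 * w ** (-0.33)


def nitrogen_nutrition_index(nm: float, w: float) -> float:
    """NNI = actual / critical plant N concentration."""
    if nm <= 0:
        raise DomainError(f"nm must be > 0, got {nm}")
    return nm / critical_nitrogen(w)


def nup_from_nni(nni: float, params: NDistributionParams | None = None) -> float:
    """Top-of-canopy leaf N (g N m⁻²) as a linear function of NNI.

    ``Nup = nup_opt + a2·(NNI − 1)``, floored at 0 for extreme deficiency.
    """
    if nni <= 0:
        raise DomainError(f"nni must be > 0, got {nni}")
    p = params or NDistributionParams()
    return max(0.0, p.nup_opt + p.a2 * (nni - 1.0))


def kn_from_nni(nni: float, params: NDistributionParams | None = None) -> float:
    """Allocation coefficient kN vs NNI, clamped to [0, 1).

    With the default alfalfa calibration a3 = 0, kN is constant at 0.25
    regardless of N status.
    """
    if nni <= 0:
        raise DomainError(f"nni must be > 0, got {nni}")
    p = params or NDistributionParams()
    kn = p.kn_opt + p.a3 * (nni - 1.0)
    return min(max(kn, 0.0), _KN_MAX)


def leaf_nitrogen(
    rel_irr: float, nni: float, params: NDistributionParams | None = None
) -> float:
    """Leaf N per area (g N m⁻²) at relative irradiance ``rel_irr``.

    ``Na = Nup(NNI) · rel_irr^kN(NNI)``; anchored at Nup for a fully lit
    leaf (rel_irr = 1) and monotone in rel_irr for kN ≥ 0.
    """
    if not 0.0 < rel_irr <= 1.0:
        raise DomainError(f"rel_irr must be in (0, 1], got {rel_irr}")
    p = params or NDistributionParams()
    return nup_from_nni(nni, p) * rel_irr ** kn_from_nni(nni, p)


def photo_params_from_nitrogen(
    na: float, params: NDistributionParams | None = None
) -> PhotoParams25:
    """Map leaf N per area to 25 °C photosynthetic capacities.

    Each capacity is ``slope·Na + intercept``; the printed regressions have
    negative intercepts, so predictions at very low Na are clamped to 0
    (with a log warning — such leaves are photosynthetically inert).
    """
    if na < 0:
        raise DomainError(f"na must be >= 0, got {na}")
    p = params or NDistributionParams()
    raw = {
        "vcmax25": p.vcmax_slope * na + p.vcmax_intercept,
        "jmax25": p.jmax_slope * na + p.jmax_intercept,
        "tpu25": p.tpu_slope * na + p.tpu_intercept,
        "rd25": p.rd_slope * na + p.rd_intercept,
    }
    clamped = {k: max(0.0, v) for k, v in raw.items()}
    if any(v < 0 for v in raw.values()):
        logger.warning(
            "negative predicted capacity at Na=%.3f g m^-2 clamped to 0", na
        )
    return PhotoParams25(**clamped)


def canopy_leaf_n_integral(nup: float, kn: float, k: float, lai: float) -> float:
    """Closed-form total canopy leaf N (g N m⁻² ground).

    With Beer–Lambert relative irradiance ``e^(−k·L)``, the profile
    integrates to ``Nup · (1 − e^(−k·kN·LAI)) / (k·kN)``; the kN → 0 limit
    is the uniform profile ``Nup·LAI``.  Serves as the analytic oracle for
    the canopy module's discretized N bookkeeping.
    """
    if lai <= 0 or k <= 0:
        raise DomainError("lai and k must be > 0")
    if kn < 0:
        raise DomainError(f"kn must be >= 0, got {kn}")
    if kn * k * lai < 1e-12:
        return nup * lai
    return nup * (1.0 - math.exp(-k * kn * lai)) / (k * kn)
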