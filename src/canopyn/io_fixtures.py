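"""File formats, configuration and synthetic-data generators.

Column names carry units (``ppfd_umol_m2_s``, ``tair_c``, ``vpd_kpa``,
``ca_umol_mol``, ``na_g_m2``) so that unit errors fail loudly at read
time instead of silently downstream.  The run configuration is a single
YAML file whose blocks mirror the parameter dataclasses; unknown keys are
rejected.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InputError
from .leaf_biochem import (
    KineticConstants,
    PhotoParams25,
    adjust_photo_params,
    net_assimilation_at_ci,
)
from .nitrogen import NDistributionParams
from .stomatal import StomatalParams

logger = logging.getLogger("canopyn.io")

__all__ = [
    "WeatherSpec",
    "ACiCurve",
    "RunConfig",
    "generate_weather_day",
    "generate_synthetic_aci",
    "generate_synthetic_profile",
    "saturation_vapour_pressure",
    "validate_weather",
    "read_weather_csv",
    "write_weather_csv",
    "read_strata_csv",
    "write_strata_csv",
    "read_aci_csv",
    "write_aci_csv",
    "load_config",
]

WEATHER_COLUMNS = ["time_h", "ppfd_umol_m2_s", "tair_c", "vpd_kpa", "ca_umol_mol"]
STRATA_COLUMNS = ["stratum_id", "depth_cm", "lai", "rel_irr", "na_g_m2"]
ACI_COLUMNS = ["ci_umol_mol", "a_umol_m2_s"]

_FLOAT_FMT = "%.12g"  # round-trips to 12 significant digits


# ---------------------------------------------------------------------------
# Synthetic weather
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeatherSpec:
    """Recipe for one synthetic day of hourly weather.

    ``day_type`` only selects a default peak PPFD (sunny 1100, cloudy 420
    µmol m⁻² s⁻¹) when ``peak_ppfd`` is not given.  PPFD follows a
    half-sine over the daylength (daytime mean = (2/π)·peak), air
    temperature a 24-h sinusoid between ``t_min`` and ``t_max`` peaking
    mid-afternoon, and VPD derives from temperature at constant relative
    humidity ``rh``.  ``noise_sd`` adds multiplicative Gaussian
    fluctuations to PPFD (cloud passage), seeded.
    """

    day_type: str = "sunny"
    daylength: float = 14.0      # h
    peak_ppfd: float | None = None
    t_min: float = 18.0          # °C
    t_max: float = 26.0          # °C
    rh: float = 0.6              # fractional relative humidity
    ca: float = 400.0            # µmol mol⁻¹
    dt_h: float = 1.0            # time step, h
    noise_sd: float = 0.0        # fractional PPFD noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.day_type not in ("sunny", "cloudy"):
            raise InputError(f"day_type must be 'sunny' or 'cloudy', got {self.day_type!r}")
        if not 0.0 < self.daylength <= 24.0:
            raise InputError(f"daylength must be in (0, 24], got {self.daylength}")
        if self.peak_ppfd is not None and self.peak_ppfd < 0:
            raise InputError("peak_ppfd must be >= 0")
        if not 0.0 < self.rh < 1.0:
            raise InputError(f"rh must be in (0, 1), got {self.rh}")
        if self.dt_h <= 0:
            raise InputError("dt_h must be > 0")

    @property
    def resolved_peak(self) -> float:
        if self.peak_ppfd is not None:
            return self.peak_ppfd
        return 1100.0 if self.day_type == "sunny" else 420.0


def saturation_vapour_pressure(t_c: float | np.ndarray) -> float | np.ndarray:
    """Tetens saturation vapour pressure (kPa) at air temperature (°C)."""
    return 0.6108 * np.exp(17.27 * np.asarray(t_c) / (np.asarray(t_c) + 237.3))


def generate_weather_day(spec: WeatherSpec) -> pd.DataFrame:
    """Generate one day of hourly weather from a :class:`WeatherSpec`.

    Times run from 0 to 24 h inclusive so daily trapezoid integrals cover
    the full day.  Sunrise is centred: daylight spans
    [(24 − daylength)/2, (24 + daylength)/2].
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, 24.0 + 0.5 * spec.dt_h, spec.dt_h)
    sunrise = (24.0 - spec.daylength) / 2.0
    phase = (t - sunrise) / spec.daylength
    ppfd = np.where(
        (phase > 0.0) & (phase < 1.0),
        spec.resolved_peak * np.sin(np.pi * np.clip(phase, 0.0, 1.0)),
        0.0,
    )
    if spec.noise_sd > 0:
        ppfd = np.clip(ppfd * (1.0 + spec.noise_sd * rng.standard_normal(len(t))), 0.0, None)
    t_mean = 0.5 * (spec.t_min + spec.t_max)
    t_amp = 0.5 * (spec.t_max - spec.t_min)
    tair = t_mean + t_amp * np.sin(2.0 * np.pi * (t - 9.0) / 24.0)  # max ~15 h
    vpd = (1.0 - spec.rh) * saturation_vapour_pressure(tair)
    logger.debug("generated weather day: %s (seed=%d)", spec.day_type, spec.seed)
    return pd.DataFrame(
        {
            "time_h": t,
            "ppfd_umol_m2_s": ppfd,
            "tair_c": tair,
            "vpd_kpa": vpd,
            "ca_umol_mol": np.full_like(t, spec.ca),
        }
    )


# ---------------------------------------------------------------------------
# Synthetic A–Ci curves and N profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ACiCurve:
    """Paired (Ci, A) observations for one leaf with cuvette metadata.

    Measurement conditions default to the standard protocol: saturating
    PPFD 1500 µmol m⁻² s⁻¹ and leaf temperature 25 °C, with day
    respiration measured separately (``rd``), not fitted.
    """

    data: pd.DataFrame           # ci_umol_mol, a_umol_m2_s
    tleaf: float = 25.0
    ppfd: float = 1500.0
    rd: float = 1.0
    true_params: PhotoParams25 | None = None  # set by the generator

    def __post_init__(self) -> None:
        missing = [c for c in ACI_COLUMNS if c not in self.data.columns]
        if missing:
            raise InputError(f"A-Ci table missing columns: {missing}")
        if len(self.data) < 6:
            raise InputError("A-Ci curve needs >= 6 points")
        ci = self.data["ci_umol_mol"]
        if ci.min() >= 300.0 or ci.max() <= 400.0:
            logger.warning(
                "A-Ci curve spans [%.0f, %.0f] umol/mol; sub- and supra-ambient "
                "coverage is needed for identifiability", ci.min(), ci.max()
            )


#: Default Ci ladder emulating a stepped-Ca cuvette protocol (µmol mol⁻¹).
DEFAULT_CI_LEVELS = (50, 80, 120, 170, 230, 300, 400, 550, 700, 900, 1100, 1400)


def generate_synthetic_aci(
    p25: PhotoParams25,
    ci_levels=DEFAULT_CI_LEVELS,
    noise_sd: float = 0.0,
    seed: int = 0,
    rd: float | None = None,
    kc: KineticConstants | None = None,
    tleaf: float = 25.0,
    ppfd: float = 1500.0,
) -> ACiCurve:
    """Forward-model an A–Ci curve with optional Gaussian noise.

    ``rd`` defaults to the generating ``p25.rd25``; the true parameters
    are stored on the curve for recovery tests.
    """
    kc = kc or KineticConstants()
    rng = np.random.default_rng(seed)
    rd_val = p25.rd25 if rd is None else rd
    pt = adjust_photo_params(
        PhotoParams25(p25.vcmax25, p25.jmax25, p25.tpu25, rd_val), kc, tleaf
    )
    ci = np.asarray(ci_levels, dtype=float)
    a = np.array([net_assimilation_at_ci(c, pt, ppfd)[0] for c in ci])
    if noise_sd > 0:
        a = a + noise_sd * rng.standard_normal(len(ci))
    return ACiCurve(
        data=pd.DataFrame({"ci_umol_mol": ci, "a_umol_m2_s": a}),
        tleaf=tleaf,
        ppfd=ppfd,
        rd=rd_val,
        true_params=p25,
    )


def generate_synthetic_profile(
    nup: float = 2.17,
    kn: float = 0.25,
    lai: float = 3.0,
    n_strata: int = 8,
    k: float = 0.8,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic per-stratum leaf-N table (10-cm strata convention).

    Relative irradiance comes from Beer–Lambert midpoints; Na from the
    light–N profile plus Gaussian noise, clamped positive.
    """
    if nup <= 0 or lai <= 0 or n_strata < 1 or k <= 0:
        raise InputError("nup, lai, n_strata and k must be positive")
    rng = np.random.default_rng(seed)
    dlai = lai / n_strata
    l_mid = (np.arange(n_strata) + 0.5) * dlai
    rel_irr = np.exp(-k * l_mid)
    na = nup * rel_irr**kn
    if noise_sd > 0:
        na = np.clip(na + noise_sd * rng.standard_normal(n_strata), 1e-6, None)
    return pd.DataFrame(
        {
            "stratum_id": np.arange(1, n_strata + 1),
            "depth_cm": (np.arange(n_strata) + 0.5) * 10.0,
            "lai": np.full(n_strata, dlai),
            "rel_irr": rel_irr,
            "na_g_m2": na,
        }
    )


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InputError(f"{what} is missing required column(s): {missing}")


def validate_weather(df: pd.DataFrame) -> None:
    """Check the weather schema: required unit-suffixed columns, strictly
    increasing time, non-negative PPFD."""
    _require_columns(df, WEATHER_COLUMNS, "weather table")
    t = df["time_h"].to_numpy()
    if len(t) >= 2 and np.any(np.diff(t) <= 0):
        raise InputError("weather time_h must be strictly increasing")
    if (df["ppfd_umol_m2_s"] < 0).any():
        raise InputError("weather ppfd_umol_m2_s must be >= 0")


def read_weather_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_weather(df)
    return df[WEATHER_COLUMNS]


def write_weather_csv(df: pd.DataFrame, path) -> None:
    validate_weather(df)
    df[WEATHER_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_strata_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, STRATA_COLUMNS, "strata table")
    if ((df["rel_irr"] <= 0) | (df["rel_irr"] > 1)).any():
        raise InputError("strata rel_irr must lie in (0, 1]")
    return df[STRATA_COLUMNS]


def write_strata_csv(df: pd.DataFrame, path) -> None:
    _require_columns(df, STRATA_COLUMNS, "strata table")
    df[STRATA_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_aci_csv(path) -> ACiCurve:
    """Read an A–Ci CSV; '# key: value' header lines carry the metadata
    (tleaf_c, ppfd_umol_m2_s, rd_umol_m2_s)."""
    meta: dict[str, float] = {}
    body_lines = []
    text = Path(path).read_text(encoding="utf-8")
    for line in text.splitlines():
        if line.startswith("#"):
            if ":" in line:
                key, _, val = line.lstrip("# ").partition(":")
                try:
                    meta[key.strip()] = float(val)
                except ValueError:
                    raise InputError(f"malformed A-Ci metadata line: {line!r}")
        else:
            body_lines.append(line)
    df = pd.read_csv(io.StringIO("\n".join(body_lines)))
    _require_columns(df, ACI_COLUMNS, "A-Ci table")
    return ACiCurve(
        data=df[ACI_COLUMNS],
        tleaf=meta.get("tleaf_c", 25.0),
        ppfd=meta.get("ppfd_umol_m2_s", 1500.0),
        rd=meta.get("rd_umol_m2_s", 1.0),
    )


def write_aci_csv(curve: ACiCurve, path) -> None:
    header = (
        f"# tleaf_c: {curve.tleaf:.12g}\n"
        f"# ppfd_umol_m2_s: {curve.ppfd:.12g}\n"
        f"# rd_umol_m2_s: {curve.rd:.12g}\n"
    )
    body = curve.data[ACI_COLUMNS].to_csv(index=False, float_format=_FLOAT_FMT)
    Path(path).write_text(header + body, encoding="utf-8")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Aggregated run configuration with documented defaults.

    Blocks mirror the parameter dataclasses: ``kinetics`` (FvCB constants),
    ``stomatal``, ``nitrogen`` (profile calibration + Na regressions) and
    ``canopy`` (lai, n_strata, k), plus the coupled-solver Ci tolerance
    and the random seed used by the generators.
    """

    kinetics: KineticConstants = KineticConstants()
    stomatal: StomatalParams = StomatalParams()
    nitrogen: NDistributionParams = NDistributionParams()
    lai: float = 3.0
    n_strata: int = 8
    k: float = 0.8
    ci_tol: float = 1e-6
    seed: int = 0


_CANOPY_KEYS = {"lai", "n_strata", "k"}
_SOLVER_KEYS = {"ci_tol"}


def _build_block(cls, block: dict, name: str):
    valid = {f.name for f in fields(cls)}
    unknown = set(block) - valid
    if unknown:
        raise InputError(f"unknown key(s) in config block '{name}': {sorted(unknown)}")
    return cls(**block)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys at any level."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise InputError("config root must be a mapping")
    known = {"kinetics", "stomatal", "nitrogen", "canopy", "solver", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise InputError(f"unknown top-level config key(s): {sorted(unknown)}")

    cfg = RunConfig(
        kinetics=_build_block(KineticConstants, raw.get("kinetics", {}) or {}, "kinetics"),
        stomatal=_build_block(StomatalParams, raw.get("stomatal", {}) or {}, "stomatal"),
        nitrogen=_build_block(NDistributionParams, raw.get("nitrogen", {}) or {}, "nitrogen"),
    )
    canopy_block = raw.get("canopy", {}) or {}
    unknown = set(canopy_block) - _CANOPY_KEYS
    if unknown:
        raise InputError(f"unknown key(s) in config block 'canopy': {sorted(unknown)}")
    solver_block = raw.get("solver", {}) or {}
    unknown = set(solver_block) - _SOLVER_KEYS
    if unknown:
        raise InputError(f"unknown key(s) in config block 'solver': {sorted(unknown)}")
    return replace(
        cfg,
        lai=float(canopy_block.get("lai", cfg.lai)),
        n_strata=int(canopy_block.get("n_strata", cfg.n_strata)),
        k=float(canopy_block.get("k", cfg.k)),
        ci_tol=float(solver_block.get("ci_tol", cfg.ci_tol)),
        seed=int(raw.get("seed", cfg.seed)),
    )
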