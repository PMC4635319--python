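"""Parameter estimation and model-evaluation statistics.

* Whole-curve A–Ci fitting: (Vcmax25, Jmax25, TPU25) estimated
  simultaneously by nonlinear least squares against the full curve, with
  the limiting branch chosen as the FvCB minimum inside the objective and
  day respiration fixed from its separate measurement.  A coarse
  multi-start grid guards against the local minima created by branch
  switching; TPU is flagged unidentifiable when no observation is
  TPU-limited at the optimum.
* Light–N profile fitting: (Nup, kN) by nonlinear least squares on the
  raw scale.
* Ordinary least-squares regression for the linear calibrations, and the
  evaluation statistics RMSE = sqrt(Σ(sᵢ−mᵢ)²/n) and
  Bias = Σ(sᵢ−mᵢ)/n (simulated minus measured, so over-prediction gives a
  positive bias).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import ConvergenceError, InputError
from .io_fixtures import ACiCurve
from .leaf_biochem import (
    KineticConstants,
    PhotoParams25,
    adjust_photo_params,
    net_assimilation_at_ci,
)

__all__ = [
    "FitResult",
    "fit_aci_curve",
    "fit_na_profile",
    "linear_regression",
    "rmse",
    "bias",
]


@dataclass(frozen=True)
class FitResult:
    """Estimates, uncertainties and diagnostics from one fit."""

    params: dict[str, float]
    se: dict[str, float]
    sse: float
    r2: float
    converged: bool
    limitation: tuple[str, ...] = ()      # per-point branch (A–Ci fits)
    flags: dict[str, bool] = field(default_factory=dict)


def _se_from_jacobian(jac: np.ndarray, resid: np.ndarray, n_params: int) -> np.ndarray:
    """Asymptotic standard errors from the Gauss–Newton approximation."""
    n = len(resid)
    dof = max(n - n_params, 1)
    s2 = float(resid @ resid) / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(n_params, np.nan)


def _r2(obs: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


#: Multi-start grid for Vcmax; Jmax and TPU start at typical ratios.
_VCMAX_STARTS = np.arange(20.0, 201.0, 30.0)
_JMAX_RATIO = 1.7
_TPU_RATIO = 1.0 / 9.0


def fit_aci_curve(
    curve: ACiCurve,
    kc: KineticConstants | None = None,
    fit_rd: bool = False,
) -> FitResult:
    """Fit (Vcmax25, Jmax25, TPU25) to a whole A–Ci curve.

    ``curve.rd`` is held fixed (measured night respiration) unless
    ``fit_rd`` is set.  Curves are assumed measured at the curve's stated
    leaf temperature (the 25 °C protocol), so estimates are 25 °C values
    after inverting the temperature adjustment is unnecessary at 25 °C.
    """
    kc = kc or KineticConstants()
    ci = curve.data["ci_umol_mol"].to_numpy(dtype=float)
    a_obs = curve.data["a_umol_m2_s"].to_numpy(dtype=float)
    if np.any(ci <= 0):
        raise InputError("A-Ci curve contains non-positive Ci")

    def model(theta: np.ndarray) -> np.ndarray:
        vcmax, jmax, tpu = theta[:3]
        rd = theta[3] if fit_rd else curve.rd
        pt = adjust_photo_params(
            PhotoParams25(vcmax, jmax, tpu, rd), kc, curve.tleaf
        )
        return np.array(
            [net_assimilation_at_ci(c, pt, curve.ppfd)[0] for c in ci]
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        return model(theta) - a_obs

    n_par = 4 if fit_rd else 3
    lower = np.zeros(n_par)
    upper = np.full(n_par, np.inf)

    best = None
    for v0 in _VCMAX_STARTS:
        x0 = [v0, _JMAX_RATIO * v0, _JMAX_RATIO * v0 * _TPU_RATIO]
        if fit_rd:
            x0.append(max(curve.rd, 0.1))
        try:
            sol = optimize.least_squares(
                residuals, x0, bounds=(lower, upper), method="trf", xtol=1e-12
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise ConvergenceError("A-Ci fit failed from every start", {"curve": curve})

    theta = best.x
    resid = best.fun
    se = _se_from_jacobian(best.jac, resid, n_par)
    pred = model(theta)

    # per-point limitation at the optimum; flatness of the TPU direction
    pt = adjust_photo_params(
        PhotoParams25(theta[0], theta[1], theta[2], theta[3] if fit_rd else curve.rd),
        kc,
        curve.tleaf,
    )
    limitation = tuple(
        net_assimilation_at_ci(c, pt, curve.ppfd)[1].value for c in ci
    )
    tpu_identifiable = "tpu" in limitation

    names = ["vcmax25", "jmax25", "tpu25"] + (["rd25"] if fit_rd else [])
    return FitResult(
        params=dict(zip(names, map(float, theta))),
        se=dict(zip(names, map(float, se))),
        sse=float(resid @ resid),
        r2=_r2(a_obs, pred),
        converged=bool(best.success),
        limitation=limitation,
        flags={"tpu_identifiable": tpu_identifiable},
    )


def fit_na_profile(rel_irr, na) -> FitResult:
    """Fit the light–N profile ``Na = Nup · rel_irr^kN`` to strata data.

    Nonlinear least squares on the raw scale; initialization
    Nup = max(Na), kN = 0.2; standard errors from the Jacobian.
    """
    x = np.asarray(rel_irr, dtype=float)
    y = np.asarray(na, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("rel_irr and na must be 1-D arrays of equal length")
    if len(x) < 3:
        raise InputError("profile fit needs >= 3 strata")
    if np.any((x <= 0) | (x > 1)):
        raise InputError("rel_irr must lie in (0, 1]")

    def f(xv, nup, kn):
        return nup * xv**kn

    try:
        popt, pcov = optimize.curve_fit(
            f, x, y, p0=[float(y.max()), 0.2],
            bounds=([0.0, 0.0], [np.inf, 5.0]), maxfev=10000,
        )
    except RuntimeError as err:
        raise ConvergenceError(f"profile fit did not converge: {err}")
    pred = f(x, *popt)
    resid = pred - y
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return FitResult(
        params={"nup": float(popt[0]), "kn": float(popt[1])},
        se={"nup": float(se[0]), "kn": float(se[1])},
        sse=float(resid @ resid),
        r2=_r2(y, pred),
        converged=True,
    )


def linear_regression(x, y) -> FitResult:
    """Ordinary least-squares line fit; slope, intercept and r²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise InputError("linear regression needs n >= 3")
    if np.ptp(x) == 0.0:
        raise InputError("x has zero variance")
    res = stats.linregress(x, y)
    pred = res.slope * x + res.intercept
    resid = pred - y
    return FitResult(
        params={"slope": float(res.slope), "intercept": float(res.intercept)},
        se={"slope": float(res.stderr), "intercept": float(res.intercept_stderr)},
        sse=float(resid @ resid),
        r2=float(res.rvalue**2),
        converged=True,
    )


def _paired(simulated, measured) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(simulated, dtype=float)
    m = np.asarray(measured, dtype=float)
    if s.shape != m.shape:
        raise InputError("simulated and measured must have equal length")
    if s.size < 1:
        raise InputError("need at least one observation")
    return s, m


def rmse(simulated, measured) -> float:
    """Root mean square error of simulated against measured values."""
    s, m = _paired(simulated, measured)
    return float(np.sqrt(np.mean((s - m) ** 2)))


def bias(simulated, measured) -> float:
    """Mean signed error (simulated − measured); over-prediction > 0."""
    s, m = _paired(simulated, measured)
    return float(np.mean(s - m))
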