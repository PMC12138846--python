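"""Moderated-exponential intensity-decay model and the speed conversion.

The fluorescence collected by the fiber tracks the number of microtubules
on its core.  That population decays exponentially as filaments glide off
the core, moderated by a second term for filaments re-joining it (returns
from the cladding, re-landing from suspension):

    I_rel(t) = (1 - Z) * exp(-Lambda * t) + Z

with decay constant Lambda (1/s) and re-joining factor Z in [0, 1).  The
decay constant is proportional to the gliding speed,

    V = Lambda * r * H

where r is the fiber core radius and H a dimensionless calibration
constant recovered by regressing independently measured speeds against
Lambda * r.  Together these give a microscope-free speed readout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "DecayParams",
    "DecayFit",
    "SpeedCalibration",
    "relative_intensity",
    "fit_decay",
    "speed_from_lambda",
    "calibrate_H",
    "speed_difference",
    "FitConvergenceError",
    "InsufficientDataError",
]

_Z_MAX = 0.999  # open upper bound for the re-joining factor


class FitConvergenceError(RuntimeError):
    """Nonlinear fit failed to converge; carries the best iterate."""

    def __init__(self, message: str, best: "DecayFit | None" = None):
        super().__init__(message)
        self.best = best


class InsufficientDataError(ValueError):
    """Too few points for the requested operation."""


@dataclass(frozen=True)
class DecayParams:
    """Parameters of the moderated-exponential decay."""

    I0: float = 1.0
    Lambda: float = 0.0
    Z: float = 0.0

    def __post_init__(self) -> None:
        if not (self.I0 > 0):
            raise ValueError("I0 must be positive")
        if self.Lambda < 0 or not math.isfinite(self.Lambda):
            raise ValueError("Lambda must be finite and >= 0")
        if not (0.0 <= self.Z < 1.0):
            raise ValueError("Z must lie in [0, 1)")


def relative_intensity(t, params: DecayParams) -> np.ndarray | float:
    """Evaluate I_rel(t) = (1 - Z) exp(-Lambda t) + Z for t >= 0."""
    t = np.asarray(t, dtype=float)
    out = (1.0 - params.Z) * np.exp(-params.Lambda * t) + params.Z
    return float(out) if out.ndim == 0 else out


@dataclass
class DecayFit:
    """Result of fitting the decay model to one intensity curve."""

    params: DecayParams
    std_errors: dict
    r_squared: float
    residuals: np.ndarray
    converged: bool = True

    @property
    def stderr_lambda(self) -> float:
        return self.std_errors["Lambda"]

    @property
    def stderr_z(self) -> float:
        return self.std_errors["Z"]

    def to_dict(self) -> dict:
        return {
            "lambda": self.params.Lambda,
            "z": self.params.Z,
            "i0": self.params.I0,
            "stderr_lambda": self.stderr_lambda,
            "stderr_z": self.stderr_z,
            "r2": self.r_squared,
            "converged": self.converged,
        }


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Deterministic start: Lambda from the log-slope of the first half of
    the curve, Z from the last observed value."""
    z0 = float(np.clip(y[-1], 0.0, 0.95))
    half = max(4, len(t) // 2)
    th, yh = t[:half], y[:half]
    positive = yh > z0 + 1e-9
    lam0 = 1e-4
    if positive.sum() >= 2:
        logy = np.log(yh[positive] - z0 + 1e-12)
        slope = np.polyfit(th[positive], logy, 1)[0]
        lam0 = max(-slope, 1e-6)
    return lam0, z0


def fit_decay(
    curve, free_i0: bool = False, n_bootstrap: int = 0, bootstrap_seed: int = 0
) -> DecayFit:
    """Fit (Lambda, Z) to an averaged intensity curve by bounded least squares.

    ``curve`` is anything with ``window_centers`` and ``mean_intensity``
    attributes (an :class:`~fiberglide.acquisition.AveragedCurve`) or a
    ``(times, intensities)`` pair.  Intensities are normalised to the first
    point, which estimates I0; with ``free_i0`` the amplitude is fitted as
    a third parameter instead.

    Standard errors come from the Jacobian-based covariance at the optimum;
    with ``n_bootstrap`` > 0 they are instead estimated by residual
    resampling (refitting ``n_bootstrap`` synthetic curves, seeded).
    Raises :class:`InsufficientDataError` below four points and
    :class:`FitConvergenceError` (carrying the best iterate) on failure.
    """
    if hasattr(curve, "window_centers"):
        t = np.asarray(curve.window_centers, dtype=float)
        y_raw = np.asarray(curve.mean_intensity, dtype=float)
    else:
        t, y_raw = (np.asarray(a, dtype=float) for a in curve)
    if t.size < 4:
        raise InsufficientDataError("decay fit needs at least 4 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    i0 = float(y_raw[0])
    if i0 <= 0:
        raise ValueError("first intensity must be positive to normalise")
    y = y_raw / i0
    t0 = t - t[0]

    lam0, z0 = _initial_guess(t0, y)

    if free_i0:
        def model(p):
            a, lam, z = p
            return a * ((1.0 - z) * np.exp(-lam * t0) + z)
        x0 = np.array([1.0, lam0, z0])
        lower = np.array([1e-12, 0.0, 0.0])
        upper = np.array([np.inf, np.inf, _Z_MAX])
        names = ("I0", "Lambda", "Z")
    else:
        def model(p):
            lam, z = p
            return (1.0 - z) * np.exp(-lam * t0) + z
        x0 = np.array([lam0, z0])
        lower = np.array([0.0, 0.0])
        upper = np.array([np.inf, _Z_MAX])
        names = ("Lambda", "Z")

    res = optimize.least_squares(
        lambda p: model(p) - y, x0, bounds=(lower, upper), method="trf", xtol=1e-14, ftol=1e-14
    )

    dof = max(t.size - len(x0), 1)
    s2 = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj) * s2
        perr = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        perr = np.full(len(x0), np.nan)
    residuals = y - model(res.x)

    if n_bootstrap > 0:
        rng = np.random.default_rng(bootstrap_seed)
        fitted = model(res.x)
        draws = []
        for _ in range(n_bootstrap):
            y_star = fitted + rng.choice(residuals, size=residuals.size, replace=True)
            r_star = optimize.least_squares(
                lambda p: model(p) - y_star, res.x, bounds=(lower, upper), method="trf"
            )
            draws.append(r_star.x)
        perr = np.std(np.asarray(draws), axis=0, ddof=1)
    std_errors = dict(zip(names, perr))
    std_errors.setdefault("I0", 0.0)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(residuals**2)) / ss_tot if ss_tot > 0 else 1.0

    if free_i0:
        params = DecayParams(I0=i0 * res.x[0], Lambda=res.x[1], Z=min(res.x[2], _Z_MAX))
    else:
        params = DecayParams(I0=i0, Lambda=res.x[0], Z=min(res.x[1], _Z_MAX))
    fit = DecayFit(
        params=params,
        std_errors=std_errors,
        r_squared=r2,
        residuals=residuals,
        converged=bool(res.success),
    )
    if not res.success:
        raise FitConvergenceError(f"decay fit did not converge: {res.message}", best=fit)
    return fit


@dataclass(frozen=True)
class SpeedCalibration:
    """Calibration linking the decay constant to gliding speed, V = Lambda r H."""

    H: float
    r: float = 100.0
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.H > 0):
            raise ValueError("H must be positive")
        if not (self.r > 0):
            raise ValueError("r must be positive")


def speed_from_lambda(Lambda: float, cal: SpeedCalibration) -> float:
    """Convert a decay constant (1/s) to a gliding speed in nm/s."""
    if Lambda < 0:
        raise ValueError("Lambda must be >= 0")
    return Lambda * cal.r * cal.H * 1e3  # µm/s -> nm/s


class DegenerateCalibrationError(ValueError):
    """All decay constants are zero; H is unidentifiable."""


def calibrate_H(pairs, r: float) -> SpeedCalibration:
    """Estimate H from paired (Lambda in 1/s, speed in nm/s) measurements.

    Least-squares regression of V on Lambda * r through the origin (the
    speed law has no intercept).  Speeds must come from an independent
    measurement (tracking software or simulation ground truth).
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 1:
        raise ValueError("pairs must be an (n, 2) array of (Lambda, V)")
    lam = pairs[:, 0]
    v_um = pairs[:, 1] * 1e-3  # nm/s -> µm/s, matching Lambda * r units
    x = lam * r
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise DegenerateCalibrationError("all Lambda values are zero")
    h = float(np.sum(x * v_um) / sxx)
    ss_res = float(np.sum((v_um - h * x) ** 2))
    ss_tot = float(np.sum(v_um**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SpeedCalibration(H=h, r=r, r_squared=r2)


def speed_difference(
    fitA: DecayFit, fitB: DecayFit, cal: SpeedCalibration
) -> tuple[float, float]:
    """Speed difference between two fitted curves, with propagated error.

    Returns ``(delta_v, sigma_delta_v)`` in nm/s where
    delta_v = (Lambda_A - Lambda_B) * r * H and the uncertainty combines
    the two Lambda standard errors in quadrature.
    """
    scale = cal.r * cal.H * 1e3
    dv = (fitA.params.Lambda - fitB.params.Lambda) * scale
    sigma = scale * math.hypot(fitA.stderr_lambda, fitB.stderr_lambda)
    return dv, sigma
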