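"""Distance, velocity and percent-velocity curves, and their landmarks.

Velocity is the first derivative of the fitted distance curve against
age in years; under the log-age transform the chain rule gives
dy/dt = (dy/dx) / t.  Percent velocity is 100 d(ln y)/dt = 100 v / y,
which removes scale differences between measurements.  Landmarks are
the pubertal peak (APV, PV) and takeoff (the velocity minimum
immediately before the peak).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import SitarFit, RandomEffectTriple, ZERO_RE, predict_curve
from .splines import basis_derivative

__all__ = [
    "CurveGrid",
    "Landmarks",
    "default_grid",
    "velocity_curve",
    "percent_velocity_curve",
    "find_landmarks",
    "fit_landmarks",
    "value_at_age",
]


@dataclass
class CurveGrid:
    """A curve evaluated on a dense age grid (years)."""

    ages: np.ndarray
    values: np.ndarray
    scale: str  # "cm", "cm/yr" or "%/yr"

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.ages.ndim != 1 or self.ages.shape != self.values.shape:
            raise ValueError("grid and values must be 1-d and matched")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("age grid must be strictly increasing")


@dataclass
class Landmarks:
    """Takeoff and peak of a velocity curve."""

    age_takeoff: float | None
    age_peak: float | None
    vel_takeoff: float | None
    vel_peak: float | None
    scale: str = "cm/yr"
    peak_found: bool = True
    takeoff_found: bool = True


def default_grid(fit: SitarFit, n_points: int = 1000, trim: float = 0.02) -> np.ndarray:
    """Dense age grid over the observed range, trimmed at each end.

    The 2% trim avoids boundary artefacts from the linear tails of the
    spline.
    """
    lo, hi = fit.age_range
    span = hi - lo
    return np.linspace(lo + trim * span, hi - trim * span, n_points)


def velocity_curve(fit: SitarFit, re: RandomEffectTriple = ZERO_RE, ages=None) -> CurveGrid:
    """Analytic velocity (cm/yr) of the curve for random effects ``re``."""
    if ages is None:
        ages = default_grid(fit)
    ages = np.asarray(ages, dtype=float)
    x = fit.to_axis(ages)
    scale = np.exp(fit.gamma0 + re.gamma)
    s = (x - fit.beta0 - re.beta) * scale
    dy_ds = basis_derivative(s, fit.spec) @ fit.spline_coefs[1:]
    dx_dt = 1.0 / ages if fit.spec.use_log_age else np.ones_like(ages)
    return CurveGrid(ages, dy_ds * scale * dx_dt, "cm/yr")


def percent_velocity_curve(fit: SitarFit, ages=None) -> CurveGrid:
    """Mean-curve velocity in percent units, 100 v(t) / y(t)."""
    if ages is None:
        ages = default_grid(fit)
    ages = np.asarray(ages, dtype=float)
    y = predict_curve(fit, ZERO_RE, ages)
    if np.any(y <= 0):
        raise ValueError("percent velocity undefined: mean curve non-positive on grid")
    v = velocity_curve(fit, ZERO_RE, ages).values
    return CurveGrid(ages, 100.0 * v / y, "%/yr")


def _quad_refine(a: np.ndarray, v: np.ndarray, i: int) -> tuple:
    """Vertex of the parabola through three grid points around index i."""
    x0, x1, x2 = a[i - 1], a[i], a[i + 1]
    y0, y1, y2 = v[i - 1], v[i], v[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    A = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    B = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if A == 0:
        return float(x1), float(y1)
    xv = -B / (2 * A)
    if not (x0 <= xv <= x2):
        return float(x1), float(y1)
    C = y1 - A * x1**2 - B * x1
    return float(xv), float(A * xv**2 + B * xv + C)


def find_landmarks(curve: CurveGrid, search_window: tuple | None = None) -> Landmarks:
    """Peak and takeoff landmarks of a velocity curve.

    The peak is the global interior maximum on the window, refined by a
    three-point parabola; takeoff is the interior minimum before the
    peak, refined the same way.  Monotone curves (no interior maximum)
    return ``peak_found=False`` — the "no peak" case of small
    measurements.  Equal maxima resolve to the earliest age.
    """
    a, v = curve.ages, curve.values
    if search_window is not None:
        lo, hi = search_window
        mask = (a >= lo) & (a <= hi)
        if mask.sum() < 3:
            raise ValueError("empty or too-narrow search window")
        a, v = a[mask], v[mask]

    ipk = int(np.argmax(v))  # argmax takes the earliest of ties
    if ipk == 0 or ipk == len(v) - 1:
        return Landmarks(None, None, None, None, curve.scale, False, False)
    age_pk, vel_pk = _quad_refine(a, v, ipk)

    itk = int(np.argmin(v[: ipk + 1]))
    if itk == 0 or itk == ipk:
        return Landmarks(None, age_pk, None, vel_pk, curve.scale, True, False)
    age_tk, vel_tk = _quad_refine(a, v, itk)
    return Landmarks(age_tk, age_pk, vel_tk, vel_pk, curve.scale, True, True)


def fit_landmarks(
    fit: SitarFit,
    scale: str = "cm/yr",
    search_window: tuple | None = None,
    n_points: int = 1000,
) -> Landmarks:
    """Landmarks of a fit's mean velocity curve on the cm or % scale."""
    grid = default_grid(fit, n_points)
    curve = percent_velocity_curve(fit, grid) if scale == "%/yr" else velocity_curve(fit, ZERO_RE, grid)
    return find_landmarks(curve, search_window)


def value_at_age(fit: SitarFit, age: float) -> float:
    """Mean-curve value at an age (e.g. size at 19)."""
    return float(predict_curve(fit, ZERO_RE, np.atleast_1d(float(age)))[0])
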