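"""Synthetic longitudinal cohorts from the SITAR generative model.

The mean curve is a sigmoid-plus-decay template (the Preece-Baines
model-1 family), whose closed-form velocity lets APV, PV and takeoff be
computed to high precision, so every simulation carries analytic ground
truth.  Subjects get trivariate-normal (size, timing, intensity) random
effects, visit schedules follow one of two study designs — a
growth-study design with 6-monthly visits outside puberty and 3-monthly
visits inside a subject-specific pubertal window, or a birth-cohort
design with nine sweeps (annual to 13.5, then 15 and 17) — and Gaussian
residual noise is added on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .data import GrowthData
from .splines import SplineSpec, build_basis, basis_derivative, place_knots

__all__ = [
    "MeanCurve",
    "SplineCurve",
    "make_mean_curve",
    "spline_project_curve",
    "TrueParams",
    "DesignSpec",
    "simulate_cohort",
]


def _velocity_landmarks(velocity_fn, window) -> dict:
    """Takeoff/peak of an analytic velocity function by bounded search."""
    lo, hi = window
    grid = np.linspace(lo, hi, 4001)
    v = velocity_fn(grid)
    ipk = int(np.argmax(v))
    if ipk == 0 or ipk == len(grid) - 1:
        return {"apv": None, "pv": None, "age_takeoff": None, "vel_takeoff": None}
    res = optimize.minimize_scalar(
        lambda t: -velocity_fn(t), bounds=(grid[ipk - 1], grid[ipk + 1]), method="bounded",
        options={"xatol": 1e-10},
    )
    apv, pv = float(res.x), float(-res.fun)
    itk = int(np.argmin(v[: ipk + 1]))
    if itk == 0 or itk == ipk:
        return {"apv": apv, "pv": pv, "age_takeoff": None, "vel_takeoff": None}
    res = optimize.minimize_scalar(
        velocity_fn, bounds=(grid[itk - 1], grid[itk + 1]), method="bounded",
        options={"xatol": 1e-10},
    )
    return {"apv": apv, "pv": pv, "age_takeoff": float(res.x), "vel_takeoff": float(res.fun)}


@dataclass(frozen=True)
class MeanCurve:
    """Preece-Baines model-1 curve: y(t) = h1 - 2(h1-htheta)/(e^{s0 d} + e^{s1 d}).

    ``h1`` is the adult asymptote (cm), ``htheta`` the size at ``theta``
    (yr), and ``s0 < s1`` the pre- and intra-pubertal rate constants
    (/yr).  ``s1 == s0`` degenerates to a logistic with no interior
    velocity peak.
    """

    h1: float
    htheta: float
    s0: float
    s1: float
    theta: float

    def value(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        d = t - self.theta
        denom = np.exp(self.s0 * d) + np.exp(self.s1 * d)
        return self.h1 - 2.0 * (self.h1 - self.htheta) / denom

    def velocity(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        d = t - self.theta
        e0, e1 = np.exp(self.s0 * d), np.exp(self.s1 * d)
        return 2.0 * (self.h1 - self.htheta) * (self.s0 * e0 + self.s1 * e1) / (e0 + e1) ** 2

    def __call__(self, t):
        return self.value(t)

    def landmarks(self, window=(7.5, 19.0)) -> dict:
        """APV, PV, takeoff age and velocity by high-precision search."""
        return _velocity_landmarks(self.velocity, window)


def make_mean_curve(
    adult_size: float,
    target_apv: float,
    target_pv: float,
    prepubertal_velocity: float,
    prepubertal_age: float = 8.0,
) -> MeanCurve:
    """Calibrate a mean curve to target landmarks.

    Solves for a curve with asymptotic size ``adult_size`` whose age at
    peak velocity, peak velocity, and velocity at ``prepubertal_age``
    match the targets.  The solution is checked to 0.02 yr (APV) and
    0.05 cm/yr (PV); infeasible target combinations raise.
    """
    if not (9.0 < target_apv < 16.0):
        raise ValueError("target_apv must lie in (9, 16) years")
    if target_pv <= prepubertal_velocity:
        raise ValueError("target peak velocity must exceed the prepubertal velocity")

    def unpack(z):
        ls0, ls1, theta, frac = z
        htheta = adult_size * (0.80 + 0.19 / (1 + np.exp(-frac)))
        return MeanCurve(adult_size, htheta, np.exp(ls0), np.exp(ls1), theta)

    def residuals(z):
        curve = unpack(z)
        lm = curve.landmarks(window=(max(6.0, target_apv - 6.0), target_apv + 5.0))
        if lm["apv"] is None:
            return np.array([10.0, 10.0, 10.0, 0.0])
        return np.array(
            [
                lm["apv"] - target_apv,
                lm["pv"] - target_pv,
                float(curve.velocity(prepubertal_age)) - prepubertal_velocity,
                0.02 * (z[3] - 0.8),  # weak pin on htheta/adult ratio
            ]
        )

    z0 = np.array([np.log(0.11), np.log(1.1), target_apv + 0.4, 0.8])
    sol = optimize.least_squares(residuals, z0, xtol=1e-12, ftol=1e-12)
    curve = unpack(sol.x)
    lm = curve.landmarks()
    if lm["apv"] is None or abs(lm["apv"] - target_apv) > 0.02 or abs(lm["pv"] - target_pv) > 0.05:
        raise ValueError(
            f"mean-curve calibration failed for targets "
            f"(adult={adult_size}, apv={target_apv}, pv={target_pv}, "
            f"prepubertal={prepubertal_velocity})"
        )
    return curve


@dataclass(frozen=True)
class SplineCurve:
    """A natural-cubic-spline mean curve of age with analytic velocity.

    Used as a generative truth that the fitted model can represent
    exactly (correct specification), so landmark-recovery checks are
    free of template-approximation error.
    """

    spec: SplineSpec
    coefs: tuple  # df+1 values including the intercept

    def value(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        x = np.log(t) if self.spec.use_log_age else t
        B = np.column_stack([np.ones(x.size), build_basis(x, self.spec)])
        return (B @ np.asarray(self.coefs)).reshape(np.shape(t))

    def velocity(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        x = np.log(t) if self.spec.use_log_age else t
        dy_dx = basis_derivative(x, self.spec) @ np.asarray(self.coefs)[1:]
        return (dy_dx / t if self.spec.use_log_age else dy_dx).reshape(np.shape(t))

    def __call__(self, t):
        return self.value(t)

    def landmarks(self, window=(7.5, 19.0)) -> dict:
        return _velocity_landmarks(self.velocity, window)


def spline_project_curve(template, ages, df: int, use_log_age: bool = True) -> SplineCurve:
    """Least-squares projection of a template curve onto a spline basis.

    ``ages`` (years) supplies both the knot quantiles and the projection
    weights, so the returned curve lives in the same function space a
    model fitted to data on that design would use.
    """
    ages = np.asarray(ages, dtype=float)
    x = np.log(ages) if use_log_age else ages
    spec = place_knots(x, df, use_log_age=use_log_age)
    B = np.column_stack([np.ones(len(x)), build_basis(x, spec)])
    c, *_ = np.linalg.lstsq(B, template.value(ages), rcond=None)
    return SplineCurve(spec, tuple(float(v) for v in c))


@dataclass
class TrueParams:
    """Generative parameters: mean curve, RE covariance, residual SD.

    ``re_cov_true`` is the 3x3 covariance of (size cm, timing, intensity)
    with timing in log-age units when ``use_log_age`` (the generative
    and fitted parameterisations then coincide).
    """

    mean_curve: MeanCurve
    re_cov_true: np.ndarray
    sigma_r_true: float
    use_log_age: bool = True
    axis_center: float | None = None  # rotation centre on the axis; default (log) 13 yr

    def __post_init__(self):
        if self.axis_center is None:
            self.axis_center = float(np.log(13.0)) if self.use_log_age else 13.0
        self.re_cov_true = np.asarray(self.re_cov_true, dtype=float)
        if self.re_cov_true.shape != (3, 3):
            raise ValueError("re_cov_true must be 3x3")
        eig = np.linalg.eigvalsh(self.re_cov_true)
        if eig[0] < -1e-10:
            raise ValueError("re_cov_true must be positive semidefinite")

    def subject_curve(self, ages, alpha, beta, gamma) -> np.ndarray:
        """Noise-free subject curve: alpha + m at the shifted/scaled age.

        The intensity scaling acts about ``axis_center`` (as in the
        fitted model, whose axis is mean-centred), so gamma compresses
        or stretches the age scale around mid-adolescence rather than
        about age zero.
        """
        ages = np.asarray(ages, dtype=float)
        c0 = self.axis_center
        if self.use_log_age:
            s = c0 + (np.log(ages) - c0 - beta) * np.exp(gamma)
            return alpha + self.mean_curve(np.exp(s))
        s = c0 + (ages - c0 - beta) * np.exp(gamma)
        return alpha + self.mean_curve(s)

    def subject_apv(self, beta, gamma) -> float:
        """Age at peak velocity of a subject's noise-free curve (years)."""
        apv0 = self.mean_curve.landmarks()["apv"]
        c0 = self.axis_center
        if self.use_log_age:
            return float(np.exp(c0 + beta + (np.log(apv0) - c0) * np.exp(-gamma)))
        return float(c0 + beta + (apv0 - c0) * np.exp(-gamma))


@dataclass
class DesignSpec:
    """Visit schedule design for a simulated cohort.

    ``mode`` is "growth_study" (6-monthly outside puberty, 3-monthly in
    a +-2 yr window around the subject's own APV, with staggered entry
    and exit) or "cohort_sweeps" (nine sweeps: annual 7.5-13.5 plus 15
    and 17, with a per-subject sweep-age offset).  ``dropout`` is the
    per-visit missingness probability; every subject keeps >= 1 visit.
    """

    n: int
    mode: str = "growth_study"
    age_window: tuple = (7.0, 20.0)
    dropout: float = 0.15
    visit_jitter: float = 0.1
    seed: int | None = None

    SWEEP_AGES = (7.5, 8.5, 9.5, 10.5, 11.5, 12.5, 13.5, 15.0, 17.0)

    def __post_init__(self):
        if self.mode not in ("growth_study", "cohort_sweeps"):
            raise ValueError(f"unknown design mode {self.mode!r}")
        lo, hi = self.age_window
        if not lo < hi:
            raise ValueError("age window must be increasing")


def _growth_study_visits(rng, design: DesignSpec, apv: float) -> np.ndarray:
    # staggered entry with multi-year follow-up, as in a rolling-recruitment
    # growth study; 6-monthly outside puberty, 3-monthly inside a window
    # centred on the subject's own spurt
    lo, hi = design.age_window
    entry = rng.uniform(lo, 13.0)
    exit_ = min(entry + rng.uniform(3.0, 12.0), hi)
    visits = list(np.arange(entry, exit_, 0.5))
    pub_lo, pub_hi = max(apv - 2.0, entry), min(apv + 2.0, exit_)
    if pub_hi > pub_lo:
        visits.extend(np.arange(pub_lo + 0.25, pub_hi, 0.5))
    return np.sort(np.asarray(visits))


def _sweep_visits(rng, design: DesignSpec) -> np.ndarray:
    offset = rng.uniform(-0.5, 0.5)  # birth-date position within the sweep
    return np.asarray(design.SWEEP_AGES) + offset


def simulate_cohort(truth: TrueParams, design: DesignSpec) -> tuple[GrowthData, pd.DataFrame]:
    """Simulate a cohort; returns the data and the true RE triples.

    Random effects are drawn from N(0, ``truth.re_cov_true``); each
    record is the subject's noise-free curve value plus
    N(0, ``truth.sigma_r_true``^2) noise.  Identical seeds give
    identical cohorts.
    """
    rng = np.random.default_rng(design.seed)
    re = rng.multivariate_normal(np.zeros(3), truth.re_cov_true, size=design.n)
    lo, hi = design.age_window
    eps = 1e-3

    rows = []
    for i in range(design.n):
        alpha, beta, gamma = re[i]
        if design.mode == "growth_study":
            ages = _growth_study_visits(rng, design, truth.subject_apv(beta, gamma))
        else:
            ages = _sweep_visits(rng, design)
        ages = ages + rng.uniform(-design.visit_jitter, design.visit_jitter, size=len(ages))
        ages = ages[(ages > lo + eps) & (ages < hi - eps)]
        keep = rng.random(len(ages)) >= design.dropout
        if not keep.any() and len(ages):
            keep[rng.integers(len(ages))] = True
        ages = np.sort(ages[keep])
        if len(ages) == 0:
            ages = np.array([rng.uniform(lo + 1.0, hi - 1.0)])
        values = truth.subject_curve(ages, alpha, beta, gamma)
        values = values + rng.normal(0.0, truth.sigma_r_true, size=len(ages))
        for a, v in zip(ages, values):
            rows.append((f"S{i + 1:05d}", a, v))

    frame = pd.DataFrame(rows, columns=["id", "age", "value"])
    truth_frame = pd.DataFrame(
        {
            "id": [f"S{i + 1:05d}" for i in range(design.n)],
            "alpha": re[:, 0],
            "beta": re[:, 1],
            "gamma": re[:, 2],
        }
    )
    return GrowthData(frame), truth_frame
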