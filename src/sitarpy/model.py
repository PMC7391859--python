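"""SITAR: a shape-invariant nonlinear mixed-effects growth model.

The model for subject i at age t is

    y_ij = alpha_i + h[(x_ij - beta0 - beta_i) * exp(gamma0 + gamma_i)] + e_ij

where h is a natural cubic spline (with its own intercept), x is age or
log age, and (alpha, beta, gamma) are the subject random effects *size*
(vertical shift, cm), *timing* (horizontal shift on the age axis) and
*intensity* (log age-scaling, dimensionless), jointly normal with
covariance Psi; e ~ N(0, sigma_r^2).

Estimation uses first-order conditional linearization (Lindstrom-Bates):
alternately (a) update the spline coefficients and the subject BLUPs on
the current linearization, and (b) update (Psi, sigma_r) by EM sweeps on
the linearized mixed model.  The fixed effects beta0 and gamma0 are not
free parameters of the optimisation - with an unconstrained spline they
are unidentified - but absorb the BLUP means each iteration, which is an
exact reparameterisation and guarantees mean-zero random effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GrowthData
from .splines import SplineSpec, build_basis, basis_derivative

__all__ = [
    "EFFECTS",
    "RandomEffectTriple",
    "SitarFit",
    "fit_sitar",
    "predict_curve",
    "variance_explained",
    "timing_sd_years",
    "standardized_residuals",
]

EFFECTS = ("size", "timing", "intensity")


@dataclass(frozen=True)
class RandomEffectTriple:
    """Per-subject (size, timing, intensity) effects.

    ``alpha`` in measurement units (cm); ``beta`` on the model's age
    axis (log-age units under the log transform); ``gamma`` a
    dimensionless log-rate.
    """

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma], dtype=float)


ZERO_RE = RandomEffectTriple()


@dataclass
class SitarFit:
    """A fitted SITAR model."""

    spec: SplineSpec
    spline_coefs: np.ndarray          # df+1 values, [0] is the intercept (cm)
    beta0: float
    gamma0: float
    re_cov: np.ndarray                # 3x3 covariance of (size, timing, intensity)
    blups: dict                       # subject id -> RandomEffectTriple
    sigma_r: float
    loglik: float
    n_params: int
    N: int
    n_subjects: int
    converged: bool
    median_age: float                 # years
    median_value: float
    age_range: tuple                  # (min, max) observed age in years
    axis_offset: float = 0.0          # subtracted from the (log-)age axis
    include_effects: tuple = EFFECTS
    fit_log: list = field(default_factory=list)
    loglik_history: list = field(default_factory=list)

    @property
    def re_sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.re_cov))

    @property
    def re_corr(self) -> np.ndarray:
        sd = self.re_sd
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = self.re_cov / np.outer(sd, sd)
        corr[~np.isfinite(corr)] = 0.0
        np.fill_diagonal(corr, 1.0)
        return corr

    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.N)

    def blup_frame(self) -> pd.DataFrame:
        ids = list(self.blups)
        arr = np.array([self.blups[i].as_array() for i in ids])
        return pd.DataFrame({"id": ids, "alpha": arr[:, 0], "beta": arr[:, 1], "gamma": arr[:, 2]})

    def to_axis(self, ages) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        if self.spec.use_log_age:
            if np.any(ages <= 0):
                raise ValueError("ages must be > 0 under the log-age transform")
            return np.log(ages) - self.axis_offset
        return ages - self.axis_offset

    def summary(self) -> dict:
        """Flat key/value report of the fit (model-summary table layout)."""
        sd = self.re_sd
        corr = self.re_corr
        return {
            "subjects": self.n_subjects,
            "points": self.N,
            "median": self.median_value,
            "df": self.spec.df,
            "log_age": self.spec.use_log_age,
            "variance_explained_pct": None,  # needs the data; see variance_explained
            "residual_sd": self.sigma_r,
            "residual_cv_pct": 100.0 * self.sigma_r / self.median_value,
            "size_sd": sd[0],
            "timing_sd": sd[1],
            "timing_sd_years": timing_sd_years(self),
            "intensity_sd": sd[2],
            "corr_size_timing": corr[0, 1],
            "corr_timing_intensity": corr[1, 2],
            "corr_intensity_size": corr[0, 2],
            "loglik": self.loglik,
            "bic": self.bic(),
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# fitting machinery


def _segment_sums(arr: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Per-subject sums of a record-level array (records sorted by subject)."""
    flat = arr.reshape(arr.shape[0], -1)
    out = np.add.reduceat(flat, starts, axis=0)
    return out.reshape((len(starts),) + arr.shape[1:])


def _clip_psd(a: np.ndarray, rel_floor: float = 1e-8) -> np.ndarray:
    """Symmetrize and floor the eigenvalues at a small fraction of the largest."""
    a = 0.5 * (a + a.T)
    vals, vecs = np.linalg.eigh(a)
    floor = max(rel_floor * float(vals[-1]), 1e-14)
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def _ols(X: np.ndarray, y: np.ndarray):
    c, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ c
    return c, resid


def fit_sitar(
    data: GrowthData,
    spec: SplineSpec,
    include_effects=EFFECTS,
    *,
    max_outer: int = 150,
    rel_tol: float = 1e-6,
    _log: list | None = None,
) -> SitarFit:
    """Fit the SITAR model by conditional linearization.

    ``include_effects`` names the random effects to estimate (subset of
    ``("size", "timing", "intensity")``); excluded effects are fixed at
    zero for every subject and carry no variance parameters, as in the
    local models of the grouping pipeline.

    Non-convergence after ``max_outer`` iterations is flagged on the
    returned fit (``converged=False``), never silent.  A singular
    random-effect covariance triggers a refit with the offending effect
    dropped, recorded in ``fit_log``.
    """
    include_effects = tuple(e for e in EFFECTS if e in tuple(include_effects))
    if len(set(include_effects)) != len(tuple(include_effects)):
        raise ValueError("duplicate effects")
    if "measure" in data.frame.columns and data.frame["measure"].nunique() > 1:
        raise ValueError("data holds several measurements; fit one measure at a time")
    log = list(_log) if _log else []

    frame = data.frame.sort_values("id", kind="mergesort").reset_index(drop=True)
    ids = frame["id"].to_numpy()
    t_years = frame["age"].to_numpy(dtype=float)
    y = frame["value"].to_numpy(dtype=float)
    x = np.log(t_years) if spec.use_log_age else t_years.copy()

    # centre the axis so the intensity effect scales age about the mean
    # (log-)age rather than about zero; knots shift with it
    offset = float(np.mean(x))
    x = x - offset
    spec_orig = spec
    spec = SplineSpec(
        df=spec.df,
        interior_knots=tuple(k - offset for k in spec.interior_knots),
        boundary_knots=(spec.boundary_knots[0] - offset, spec.boundary_knots[1] - offset),
        use_log_age=spec.use_log_age,
    )

    subjects, codes = np.unique(ids, return_inverse=True)
    n, N = len(subjects), len(y)
    counts = np.bincount(codes)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])

    has = {e: e in include_effects for e in EFFECTS}
    q = sum(has.values())
    p = spec.df + 1

    # ---- initial values
    B0 = np.column_stack([np.ones(N), build_basis(x, spec)])
    c, resid0 = _ols(B0, y)
    var_floor = 1e-10 * float(np.var(y)) + 1e-12
    sigma2 = max(float(np.var(resid0)), var_floor)

    if q == 0:
        sigma2 = max(float(resid0 @ resid0) / N, var_floor)
        ll = -0.5 * (N * np.log(2 * np.pi * sigma2) + (resid0 @ resid0) / sigma2)
        return SitarFit(
            spec=spec, spline_coefs=c, beta0=0.0, gamma0=0.0,
            re_cov=np.zeros((3, 3)),
            blups={s: ZERO_RE for s in subjects},
            sigma_r=float(np.sqrt(sigma2)), loglik=float(ll),
            n_params=p + 1, N=N, n_subjects=n, converged=True,
            median_age=float(np.median(t_years)), median_value=float(np.median(y)),
            age_range=(float(t_years.min()), float(t_years.max())),
            axis_offset=offset,
            include_effects=(), fit_log=log + ["fixed-effects-only fit (no random effects)"],
            loglik_history=[float(ll)],
        )

    init_sd = {"size": float(np.std(resid0)) / 2.0, "timing": 0.05, "intensity": 0.1}
    psi = np.diag([max(init_sd[e] ** 2, 1e-8) for e in EFFECTS if has[e]])
    init_diag = np.diag(psi).copy()

    u = np.zeros((n, q))
    beta0, gamma0 = 0.0, 0.0
    idx = {e: i for i, e in enumerate([e for e in EFFECTS if has[e]])}

    def _exact_resid(c_cur, u_cur):
        """Residuals of the exact (non-linearized) model."""
        ub = u_cur[:, idx["timing"]][codes] if has["timing"] else 0.0
        ug = u_cur[:, idx["intensity"]][codes] if has["intensity"] else 0.0
        s_cur = (x - beta0 - ub) * np.exp(gamma0 + ug)
        f = np.column_stack([np.ones(N), build_basis(s_cur, spec)]) @ c_cur
        if has["size"]:
            f = f + u_cur[:, idx["size"]][codes]
        return y - f

    ll_prev = -np.inf
    ll_hist: list = []
    converged = False
    dropped_effect = None

    def _linearize(c_cur, u_cur):
        ub = u_cur[:, idx["timing"]][codes] if has["timing"] else 0.0
        ug = u_cur[:, idx["intensity"]][codes] if has["intensity"] else 0.0
        scale = np.exp(gamma0 + ug)
        s = (x - beta0 - ub) * scale
        Bs = np.column_stack([np.ones(N), build_basis(s, spec)])
        hp = basis_derivative(s, spec) @ c_cur[1:]
        zcols = []
        if has["size"]:
            zcols.append(np.ones(N))
        if has["timing"]:
            zcols.append(-scale * hp)
        if has["intensity"]:
            zcols.append(s * hp)
        return s, Bs, np.column_stack(zcols)

    def _subject_obj(c_cur, u_cur, psi_inv):
        """Per-subject penalized SSR of the exact (non-linearized) model."""
        rr = _exact_resid(c_cur, u_cur)
        rss = _segment_sums((rr * rr)[:, None], starts)[:, 0]
        pen = np.einsum("nq,qr,nr->n", u_cur, psi_inv, u_cur)
        return rss / sigma2 + pen

    def _damped_accept(c_cur, u_old, u_prop, psi_inv):
        """Per-subject step halving against the exact penalized objective.

        Plain Gauss-Newton overshoots on the strongly nonlinear timing /
        intensity directions; each subject backtracks independently and
        keeps its old value if no step length helps.
        """
        obj_old = _subject_obj(c_cur, u_old, psi_inv)
        step = np.ones(n)
        u_cand = u_prop.copy()
        for _try in range(8):
            obj_new = _subject_obj(c_cur, u_cand, psi_inv)
            bad = obj_new > obj_old + 1e-12
            if not bad.any():
                return u_cand
            step[bad] *= 0.5
            u_cand[bad] = u_old[bad] + step[bad, None] * (u_prop[bad] - u_old[bad])
        obj_new = _subject_obj(c_cur, u_cand, psi_inv)
        bad = obj_new > obj_old + 1e-12
        u_cand[bad] = u_old[bad]
        return u_cand

    for outer in range(max_outer):
        # ---- PNLS: alternate GLS spline-coefficient and damped BLUP updates
        psi_inv = np.linalg.inv(psi)
        for _ in range(3):
            s, Bs, Z = _linearize(c, u)
            pred = Bs @ c
            if has["size"]:
                pred = pred + u[:, idx["size"]][codes]
            ytil = (y - pred) + Bs @ c + (Z * u[codes]).sum(axis=1)

            ZtZ = _segment_sums(Z[:, :, None] * Z[:, None, :], starts)      # n,q,q
            XtZ = _segment_sums(Bs[:, :, None] * Z[:, None, :], starts)     # n,p,q
            M = psi_inv[None, :, :] + ZtZ / sigma2
            Minv = np.linalg.inv(M)

            Zty = _segment_sums(Z * ytil[:, None], starts)
            A = Bs.T @ Bs / sigma2 - np.einsum("npq,nqr,nsr->ps", XtZ, Minv, XtZ) / sigma2**2
            rhs = Bs.T @ ytil / sigma2 - np.einsum("npq,nqr,nr->p", XtZ, Minv, Zty) / sigma2**2
            c = np.linalg.solve(A, rhs)

            w = ytil - Bs @ c
            Ztw = _segment_sums(Z * w[:, None], starts)
            ustar = np.einsum("nqr,nr->nq", Minv, Ztw) / sigma2
            u = _damped_accept(c, u, ustar, psi_inv)

        # ---- LME step: EM to convergence for (psi, sigma2) on the fixed
        # linearization, updating the spline coefficients by GLS each sweep
        s, Bs, Z = _linearize(c, u)
        pred = Bs @ c
        if has["size"]:
            pred = pred + u[:, idx["size"]][codes]
        ytil = (y - pred) + Bs @ c + (Z * u[codes]).sum(axis=1)
        ZtZ = _segment_sums(Z[:, :, None] * Z[:, None, :], starts)
        XtZ = _segment_sums(Bs[:, :, None] * Z[:, None, :], starts)
        XtX = Bs.T @ Bs
        Xty = Bs.T @ ytil
        Zty = _segment_sums(Z * ytil[:, None], starts)
        y2 = _segment_sums((ytil * ytil)[:, None], starts)[:, 0]

        def _lmm_ll(psi_c, sig2, c_c):
            psi_i = np.linalg.inv(psi_c)
            Ml = psi_i[None, :, :] + ZtZ / sig2
            wl = ytil - Bs @ c_c
            Ztwl = _segment_sums(Z * wl[:, None], starts)
            w2l = _segment_sums((wl * wl)[:, None], starts)[:, 0]
            _, ldM = np.linalg.slogdet(Ml)
            _, ldpsi = np.linalg.slogdet(psi_c)
            Minvl = np.linalg.inv(Ml)
            quad = w2l / sig2 - np.einsum("nq,nqr,nr->n", Ztwl, Minvl, Ztwl) / sig2**2
            return -0.5 * float(
                np.sum(counts * np.log(sig2) + ldpsi + ldM + quad) + N * np.log(2 * np.pi)
            )

        ll_in = -np.inf
        for _em in range(40):
            psi_i = np.linalg.inv(psi)
            M = psi_i[None, :, :] + ZtZ / sigma2
            Minv = np.linalg.inv(M)
            A = XtX / sigma2 - np.einsum("npq,nqr,nsr->ps", XtZ, Minv, XtZ) / sigma2**2
            rhs = Xty / sigma2 - np.einsum("npq,nqr,nr->p", XtZ, Minv, Zty) / sigma2**2
            c = np.linalg.solve(A, rhs)
            w = ytil - Bs @ c
            Ztw = _segment_sums(Z * w[:, None], starts)
            ub = np.einsum("nqr,nr->nq", Minv, Ztw) / sigma2
            psi = _clip_psd(
                (np.einsum("nq,nr->qr", ub, ub) + Minv.sum(axis=0)) / n
            )
            e = w - (Z * ub[codes]).sum(axis=1)
            tr = float(np.einsum("nqr,nrq->", Minv, ZtZ))
            sigma2 = max((float(e @ e) + tr) / N, var_floor)
            ll_new = _lmm_ll(psi, sigma2, c)
            if abs(ll_new - ll_in) < 0.1 * rel_tol * (abs(ll_new) + 1.0):
                ll_in = ll_new
                break
            ll_in = ll_new

        # carry the LMM BLUPs into the nonlinear state, guarded by the
        # exact-objective backtracking
        psi_inv = np.linalg.inv(psi)
        u = _damped_accept(c, u, ub, psi_inv)
        ll = ll_in
        ll_hist.append(ll)

        # re-center BLUP means into the fixed effects (exact reparameterization)
        if has["size"]:
            ma = float(u[:, idx["size"]].mean())
            c[0] += ma
            u[:, idx["size"]] -= ma
        if has["timing"]:
            mb = float(u[:, idx["timing"]].mean())
            beta0 += mb
            u[:, idx["timing"]] -= mb
        if has["intensity"]:
            mg = float(u[:, idx["intensity"]].mean())
            gamma0 += mg
            u[:, idx["intensity"]] -= mg

        # collapsed variance -> drop the offending effect and refit
        rel = np.diag(psi) / init_diag
        if np.any(rel < 1e-10):
            dropped_effect = [e for e in EFFECTS if has[e]][int(np.argmin(rel))]
            break

        if outer > 0 and abs(ll - ll_prev) < rel_tol * (abs(ll) + 1.0):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll

    if dropped_effect is not None:
        log.append(
            f"random-effect covariance singular; refitting without the "
            f"'{dropped_effect}' effect"
        )
        remaining = tuple(e for e in include_effects if e != dropped_effect)
        return fit_sitar(
            data, spec_orig, remaining,
            max_outer=max_outer, rel_tol=rel_tol, _log=log,
        )

    if not converged:
        log.append(f"no convergence after {max_outer} outer iterations")

    # assemble 3x3 covariance and BLUP triples with zeros for excluded effects
    re_cov = np.zeros((3, 3))
    order = [e for e in EFFECTS if has[e]]
    pos = [EFFECTS.index(e) for e in order]
    for a, ia in enumerate(pos):
        for b, ib in enumerate(pos):
            re_cov[ia, ib] = psi[a, b]

    blups = {}
    for k, sid in enumerate(subjects):
        triple = np.zeros(3)
        for a, ia in enumerate(pos):
            triple[ia] = u[k, a]
        blups[sid] = RandomEffectTriple(*triple)

    n_fixed = p + int(has["timing"]) + int(has["intensity"])
    n_params = n_fixed + q * (q + 1) // 2 + 1

    return SitarFit(
        spec=spec,
        spline_coefs=np.asarray(c, dtype=float),
        beta0=float(beta0),
        gamma0=float(gamma0),
        re_cov=re_cov,
        blups=blups,
        sigma_r=float(np.sqrt(sigma2)),
        loglik=float(ll_hist[-1]),
        n_params=n_params,
        N=N,
        n_subjects=n,
        converged=converged,
        median_age=float(np.median(t_years)),
        median_value=float(np.median(y)),
        age_range=(float(t_years.min()), float(t_years.max())),
        axis_offset=offset,
        include_effects=include_effects,
        fit_log=log,
        loglik_history=[float(v) for v in ll_hist],
    )


# ---------------------------------------------------------------------------
# derived quantities


def predict_curve(fit: SitarFit, re: RandomEffectTriple, ages) -> np.ndarray:
    """Evaluate alpha + h[(x - beta0 - beta) exp(gamma0 + gamma)] at ``ages`` (years).

    ``re = RandomEffectTriple()`` (all zeros) gives the population mean
    curve.
    """
    x = fit.to_axis(ages)
    s = (x - fit.beta0 - re.beta) * np.exp(fit.gamma0 + re.gamma)
    B = np.column_stack([np.ones(x.size), build_basis(s, fit.spec)])
    return re.alpha + (B @ fit.spline_coefs).reshape(np.shape(x))


def predict_records(fit: SitarFit, data: GrowthData) -> np.ndarray:
    """Per-record predictions using each subject's own BLUPs."""
    ids = data.subject_ids
    missing = set(pd.unique(ids)) - set(fit.blups)
    if missing:
        raise ValueError(f"subjects absent from fit: {sorted(missing)[:5]} ...")
    tri = np.array([fit.blups[i].as_array() for i in ids])
    x = fit.to_axis(data.ages)
    s = (x - fit.beta0 - tri[:, 1]) * np.exp(fit.gamma0 + tri[:, 2])
    B = np.column_stack([np.ones(len(s)), build_basis(s, fit.spec)])
    return tri[:, 0] + B @ fit.spline_coefs


def variance_explained(fit: SitarFit, data: GrowthData) -> float:
    """Percent variance explained, 100 (1 - sigma_r^2 / sigma_f^2).

    sigma_f is the residual SD of a companion fixed-effects-only fit of
    the same spline spec (the data treated cross-sectionally).
    """
    x = fit.to_axis(data.ages)
    B = np.column_stack([np.ones(len(x)), build_basis(x, fit.spec)])
    _, resid = _ols(B, data.values)
    dof = len(x) - B.shape[1]
    if dof <= 0 or float(resid @ resid) == 0.0:
        raise ValueError("degenerate data: fixed-effects-only residual variance is zero")
    sigma_f2 = float(resid @ resid) / dof
    return 100.0 * (1.0 - fit.sigma_r**2 / sigma_f2)


def timing_sd_years(fit: SitarFit) -> float:
    """Timing random-effect SD in years.

    Under the log-age transform the timing SD lives on the log-age axis;
    multiplying by the median age converts it to years.
    """
    sd_b = float(np.sqrt(fit.re_cov[1, 1]))
    return sd_b * fit.median_age if fit.spec.use_log_age else sd_b


def standardized_residuals(fit: SitarFit, data: GrowthData) -> np.ndarray:
    """(observed - subject-level prediction) / sigma_r, per record."""
    resid = data.values - predict_records(fit, data)
    return resid / fit.sigma_r
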