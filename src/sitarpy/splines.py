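"""Natural cubic spline basis with analytic derivatives.

The mean curve h(.) of the SITAR model is a natural cubic spline
parameterised by its degrees of freedom (d.f.).  The basis here is the
standard B-spline basis projected onto the null space of the natural
boundary constraints (zero second derivative at both boundary knots),
the same construction used by R's ``splines::ns``.  Beyond the boundary
knots the basis continues linearly, which matters in practice because
subject-specific age shifts ``(t - beta) * exp(gamma)`` routinely push
evaluation slightly outside the observed age range.

The basis excludes the constant column; models add an explicit
intercept, which keeps the size effect identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineSpec", "place_knots", "build_basis", "basis_derivative"]


@dataclass(frozen=True)
class SplineSpec:
    """Definition of a natural cubic spline basis.

    Parameters
    ----------
    df : int
        Number of basis columns, excluding the intercept.  A spec with
        ``df`` has ``df - 1`` interior knots.
    interior_knots : tuple of float
        Strictly increasing knots, strictly inside the boundary knots,
        on the (possibly log-transformed) age axis.
    boundary_knots : (float, float)
        Axis values at which the natural (linear-tail) condition holds.
    use_log_age : bool
        Whether the axis is natural-log age.  Carried as metadata so a
        fit knows how to map years onto the axis.
    """

    df: int
    interior_knots: tuple = ()
    boundary_knots: tuple = (0.0, 1.0)
    use_log_age: bool = True

    def __post_init__(self):
        object.__setattr__(self, "interior_knots", tuple(float(k) for k in self.interior_knots))
        object.__setattr__(self, "boundary_knots", tuple(float(k) for k in self.boundary_knots))
        if self.df < 2:
            raise ValueError(f"df must be >= 2, got {self.df}")
        if len(self.interior_knots) != self.df - 1:
            raise ValueError(
                f"df={self.df} requires {self.df - 1} interior knots, "
                f"got {len(self.interior_knots)}"
            )
        lo, hi = self.boundary_knots
        if not lo < hi:
            raise ValueError("boundary knots must be increasing")
        ks = np.asarray(self.interior_knots)
        if ks.size and (np.any(np.diff(ks) <= 0) or ks[0] <= lo or ks[-1] >= hi):
            raise ValueError("interior knots must be strictly increasing and strictly inside the boundary knots")

    def to_dict(self) -> dict:
        return {
            "df": self.df,
            "interior_knots": list(self.interior_knots),
            "boundary_knots": list(self.boundary_knots),
            "use_log_age": self.use_log_age,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(
            df=int(d["df"]),
            interior_knots=tuple(d["interior_knots"]),
            boundary_knots=tuple(d["boundary_knots"]),
            use_log_age=bool(d["use_log_age"]),
        )


def place_knots(x_sample, df: int, use_log_age: bool = True) -> SplineSpec:
    """Place knots at equally spaced quantiles of a sample of axis values.

    Interior knots sit at the k/df quantiles (k = 1..df-1) of
    ``x_sample``; boundary knots at its min and max.
    """
    x = np.asarray(x_sample, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    distinct = np.unique(x)
    needed = df + 1
    if distinct.size < needed:
        raise ValueError(
            f"knot placement with df={df} needs at least {needed} distinct values, "
            f"got {distinct.size} ({needed - distinct.size} short)"
        )
    probs = np.arange(1, df) / df
    interior = np.quantile(x, probs)
    # collapse accidental duplicates by nudging within the data range
    interior = np.unique(interior)
    if interior.size != df - 1:
        raise ValueError("quantile knots are not distinct; data too discrete for this df")
    return SplineSpec(
        df=df,
        interior_knots=tuple(interior),
        boundary_knots=(float(x.min()), float(x.max())),
        use_log_age=use_log_age,
    )


@lru_cache(maxsize=128)
def _ns_construction(interior: tuple, boundary: tuple):
    """Full knot vector and coefficient matrix of the projected basis.

    Returns ``(knots, coefs)`` where column j of ``coefs`` gives the
    B-spline coefficients of the j-th natural-spline basis function.
    """
    lo, hi = boundary
    t = np.concatenate([[lo] * 4, np.asarray(interior, float), [hi] * 4])
    K = len(interior) + 4
    # natural constraints: second derivative zero at both boundaries
    C = np.empty((2, K))
    eye = np.eye(K)
    for j in range(K):
        b2 = BSpline(t, eye[j], 3).derivative(2)
        C[0, j] = b2(lo)
        C[1, j] = b2(hi)
    Q, _ = np.linalg.qr(C.T, mode="complete")
    Z = Q[:, 2:]  # K x (K-2); K-2 = df + 1 columns spanning the natural space
    # drop the first column; together with an explicit intercept the
    # remaining df columns span the natural spline space
    return t, Z[:, 1:]


def _evaluate(x, spec: SplineSpec, deriv: int) -> np.ndarray:
    t, coefs = _ns_construction(spec.interior_knots, spec.boundary_knots)
    x = np.asarray(x, dtype=float)
    shape = x.shape
    x = x.ravel()
    lo, hi = spec.boundary_knots
    xi = np.clip(x, lo, hi)
    out = np.empty((x.size, coefs.shape[1]))
    for j in range(coefs.shape[1]):
        b = BSpline(t, coefs[:, j], 3)
        if deriv == 0:
            # linear continuation beyond the boundary knots
            out[:, j] = b(xi) + b.derivative()(xi) * (x - xi)
        elif deriv == 1:
            out[:, j] = b.derivative()(xi)
        elif deriv == 2:
            vals = b.derivative(2)(xi)
            vals[x != xi] = 0.0
            out[:, j] = vals
        else:  # pragma: no cover
            raise ValueError("deriv must be 0, 1 or 2")
    return out.reshape(shape + (coefs.shape[1],))


def build_basis(x, spec: SplineSpec) -> np.ndarray:
    """Evaluate the natural spline basis at axis values ``x``.

    Returns an array of shape ``(len(x), spec.df)``.  Values beyond the
    boundary knots continue linearly (the natural condition).
    """
    return _evaluate(x, spec, 0)


def basis_derivative(x, spec: SplineSpec, order: int = 1) -> np.ndarray:
    """Entrywise analytic derivative of :func:`build_basis` columns."""
    return _evaluate(x, spec, order)
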