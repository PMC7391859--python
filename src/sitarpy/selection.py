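"""Spline d.f. selection by BIC and bootstrap standard errors for landmarks.

The bootstrap resamples *subjects* with replacement (a cluster
bootstrap): the data are longitudinal, so resampling records would break
the within-subject correlation that the model exists to describe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import fit_landmarks
from .data import GrowthData
from .model import EFFECTS, fit_sitar
from .splines import SplineSpec, place_knots

__all__ = ["select_df", "BootstrapResult", "bootstrap_landmarks"]


def select_df(
    data: GrowthData,
    df_range,
    use_log_age: bool = True,
    include_effects=EFFECTS,
) -> tuple[int, pd.DataFrame]:
    """Fit every d.f. in ``df_range`` and return the BIC minimiser.

    Non-converged candidates are recorded in the table but excluded from
    the choice.  Ties go to the smaller d.f.
    """
    x = np.log(data.ages) if use_log_age else data.ages
    rows = []
    for df in df_range:
        spec = place_knots(x, int(df), use_log_age=use_log_age)
        fit = fit_sitar(data, spec, include_effects)
        rows.append(
            {
                "df": int(df),
                "loglik": fit.loglik,
                "n_params": fit.n_params,
                "bic": fit.bic(),
                "converged": fit.converged,
            }
        )
    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    if ok.empty:
        raise RuntimeError("no candidate d.f. converged")
    # idxmin takes the first minimum; table is in ascending df order
    chosen = int(ok.sort_values("df").loc[lambda t: t["bic"].idxmin(), "df"])
    return chosen, table


@dataclass
class BootstrapResult:
    """Cluster-bootstrap replicate landmarks and their SEs."""

    B: int
    replicates: pd.DataFrame    # one row per successful replicate
    se: dict                    # landmark name -> SD over replicates
    n_failed: int
    seed: int | None


def _resample_subjects(rng, subject_ids: np.ndarray) -> np.ndarray:
    return rng.choice(subject_ids, size=len(subject_ids), replace=True)


def bootstrap_landmarks(
    data: GrowthData,
    spec: SplineSpec,
    B: int = 200,
    seed: int | None = None,
    scale: str = "cm/yr",
    include_effects=EFFECTS,
    resampler=None,
) -> BootstrapResult:
    """Bootstrap SEs for the mean-curve landmarks.

    Each replicate draws n subjects with replacement, refits, and
    recomputes the landmarks; the SE is the SD across replicates.
    Replicates whose velocity curve has no peak are excluded and
    counted; more than 20% such failures raises (the model is too
    unstable for the landmark to mean anything).

    ``resampler(rng, ids) -> ids`` can replace the resampling rule
    (e.g. the identity, for which every SE is exactly zero).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    draw = resampler or _resample_subjects
    subject_ids = np.asarray(pd.unique(data.frame["id"]))
    blocks = {sid: sub for sid, sub in data.frame.groupby("id", sort=False)}

    rows = []
    n_failed = 0
    for b in range(B):
        chosen = draw(rng, subject_ids)
        parts = []
        for k, sid in enumerate(chosen):
            block = blocks[sid].copy()
            block["id"] = f"b{k}"  # duplicates become distinct subjects
            parts.append(block)
        bdata = GrowthData(pd.concat(parts, ignore_index=True), data.measure, data.sex, data.units)
        fit = fit_sitar(bdata, spec, include_effects)
        lm = fit_landmarks(fit, scale=scale)
        if not (lm.peak_found and lm.takeoff_found):
            n_failed += 1
            continue
        rows.append(
            {
                "replicate": b,
                "age_takeoff": lm.age_takeoff,
                "age_peak": lm.age_peak,
                "vel_takeoff": lm.vel_takeoff,
                "vel_peak": lm.vel_peak,
            }
        )
    if n_failed > 0.2 * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap replicates found no velocity peak; model unstable"
        )
    reps = pd.DataFrame(rows)
    se = {k: float(reps[k].std(ddof=1)) for k in ["age_takeoff", "age_peak", "vel_takeoff", "vel_peak"]}
    return BootstrapResult(B=B, replicates=reps, se=se, n_failed=n_failed, seed=seed)
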