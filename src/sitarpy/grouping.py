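"""Global-to-local stratification of a cohort by its growth tempo.

The procedure: fit a global model, rank subjects by their timing BLUP
and cut them into k equal-size groups (the spectrum from early to late
puberty), fit a *local* model to each group with the timing effect
omitted (it is already adjusted for by the grouping), then split each
timing group by the intensity BLUPs *from its local model* into
equal-size subgroups and fit again with both timing and intensity
omitted.  Local mean curves are compared with curves predicted from the
global model at each group's mean random effects: close agreement means
the shape-invariance assumption holds across the tempo spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import CurveGrid, fit_landmarks
from .data import GrowthData
from .model import EFFECTS, RandomEffectTriple, SitarFit, fit_sitar, predict_curve
from .splines import place_knots

__all__ = [
    "GroupAssignment",
    "CurveComparison",
    "split_by_blup",
    "fit_local_models",
    "predict_group_from_global",
    "compare_curves",
    "run_grouping_pipeline",
    "GroupingResult",
]

_EFFECT_COL = {"size": "alpha", "timing": "beta", "intensity": "gamma"}


def _equal_sizes(n: int, k: int) -> np.ndarray:
    """Group sizes differing by at most one, extras at the extremes."""
    base, rem = divmod(n, k)
    sizes = np.full(k, base, dtype=int)
    order = []
    lo, hi = 0, k - 1
    while lo <= hi:
        order.append(lo)
        if hi != lo:
            order.append(hi)
        lo += 1
        hi -= 1
    for j in order[:rem]:
        sizes[j] += 1
    return sizes


@dataclass
class GroupAssignment:
    """Contiguous rank blocks of subjects ordered by one BLUP."""

    effect: str
    k: int
    groups: dict                      # subject id -> group index (1-based)
    group_mean_re: list               # RandomEffectTriple per group
    sizes: np.ndarray

    def subjects_in(self, group: int) -> list:
        return [s for s, g in self.groups.items() if g == group]


def split_by_blup(fit: SitarFit, effect: str, k: int) -> GroupAssignment:
    """Rank subjects by a BLUP and cut into k equal-size ordered groups.

    Ties break on subject id, so the assignment is deterministic.
    """
    if effect not in EFFECTS:
        raise ValueError(f"unknown effect {effect!r}")
    if effect not in fit.include_effects:
        raise ValueError(f"fit has no {effect!r} random effect")
    bf = fit.blup_frame()
    n = len(bf)
    if k > n:
        raise ValueError(f"cannot split {n} subjects into {k} groups")
    col = _EFFECT_COL[effect]
    bf = bf.sort_values([col, "id"], key=lambda s: s.astype(str) if s.name == "id" else s)
    sizes = _equal_sizes(n, k)
    labels = np.repeat(np.arange(1, k + 1), sizes)
    bf["group"] = labels
    means = [
        RandomEffectTriple(*bf.loc[bf["group"] == g, ["alpha", "beta", "gamma"]].mean())
        for g in range(1, k + 1)
    ]
    return GroupAssignment(
        effect=effect,
        k=k,
        groups=dict(zip(bf["id"], bf["group"])),
        group_mean_re=means,
        sizes=sizes,
    )


def fit_local_models(
    data: GrowthData,
    assignment: GroupAssignment,
    df: int = 5,
    omit=("timing",),
    use_log_age: bool = True,
    min_subjects: int = 5,
) -> list:
    """One SITAR fit per group, with the conditioned-on effects omitted.

    Returns a list indexed by group (entry ``None``, with a log record,
    for groups too small to fit).
    """
    effects = tuple(e for e in EFFECTS if e not in tuple(omit))
    fits = []
    for g in range(1, assignment.k + 1):
        ids = assignment.subjects_in(g)
        if len(ids) < min_subjects:
            fits.append(None)
            continue
        sub = data.subset_subjects(ids)
        x = np.log(sub.ages) if use_log_age else sub.ages
        spec = place_knots(x, df, use_log_age=use_log_age)
        fits.append(fit_sitar(sub, spec, effects))
    return fits


def predict_group_from_global(
    fit_global: SitarFit, assignment: GroupAssignment, group: int, ages
) -> CurveGrid:
    """Global-model curve at a group's mean random-effect triple."""
    re = assignment.group_mean_re[group - 1]
    return CurveGrid(np.asarray(ages, float), predict_curve(fit_global, re, ages), "cm")


@dataclass
class CurveComparison:
    """Pointwise agreement of a local and a globally predicted curve."""

    ages: np.ndarray
    local: np.ndarray
    predicted: np.ndarray
    max_abs: float
    rmse: float


def compare_curves(local: CurveGrid, predicted: CurveGrid) -> CurveComparison:
    if local.ages.shape != predicted.ages.shape or not np.allclose(local.ages, predicted.ages):
        raise ValueError("curves must share the same age grid")
    diff = local.values - predicted.values
    return CurveComparison(
        ages=local.ages,
        local=local.values,
        predicted=predicted.values,
        max_abs=float(np.max(np.abs(diff))),
        rmse=float(np.sqrt(np.mean(diff**2))),
    )


@dataclass
class GroupingResult:
    """Everything the two-stage pipeline produced."""

    global_fit: SitarFit
    timing_assignment: GroupAssignment
    timing_fits: list
    intensity_assignments: list       # per timing group
    intensity_fits: list              # list (timing group) of lists (intensity group)
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_grouping_pipeline(
    data: GrowthData,
    global_fit: SitarFit,
    k_timing: int = 9,
    k_intensity: int = 5,
    df_local: int = 5,
    use_log_age: bool = True,
) -> GroupingResult:
    """Two-stage timing-by-intensity stratification with local fits.

    Stage-2 intensity BLUPs come from each timing group's *local* model,
    not the global one, so the subgroups are conditionally independent
    of the timing adjustment.
    """
    timing_assignment = split_by_blup(global_fit, "timing", k_timing)
    timing_fits = fit_local_models(
        data, timing_assignment, df=df_local, omit=("timing",), use_log_age=use_log_age
    )

    intensity_assignments = []
    intensity_fits = []
    for g, tfit in enumerate(timing_fits, start=1):
        if tfit is None:
            intensity_assignments.append(None)
            intensity_fits.append([None] * k_intensity)
            continue
        sub = data.subset_subjects(timing_assignment.subjects_in(g))
        assign2 = split_by_blup(tfit, "intensity", k_intensity)
        fits2 = fit_local_models(
            sub, assign2, df=df_local, omit=("timing", "intensity"), use_log_age=use_log_age
        )
        intensity_assignments.append(assign2)
        intensity_fits.append(fits2)

    rows = []
    for g, tfit in enumerate(timing_fits, start=1):
        if tfit is None:
            continue
        lm = fit_landmarks(tfit)
        rows.append(
            {
                "timing_group": g,
                "subjects": int(timing_assignment.sizes[g - 1]),
                "points": tfit.N,
                "apv": lm.age_peak,
                "pv": lm.vel_peak,
                "age_takeoff": lm.age_takeoff,
                "vel_takeoff": lm.vel_takeoff,
                "residual_sd": tfit.sigma_r,
            }
        )
    return GroupingResult(
        global_fit=global_fit,
        timing_assignment=timing_assignment,
        timing_fits=timing_fits,
        intensity_assignments=intensity_assignments,
        intensity_fits=intensity_fits,
        summary=pd.DataFrame(rows),
    )
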