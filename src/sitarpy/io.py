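"""Reading growth CSVs, writing summary tables, and analysis configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .curves import Landmarks, fit_landmarks, value_at_age
from .data import GrowthData
from .model import SitarFit, timing_sd_years, variance_explained
from .multimeasure import size_percent_sd

__all__ = [
    "AnalysisConfig",
    "read_growth_csv",
    "write_growth_csv",
    "write_model_summary",
    "write_random_effects_summary",
    "write_landmarks_summary",
]


@dataclass
class AnalysisConfig:
    """Flat configuration for the analysis recipes.

    Ages outside the open interval ``age_window`` are dropped on read
    (strict inequalities at both ends).
    """

    age_window: tuple = (7.0, 20.0)
    use_log_age: bool = True
    df: int | None = None
    df_range: tuple = (3, 8)
    effects: tuple = ("size", "timing", "intensity")
    bootstrap_B: int = 200
    seed: int | None = None
    cleaning_threshold: float = 4.0
    cleaning_max_iter: int = 3
    k_timing: int = 9
    k_intensity: int = 5
    df_local: int = 5

    def __post_init__(self):
        lo, hi = self.age_window
        if not lo < hi:
            raise ValueError("age window lower bound must be below upper bound")
        if self.df is not None and self.df < 2:
            raise ValueError("df must be >= 2")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["age_window"] = list(self.age_window)
        d["df_range"] = list(self.df_range)
        d["effects"] = list(self.effects)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("age_window", "df_range", "effects"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


REQUIRED = ["id", "sex", "age", "measure", "value"]


def read_growth_csv(path, age_window=(7.0, 20.0), logger=None) -> GrowthData:
    """Read a long-format growth table.

    Requires columns id, sex, age, measure, value.  Rows with age
    outside the *open* window are dropped and counted; non-numeric age
    or value raises with the offending row numbers.
    """
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"{path}: file has no data rows")
    missing = [c for c in REQUIRED if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("age", "value"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()] + 2  # 1-based + header
        if len(bad):
            raise ValueError(f"{path}: non-numeric {col} at file rows {list(bad[:10])}")
        frame[col] = coerced
    frame = frame.dropna(subset=["age", "value"])
    lo, hi = age_window
    keep = (frame["age"] > lo) & (frame["age"] < hi)
    n_dropped = int((~keep).sum())
    if logger:
        logger.info("dropped %d rows outside age window (%g, %g)", n_dropped, lo, hi)
    frame = frame.loc[keep].reset_index(drop=True)
    if frame.empty:
        raise ValueError(f"{path}: no rows left inside age window ({lo}, {hi})")
    return GrowthData(frame)


def write_growth_csv(data: GrowthData, path) -> None:
    data.frame.to_csv(path, index=False)


def _fit_label(fit: SitarFit, data: GrowthData) -> dict:
    return {
        "measure": data.measure or "",
        "sex": data.sex or "",
    }


def write_model_summary(fits_data: list, path) -> pd.DataFrame:
    """Model-summary table: subjects, points, median, df, log age,
    variance explained, residual SD, residual CV (one row per fit)."""
    rows = []
    for fit, data in fits_data:
        rows.append(
            {
                **_fit_label(fit, data),
                "subjects": fit.n_subjects,
                "points": fit.N,
                "median": round(fit.median_value, 1),
                "df": fit.spec.df,
                "log_age": "yes" if fit.spec.use_log_age else "no",
                "variance_explained_pct": round(variance_explained(fit, data), 1),
                "residual_sd": round(fit.sigma_r, 3),
                "residual_cv_pct": round(100.0 * fit.sigma_r / fit.median_value, 2),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(path, index=False)
    return table


def write_random_effects_summary(fits_data: list, path) -> pd.DataFrame:
    """Random-effect table: SDs (size in cm and %, timing in yr,
    intensity) and pairwise correlations."""
    rows = []
    for fit, data in fits_data:
        corr = fit.re_corr
        rows.append(
            {
                **_fit_label(fit, data),
                "size_sd_cm": round(float(fit.re_sd[0]), 2),
                "size_sd_pct": round(size_percent_sd(fit), 1),
                "timing_sd_yr": round(timing_sd_years(fit), 2),
                "intensity_sd": round(float(fit.re_sd[2]), 2),
                "corr_size_timing": round(float(corr[0, 1]), 2),
                "corr_timing_intensity": round(float(corr[1, 2]), 2),
                "corr_intensity_size": round(float(corr[0, 2]), 2),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(path, index=False)
    return table


def write_landmarks_summary(fits_data: list, path) -> pd.DataFrame:
    """Landmark table: takeoff/peak ages and velocities on the cm and %
    scales, plus the value at age 19.

    Measurements whose percent-velocity curve has no interior peak get
    a ``*`` in the percent columns.
    """
    rows = []
    for fit, data in fits_data:
        cm = fit_landmarks(fit, scale="cm/yr")
        pct = fit_landmarks(fit, scale="%/yr")
        star = not pct.peak_found

        def fmt(v, nd=1):
            return "*" if v is None else round(v, nd)

        rows.append(
            {
                **_fit_label(fit, data),
                "age_takeoff_yr": fmt(cm.age_takeoff),
                "age_peak_yr": fmt(cm.age_peak),
                "takeoff_cm_yr": fmt(cm.vel_takeoff, 2),
                "peak_cm_yr": fmt(cm.vel_peak, 2),
                "takeoff_pct_yr": "*" if star else fmt(pct.vel_takeoff),
                "peak_pct_yr": "*" if star else fmt(pct.vel_peak),
                "value_at_19": round(value_at_age(fit, 19.0), 1),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(path, index=False)
    return table


def write_curve_csv(grid, path) -> None:
    """Two-column curve export with the unit in the header."""
    pd.DataFrame({"age_yr": grid.ages, f"value ({grid.scale})": grid.values}).to_csv(
        path, index=False
    )


def landmarks_row(lm: Landmarks) -> dict:
    return {
        "age_takeoff": lm.age_takeoff,
        "age_peak": lm.age_peak,
        "vel_takeoff": lm.vel_takeoff,
        "vel_peak": lm.vel_peak,
        "scale": lm.scale,
        "peak_found": lm.peak_found,
        "takeoff_found": lm.takeoff_found,
    }
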