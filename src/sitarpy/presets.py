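"""Preset study conditions for the two cohort designs the package emulates.

Each preset bundles a generative truth (mean curve, random-effect
covariance, residual SD) with a visit design, using the published
summary statistics of the corresponding cohort as the generative
parameters: a boys' height model from an intensively measured growth
study (n = 371, ~10-12 visits per child between 7 and 20 years), and a
boys' height model from a large birth cohort measured over nine sweeps.

The constants below are frozen properties of the designs themselves,
computed once from the schedule generators:

* ``*_MEDIAN_AGE`` — the design's median observation age, used to
  convert the timing random-effect SD between years and the log-age
  axis (the same median-age rule the fitted model uses).
* ``*_AXIS_CENTER`` — the design's mean log age, where the intensity
  effect rotates the age scale (matching the fitted model, which
  centres its axis at the mean log age).
"""

from __future__ import annotations

import numpy as np

from .simulate import (
    DesignSpec,
    TrueParams,
    make_mean_curve,
    simulate_cohort,
    spline_project_curve,
)

__all__ = ["harpenden_male_height", "alspac_boys"]

# growth-study design (6-monthly / 3-monthly visits, staggered entry)
HARPENDEN_MEDIAN_AGE = 13.5
HARPENDEN_AXIS_CENTER = float(np.log(13.54))
HARPENDEN_DROPOUT = 0.45

# birth-cohort design (nine sweeps, annual to 13.5 then 15 and 17)
ALSPAC_MEDIAN_AGE = 11.5
ALSPAC_AXIS_CENTER = float(np.log(11.38))
ALSPAC_DROPOUT = 0.32

# random-effect correlations (size-timing, timing-intensity, intensity-size)
# for boys' height
_HEIGHT_CORR = np.array(
    [
        [1.00, 0.36, 0.42],
        [0.36, 1.00, 0.28],
        [0.42, 0.28, 1.00],
    ]
)


def _cov(size_sd: float, timing_sd: float, intensity_sd: float) -> np.ndarray:
    sd = np.array([size_sd, timing_sd, intensity_sd])
    return _HEIGHT_CORR * np.outer(sd, sd)


def harpenden_male_height(n: int = 371, seed: int | None = None):
    """Male-height truth and design for the intensive growth-study setting.

    Generative values: size SD 6.46 cm, timing SD 0.86 yr (converted to
    the log-age axis via the design median age), intensity SD 0.13,
    residual SD 0.51 cm; mean curve with APV 14.2 yr, PV 9.3 cm/yr and
    adult size ~174 cm at 19.
    """
    curve = make_mean_curve(
        adult_size=175.5, target_apv=14.2, target_pv=9.3, prepubertal_velocity=5.5
    )
    truth = TrueParams(
        mean_curve=curve,
        re_cov_true=_cov(6.46, 0.86 / HARPENDEN_MEDIAN_AGE, 0.13),
        sigma_r_true=0.51,
        use_log_age=True,
        axis_center=HARPENDEN_AXIS_CENTER,
    )
    design = DesignSpec(
        n=n, mode="growth_study", dropout=HARPENDEN_DROPOUT, seed=seed
    )
    return truth, design


def _alspac_reference_ages(n: int = 2000) -> np.ndarray:
    """Deterministic sample of the sweep design's observation ages."""
    rng = np.random.default_rng(20210520)
    sweeps = np.asarray(DesignSpec.SWEEP_AGES)
    offs = rng.uniform(-0.5, 0.5, size=n)
    ages = (sweeps[None, :] + offs[:, None]).ravel()
    ages += rng.uniform(-0.1, 0.1, size=ages.size)
    return ages[(ages > 7.001) & (ages < 19.999)]

def alspac_boys(n: int = 5227, seed: int | None = None, df: int = 6):
    """Boys'-height truth and design for the nine-sweep birth-cohort setting.

    The generating mean curve is a sigmoid template calibrated to
    APV 13.5 yr / PV 10.6 cm/yr / height 179 cm, projected onto the
    ``df``-d.f. natural-spline space of the design's log ages, so the
    fitted model is correctly specified and landmark recovery is free of
    template-approximation error.  Random effects: size SD 6.6 cm
    (3.7% of height at 19), timing SD 0.8 yr, intensity SD 0.11;
    residual SD 1.02 cm.
    """
    template = make_mean_curve(
        adult_size=179.0, target_apv=13.5, target_pv=10.6, prepubertal_velocity=5.6
    )
    curve = spline_project_curve(template, _alspac_reference_ages(), df=df)
    truth = TrueParams(
        mean_curve=curve,
        re_cov_true=_cov(6.6, 0.8 / ALSPAC_MEDIAN_AGE, 0.11),
        sigma_r_true=1.02,
        use_log_age=True,
        axis_center=ALSPAC_AXIS_CENTER,
    )
    design = DesignSpec(
        n=n, mode="cohort_sweeps", dropout=ALSPAC_DROPOUT, seed=seed
    )
    return truth, design
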