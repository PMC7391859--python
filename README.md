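# sitarpy

SITAR growth-curve modelling of pubertal growth in Python: model
fitting, velocity-curve landmarks, bootstrap standard errors, outlier
cleaning, tempo-based cohort stratification, cross-measurement
random-effect analysis, and a synthetic-cohort simulator with known
ground truth.

## Who this is for

Auxologists, epidemiologists and biostatisticians with longitudinal
anthropometry — repeated height (or sitting height, leg length, ...)
measurements on children across puberty — who want each child's growth
summarised by three interpretable numbers and the cohort by one mean
curve.

## The model

SITAR (SuperImposition by Translation And Rotation) is a
shape-invariant nonlinear mixed-effects model. For subject *i* at age
*t* (analysed on the log-age axis by default):

    y_ij = α_i + h[(x_ij − β0 − β_i) · e^(γ0 + γ_i)] + ε_ij,
    (α_i, β_i, γ_i) ~ N(0, Ψ),   ε_ij ~ N(0, σ_r²)

One natural cubic spline *h* (degrees of freedom chosen by BIC) is the
common curve shape; each child's curve is that shape shifted up or down
(**size** α, cm), shifted left or right (**timing** β — earlier or
later puberty; its SD × median age gives years), and compressed or
stretched along the age axis (**intensity** γ — e^γ multiplies growth
velocity, so γ is the fractional difference in peak velocity). The
first derivative of the fitted curve is the velocity curve, from which
the package extracts age at peak velocity (APV), peak velocity (PV) and
takeoff (the velocity minimum before the peak), on both the cm/yr and
the percent (100·d ln y/dt) scales.

Because no suitable cohort data are public, the package ships a
generator that simulates cohorts from the same model — with either an
intensive growth-study visit design (6-monthly, 3-monthly during
puberty) or a birth-cohort sweep design (annual to 13.5, then 15
and 17) — recording every subject's true effects so estimation can be
validated end to end.

## Worked example

Simulate a growth-study-scale male-height cohort (n = 371, the preset's
generative values are the package's benchmark conditions) and fit it:

```python
import numpy as np
from sitarpy import (fit_sitar, place_knots, simulate_cohort,
                     timing_sd_years, variance_explained,
                     fit_landmarks, value_at_age)
from sitarpy.presets import harpenden_male_height

truth, design = harpenden_male_height(seed=1)
data, true_effects = simulate_cohort(truth, design)

spec = place_knots(np.log(data.ages), df=7)   # knots at log-age quantiles
fit = fit_sitar(data, spec)

print(f"subjects: {fit.n_subjects}, records: {fit.N}, converged: {fit.converged}")
print(f"variance explained: {variance_explained(fit, data):.1f}%")
print(f"residual SD: {fit.sigma_r:.2f} cm")
print(f"size SD: {fit.re_sd[0]:.2f} cm   timing SD: {timing_sd_years(fit):.2f} yr"
      f"   intensity SD: {fit.re_sd[2]:.2f}")
lm = fit_landmarks(fit)
print(f"takeoff: {lm.vel_takeoff:.1f} cm/yr at {lm.age_takeoff:.1f} yr")
print(f"peak:    {lm.vel_peak:.1f} cm/yr at {lm.age_peak:.1f} yr")
print(f"height at 19: {value_at_age(fit, 19):.1f} cm")
```

Output:

```
subjects: 371, records: 4329, converged: True
variance explained: 99.5%
residual SD: 0.50 cm
size SD: 6.40 cm   timing SD: 0.91 yr   intensity SD: 0.13
takeoff: 4.3 cm/yr at 11.3 yr
peak:    9.2 cm/yr at 14.3 yr
height at 19: 175.3 cm
```

Reading it: the three random effects plus the mean curve account for
99.5% of the cross-sectional variance, leaving half a centimetre of
measurement noise. Children vary by ±6.4 cm in size (1 SD), ±0.91 yr in
the timing of their spurt, and ±13% in how fast they pass through it.
The mean spurt takes off at 11.3 yr (4.3 cm/yr) and peaks at 14.3 yr
(9.2 cm/yr) — and the generator's true values for all of these are
recovered within sampling error (they were 6.46 cm, 0.86 yr, 0.13,
0.51 cm, APV 14.2, PV 9.3).

The same workflow is available from the shell:

```bash
sitarpy simulate --preset harpenden --seed 1 --out run/
sitarpy fit run/cohort.csv --df 7 --out run/fit/
sitarpy landmarks run/cohort.csv --df 7 --out run/lm/
sitarpy group run/cohort.csv --k-timing 9 --k-intensity 5 --out run/groups/
```

Input CSVs are long-format with columns `id, sex, age, measure, value`
(decimal ages in years, strict window 7–20; every model is fitted per
sex and measure).

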