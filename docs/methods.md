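# Methods

## The model

sitarpy fits the SITAR growth-curve model (SuperImposition by
Translation And Rotation): for subject *i* at age *t*,

    y_ij = α_i + h[(x_ij − β0 − β_i) · exp(γ0 + γ_i)] + ε_ij

where *h* is a natural cubic spline with an explicit intercept, *x* is
age or (by default) natural-log age, and (α, β, γ) are subject random
effects:

* **size** α — a vertical shift in measurement units (cm);
* **timing** β — a horizontal shift on the age axis; under log age it is
  a proportional age shift, and its SD converts to years by multiplying
  by the median observation age;
* **intensity** γ — a log scaling of the age axis, so exp(γ) multiplies
  growth velocity; its SD is effectively the coefficient of variation of
  peak velocity.

The triple is jointly normal with unstructured 3×3 covariance Ψ;
residuals are N(0, σ_r²). Fixed effects β0 and γ0 keep the random
effects mean-zero. The model's working age axis is centred at the mean
(log-)age, so the intensity rotation stretches the age scale about
mid-adolescence; without this centring a plausible intensity SD would
displace curves by tens of centimetres at the ends of the age range.

The log-age transform measures age differences proportionally and
usually fits pubertal data better; all curves and landmarks are reported
back on the age-in-years axis.

## Spline basis

`splines` builds the natural cubic spline as the B-spline basis
projected onto the null space of the two natural boundary constraints
(zero second derivative at the boundary knots), the same construction as
R's `splines::ns`, on top of `scipy.interpolate.BSpline`. Interior knots
sit at equally spaced quantiles of the observed (transformed) ages —
observation quantiles, not subject-mean-age quantiles; this is
configurable by passing explicit knots in a `SplineSpec`. Beyond the
boundary knots the basis continues linearly. This matters in practice:
subject-specific transformed ages (x − β)·e^γ routinely fall slightly
outside the observed range, so extrapolation is defined and smooth, and
no warning is raised.

## Estimation

`fit_sitar` uses first-order conditional linearization in the
Lindstrom–Bates style, alternating two steps until the marginal
log-likelihood of the linearized model stabilises (relative change
below 1e-6, at most 150 outer iterations; non-convergence is flagged,
never silent):

1. **Penalized nonlinear least squares.** With (Ψ, σ_r) fixed, the
   spline coefficients are updated by GLS on the current linearization
   and the subject effects by their linear-model BLUPs. Because the
   timing/intensity directions are strongly nonlinear, each subject's
   BLUP step is backtracked (step halving) against the *exact*
   penalized residual sum of squares; a subject whose step never helps
   keeps its previous value. This per-subject damping is what makes the
   fit stable on realistic cohorts.
2. **Linear mixed-model step.** On the fixed linearization, (Ψ, σ_r)
   and the spline coefficients are updated by EM sweeps with closed-form
   M-steps, iterated to convergence of the linearized-model likelihood.
   The Ψ update is eigenvalue-floored (at 1e-8 of the largest
   eigenvalue) so a rank-deficient BLUP covariance — routine in tiny or
   noise-free data — cannot stall the iteration. If a variance
   component truly collapses (below 1e-10 of its starting value), the
   fit is restarted without that effect and the event recorded in
   `fit_log`.

β0 and γ0 are not free optimisation parameters: with an unconstrained
spline they are unidentified, since *h* can absorb any shift or scale.
Instead the BLUP means are folded into them (and the α mean into the
spline intercept) each iteration — an exact reparameterization that
enforces mean-zero random effects by construction.

Starting values: spline coefficients from the fixed-effects-only
least-squares fit, β0 = γ0 = 0, Ψ diagonal with size variance from the
subject-mean residuals of that fit and timing/intensity SDs of 0.05 and
0.1.

Reported random-effect SDs and correlations come from the estimated
covariance Ψ, not from BLUP sample moments — shrinkage distorts the
latter, particularly for subjects with few visits. BIC is
−2·loglik + p·ln N with p counting spline coefficients, β0, γ0, the
free elements of Ψ and σ_r. The log-likelihood is that of the final
linearized model, the standard conditional approximation; across outer
iterations it is monotone up to linearization error (asserted in the
tests with a small slack).

Variance explained is 100·(1 − σ_r²/σ_f²), with σ_f the residual SD of
a fixed-effects-only spline fit of the same d.f. (the data treated
cross-sectionally). The residual CV divides σ_r by the median of all
observations. Note two finite-sample properties verified in the test
suite: when the true random effects are absent, the fitted effects still
absorb roughly q/m of pure noise (q effects, m visits per subject), and
when the true mean curve is not exactly spline-representable the
nonlinear shift/scale terms genuinely fit better than the plain spline —
so "variance explained ≈ 0" holds only for representable truths and
dense designs.

## Curves and landmarks

Velocity is the analytic spline derivative mapped through the chain rule
(dy/dt = (dy/dx)/t under log age). Percent velocity is 100·v/y, i.e.
100·d(ln y)/dt. Landmarks are found on a dense grid (default 1000
points over the observed age range trimmed 2% at each end, to stay clear
of the linear extrapolation tails): the peak is the earliest global
interior maximum refined by a three-point parabola (accuracy ~grid
spacing squared), takeoff is the interior minimum before the peak,
refined the same way. A curve with no interior maximum returns
`peak_found=False`, which the report writers render as `*` — the
"no peak on the percent-velocity curve" case of small measurements.

## d.f. selection, bootstrap, cleaning

* `select_df` fits each candidate d.f. and returns the BIC minimiser;
  ties go to the smaller d.f.; non-converged candidates are tabulated
  but excluded.
* `bootstrap_landmarks` resamples **subjects** with replacement (cluster
  bootstrap; resampling records would destroy the within-subject
  correlation the model describes), refits, and takes the SD of each
  landmark over replicates. Default B = 200; replicates without a
  velocity peak are dropped and counted, and more than 20% of them is an
  error. Resampled duplicates are relabelled as distinct subjects.
* `clean` iterates fit → flag |standardized residual| > 4 → drop →
  refit, at most 3 times. Under Gaussian residuals the rule flags
  0.006% of records, so clean data pass essentially untouched. The
  operation only excludes; `CleaningReport.context` lists neighbouring
  records of each flagged one for manual review.

## Tempo stratification (global → local)

`run_grouping_pipeline` ranks subjects by their timing BLUP from a
global fit and cuts them into k equal-size contiguous blocks (sizes
differ by at most one; when n mod k ≠ 0 the larger blocks go to the
extremes, alternating outside-in; ties in the BLUP break on subject id).
Each timing group gets a local model with the timing effect omitted
(df = 5 by default); each timing group is then split by the intensity
BLUPs *from its own local model* into equal subgroups, fitted with both
timing and intensity omitted. Local mean curves are compared with
global-model predictions at each group's mean random-effect triple
(default grid 9–19 yr, 200 points): close agreement is exactly the
shape-invariance assumption holding across the tempo spectrum.

A caution on granularity: the strict ordering of local peak velocities
across intensity subgroups is a *population* property. At ~20 subjects
per cell the local PV estimate has a standard error comparable to the
adjacent-subgroup separation, so sample orderings show occasional
adjacent inversions; ~100+ subjects per cell are needed for the ordering
to be nearly deterministic.

## Cross-measurement analyses

`cross_measure_correlations` computes Pearson correlations of one
effect's BLUPs across measurements over shared subjects (pairs with
fewer than 3 shared subjects are marked missing). `seriate` reorders
the matrix by descending median correlation with the other measurements
— a pure permutation, asserted as such in the tests. `size_percent_sd`
reports the size SD as a percentage of the mean-curve value at age 19,
making size variability comparable across measurements spanning a
thirty-fold size range.

## Synthetic cohorts

`simulate_cohort` draws (α, β, γ) from a trivariate normal, evaluates
each subject's curve exactly as the fitted model would (same axis,
same rotation centre), and adds Gaussian noise. Two mean-curve
families:

* `make_mean_curve` calibrates a Preece–Baines model-1 sigmoid
  (parameters: adult asymptote, size at θ, two rate constants, θ) to
  target APV, PV and a prepubertal velocity at age 8, by nested
  least squares with a weak pin on the size-at-θ/adult ratio; the
  calibration is checked to 0.02 yr / 0.05 cm/yr. Its velocity is
  closed-form, so landmark ground truth is available to ~1e-10 yr.
* `spline_project_curve` projects such a template onto the natural
  spline space of a design's log ages, giving a truth the model can
  represent exactly — used where landmark-recovery checks must be free
  of template-approximation error (a df=6 spline tracks the sigmoid to
  <0.2 cm yet its velocity-peak sits ~0.13 yr early, because velocity
  is flat near the peak).

Two visit designs:

* **growth_study** — rolling recruitment: entry U(7, 13) yr, follow-up
  U(3, 12) yr truncated at 20, visits 6-monthly, 3-monthly inside ±2 yr
  of the subject's own (shifted) APV, per-visit jitter ±0.1 yr and 45%
  per-visit missingness in the preset. At n = 371 this yields ≈4300
  records with median age ≈13.5 yr.
* **cohort_sweeps** — nine sweeps at 7.5–13.5 (annual), 15 and 17 yr,
  a per-subject U(−0.5, 0.5) sweep-age offset (birth-date spread),
  ±0.1 yr jitter and 32% missingness, giving ≈6 visits per subject.

`presets` freezes the two study configurations used by the benchmark
experiments: a male-height growth-study cohort (size SD 6.46 cm, timing
SD 0.86 yr, intensity SD 0.13, residual SD 0.51 cm, correlations
0.36/0.28/0.42, curve APV 14.2 / PV 9.3 / ~174 cm at 19) and a boys'
birth-cohort height setting (size SD 6.6 cm, timing SD 0.8 yr, intensity
SD 0.11, residual SD 1.02 cm, curve APV 13.5 / PV 10.6 / 179 cm).
Timing SDs are converted to the log-age axis with each design's median
age (13.5 and 11.5 yr, computed once from the schedule generators and
frozen), and the generative rotation centre matches each design's mean
log age for the same reason the fitter centres its axis.

What the generator does **not** emulate: secular trends, measurement-
device error structure, digit preference, seasonal growth variation, or
recruitment patterns beyond the entry/exit model above. Passing
recovery tests on these cohorts therefore shows the estimator is
consistent under the model's own assumptions at realistic noise and
design density — not that real cohort data satisfy those assumptions.

## Numerical choices and limitations

* Ages must be strictly positive (log-definable); the default analysis
  window is the open interval (7, 20) yr, with strict inequalities on
  read.
* σ_r² is floored at ~1e-10 of the data variance so noise-free input
  cannot divide by zero.
* Landmark ties (equal velocities) resolve to the earliest age.
* Variance components near zero converge slowly (EM boundary crawl);
  the parameter-collapse rule then drops the effect rather than letting
  Ψ degenerate.
* Subject-level bootstrap and BIC selection refit the model from
  scratch each time; at n≈400, N≈4000 a full fit takes a few seconds on
  one CPU, so B in the hundreds is practical.
* The benchmark experiments in `scripts/acceptance.py` run at n = 371
  (five seeds) and n = 1000 — the sizes at which the recovery targets
  are defined and which keep a full run under a minute.
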