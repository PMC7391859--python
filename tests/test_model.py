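import numpy as np
import pandas as pd
import pytest

from conftest import build_truth, quick_cohort
from sitarpy.curves import fit_landmarks
from sitarpy.data import GrowthData
from sitarpy.model import (
    RandomEffectTriple,
    ZERO_RE,
    fit_sitar,
    predict_curve,
    standardized_residuals,
    timing_sd_years,
    variance_explained,
)
from sitarpy.simulate import DesignSpec, TrueParams, simulate_cohort
from sitarpy.splines import place_knots


class TestSelfConsistency:
    def test_noise_free_zero_re_data_is_reproduced(self, small_truth):
        # spline-representable truth, so the fit can be exact
        from sitarpy.simulate import spline_project_curve
        curve = spline_project_curve(small_truth.mean_curve, np.linspace(7.3, 19.7, 400), df=5)
        truth0 = TrueParams(curve, np.zeros((3, 3)), 0.0)
        data, _ = simulate_cohort(truth0, DesignSpec(n=25, mode="cohort_sweeps", dropout=0.1, seed=4))
        fit = fit_sitar(data, place_knots(np.log(data.ages), 5))
        assert fit.sigma_r < 0.05
        blups = fit.blup_frame()
        # residual BLUP magnitudes are at the knot-mismatch approximation
        # scale, far below any real effect
        assert np.abs(blups[["alpha", "beta", "gamma"]].to_numpy()).max() < 0.1
        pred = predict_curve(fit, ZERO_RE, data.ages)
        assert np.max(np.abs(pred - data.values)) < 0.2  # knot-mismatch scale, vs ~60 cm of growth

    def test_blup_means_are_zero(self, small_fit):
        bf = small_fit.blup_frame()
        for col, sd in zip(["alpha", "beta", "gamma"], small_fit.re_sd):
            assert abs(bf[col].mean()) < 0.05 * sd

    def test_loglik_nondecreasing_within_tolerance(self, small_fit):
        h = np.array(small_fit.loglik_history)
        slack = 1e-4 * (np.abs(h).max() + 1.0)
        assert np.all(np.diff(h) > -slack)


class TestPredictCurve:
    def test_zero_re_gives_mean_curve_and_alpha_adds(self, small_fit):
        ages = np.linspace(8, 19, 50)
        mean = predict_curve(small_fit, ZERO_RE, ages)
        up5 = predict_curve(small_fit, RandomEffectTriple(alpha=5.0), ages)
        assert np.allclose(up5, mean + 5.0)

    def test_log_age_timing_shift_is_multiplicative_delay(self, small_fit):
        # a timing shift of ln(1.05) delays the curve by 5% of age
        ages = np.linspace(9, 18, 40)
        shifted = predict_curve(small_fit, RandomEffectTriple(beta=np.log(1.05)), ages)
        delayed = predict_curve(small_fit, ZERO_RE, ages / 1.05)
        assert np.allclose(shifted, delayed, atol=1e-10)


class TestEffectsSubsets:
    def test_excluded_effects_are_zero_with_no_variance(self, small_cohort):
        data, _ = small_cohort
        fit = fit_sitar(data, place_knots(np.log(data.ages), 4), include_effects=("size",))
        assert fit.include_effects == ("size",)
        assert fit.re_cov[1, 1] == 0.0 and fit.re_cov[2, 2] == 0.0
        bf = fit.blup_frame()
        assert np.all(bf["beta"] == 0.0) and np.all(bf["gamma"] == 0.0)
        assert fit.re_cov[0, 0] > 0

    def test_multiple_measures_rejected(self, small_cohort):
        data, _ = small_cohort
        f = data.frame.copy()
        f["measure"] = np.where(np.arange(len(f)) % 2 == 0, "height", "weight")
        with pytest.raises(ValueError, match="one measure"):
            fit_sitar(GrowthData(f), place_knots(np.log(data.ages), 4))


class TestInvariants:
    def test_single_record_subject_has_shrunk_timing_blup(self, small_cohort):
        data, _ = small_cohort
        extra = pd.DataFrame({"id": ["LONE"], "age": [12.0], "value": [150.0]})
        aug = GrowthData(pd.concat([data.frame, extra], ignore_index=True))
        fit = fit_sitar(aug, place_knots(np.log(aug.ages), 5))
        # one record cannot pin a timing shift: the BLUP shrinks well
        # inside the population SD (only the prior correlation with size
        # keeps it off exactly zero)
        lone = fit.blups["LONE"]
        assert abs(lone.beta) < 0.5 * np.sqrt(fit.re_cov[1, 1] + 1e-12)

    def test_translation_equivariance(self, dense_cohort):
        data, _ = dense_cohort
        spec = place_knots(np.log(data.ages), 6)
        base = fit_sitar(data, spec)
        target = data.frame["id"].iloc[0]
        shifted = data.frame.copy()
        c = 10.0
        shifted.loc[shifted["id"] == target, "value"] += c
        fit2 = fit_sitar(GrowthData(shifted), spec)
        # BLUPs are mean-zero, so the population mean absorbs c/n of the shift
        n = base.n_subjects
        d_alpha = fit2.blups[target].alpha - base.blups[target].alpha
        assert abs(d_alpha - c * (1 - 1 / n)) < 0.01 * c
        lm1, lm2 = fit_landmarks(base), fit_landmarks(fit2)
        assert abs(lm1.age_peak - lm2.age_peak) < 0.05


class TestVarianceExplained:
    def test_zero_random_effects_give_near_zero(self, small_truth):
        # spline-representable truth and dense visits, so neither curve
        # approximation nor per-subject noise absorption inflates the statistic
        from sitarpy.simulate import spline_project_curve
        curve = spline_project_curve(small_truth.mean_curve, np.linspace(7.3, 19.7, 400), df=5)
        rng = np.random.default_rng(9)
        ages0 = np.arange(7.25, 19.8, 0.5)
        rows = []
        for i in range(40):
            a = ages0 + rng.uniform(-0.1, 0.1, len(ages0))
            v = curve.value(a) + rng.normal(0, 0.8, len(a))
            rows.extend((f"Z{i}", aa, vv) for aa, vv in zip(a, v))
        data = GrowthData(pd.DataFrame(rows, columns=["id", "age", "value"]))
        fit = fit_sitar(data, place_knots(np.log(data.ages), 5))
        assert variance_explained(fit, data) < 15.0

    def test_decreases_with_generative_noise(self):
        ve = []
        for sigma in (0.3, 1.2):
            truth = build_truth(sigma=sigma)
            data, _, _ = quick_cohort(truth, n=80, seed=21)
            fit = fit_sitar(data, place_knots(np.log(data.ages), 5))
            ve.append(variance_explained(fit, data))
        assert ve[1] < ve[0]


class TestTimingSdYears:
    def test_identity_without_log_age(self, small_cohort):
        data, _ = small_cohort
        spec = place_knots(data.ages, 4, use_log_age=False)
        fit = fit_sitar(data, spec)
        assert timing_sd_years(fit) == pytest.approx(np.sqrt(fit.re_cov[1, 1]))

    def test_recovers_generative_timing_scale(self, dense_cohort, dense_fit, small_truth):
        # generative timing SD (log axis) x median age, within sampling error
        data, _ = dense_cohort
        target = np.sqrt(small_truth.re_cov_true[1, 1]) * np.median(data.ages)
        assert timing_sd_years(dense_fit) == pytest.approx(target, rel=0.30)


class TestStandardizedResiduals:
    def test_noise_free_data_raise_no_false_outliers(self, small_truth):
        truth0 = TrueParams(small_truth.mean_curve, np.zeros((3, 3)), 0.0)
        data, _ = simulate_cohort(truth0, DesignSpec(n=20, mode="cohort_sweeps", dropout=0.1, seed=2))
        fit = fit_sitar(data, place_knots(np.log(data.ages), 5))
        z = standardized_residuals(fit, data)
        assert np.max(np.abs(z)) < 4.0

    def test_injected_gross_error_is_extreme(self, small_cohort):
        data, _ = small_cohort
        f = data.frame.copy()
        spec = place_knots(np.log(data.ages), 5)
        base = fit_sitar(data, spec)
        k = len(f) // 2
        f.loc[k, "value"] += 10 * base.sigma_r
        poisoned = GrowthData(f)
        fit = fit_sitar(poisoned, spec)
        z = standardized_residuals(fit, poisoned)
        assert int(np.argmax(np.abs(z))) == k
        assert abs(z[k]) > 4
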