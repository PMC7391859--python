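import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import build_truth, quick_cohort
from sitarpy.curves import CurveGrid, fit_landmarks
from sitarpy.grouping import (
    _equal_sizes,
    compare_curves,
    fit_local_models,
    predict_group_from_global,
    split_by_blup,
)
from sitarpy.model import ZERO_RE, fit_sitar, predict_curve
from sitarpy.splines import place_knots


@given(n=st.integers(10, 6000), k=st.integers(1, 9))
def test_equal_size_constraint_for_any_n_k(n, k):
    sizes = _equal_sizes(n, k)
    assert sizes.sum() == n
    assert sizes.max() - sizes.min() <= 1
    # extras sit at the extremes of the ordering
    rem = n % k
    if rem:
        assert sizes[0] == sizes.max()
    if rem >= 2:
        assert sizes[-1] == sizes.max()


def test_cohort_of_5227_splits_like_the_nine_group_design():
    sizes = _equal_sizes(5227, 9)
    assert sorted(sizes.tolist(), reverse=True) == [581] * 7 + [580] * 2


class TestSplitByBlup:
    def test_single_group_holds_everyone_with_zero_mean_res(self, small_fit):
        assign = split_by_blup(small_fit, "timing", 1)
        assert assign.sizes.tolist() == [small_fit.n_subjects]
        mean = assign.group_mean_re[0]
        for v, sd in zip(mean.as_array(), small_fit.re_sd):
            assert abs(v) < 0.06 * sd + 1e-9

    def test_groups_ordered_by_generative_timing(self, dense_cohort, dense_fit):
        data, re_true = dense_cohort
        assign = split_by_blup(dense_fit, "timing", 4)
        truth = re_true.set_index("id")["beta"]
        means = [truth.loc[assign.subjects_in(g)].mean() for g in range(1, 5)]
        assert np.all(np.diff(means) > 0)

    def test_k_exceeding_n_errors(self, small_fit):
        with pytest.raises(ValueError, match="split"):
            split_by_blup(small_fit, "timing", small_fit.n_subjects + 1)

    def test_unknown_or_absent_effect_errors(self, small_cohort):
        data, _ = small_cohort
        fit = fit_sitar(data, place_knots(np.log(data.ages), 4), include_effects=("size",))
        with pytest.raises(ValueError):
            split_by_blup(fit, "timing", 3)


class TestLocalModels:
    def test_whole_cohort_local_fit_matches_global(self, small_cohort, small_fit):
        data, _ = small_cohort
        assign = split_by_blup(small_fit, "timing", 1)
        local = fit_local_models(data, assign, df=small_fit.spec.df, omit=())[0]
        assert local.loglik == pytest.approx(small_fit.loglik, rel=0.01)

    def test_omitted_effects_are_absent(self, dense_cohort, dense_fit):
        data, _ = dense_cohort
        assign = split_by_blup(dense_fit, "timing", 2)
        fits = fit_local_models(data, assign, df=4, omit=("timing",))
        for f in fits:
            assert "timing" not in f.include_effects
            assert f.re_cov[1, 1] == 0.0

    def test_tiny_group_skipped(self, small_cohort, small_fit):
        data, _ = small_cohort
        assign = split_by_blup(small_fit, "timing", 2)
        fits = fit_local_models(data, assign, df=4, min_subjects=10**6)
        assert fits == [None, None]


class TestPredictedVsLocal:
    def test_zero_re_group_prediction_is_global_mean_curve(self, small_fit):
        assign = split_by_blup(small_fit, "timing", 1)
        grid = np.linspace(9, 18, 100)
        pred = predict_group_from_global(small_fit, assign, 1, grid)
        assert np.allclose(pred.values, predict_curve(small_fit, ZERO_RE, grid), atol=1e-6)

    def test_early_group_has_earlier_predicted_apv(self, dense_cohort, dense_fit):
        data, _ = dense_cohort
        assign = split_by_blup(dense_fit, "timing", 3)
        grid = np.linspace(8.5, 19, 400)
        from sitarpy.curves import find_landmarks, velocity_curve
        apvs = []
        for g in (1, 3):
            re = assign.group_mean_re[g - 1]
            apvs.append(find_landmarks(velocity_curve(dense_fit, re, grid)).age_peak)
        global_apv = find_landmarks(velocity_curve(dense_fit, ZERO_RE, grid)).age_peak
        assert apvs[0] < global_apv < apvs[1]


class TestCompareCurves:
    def test_identical_curves_have_zero_distance(self):
        grid = np.linspace(9, 18, 50)
        c = CurveGrid(grid, np.sin(grid), "cm")
        comp = compare_curves(c, CurveGrid(grid, np.sin(grid), "cm"))
        assert comp.max_abs == 0.0 and comp.rmse == 0.0

    def test_constant_offset_is_reported_exactly(self):
        grid = np.linspace(9, 18, 50)
        a = CurveGrid(grid, np.cos(grid), "cm")
        b = CurveGrid(grid, np.cos(grid) + 2.0, "cm")
        comp = compare_curves(a, b)
        assert comp.max_abs == pytest.approx(2.0)
        assert comp.rmse == pytest.approx(2.0)

    def test_grid_mismatch_errors(self):
        a = CurveGrid(np.linspace(9, 18, 50), np.zeros(50), "cm")
        b = CurveGrid(np.linspace(9, 18, 60), np.zeros(60), "cm")
        with pytest.raises(ValueError, match="grid"):
            compare_curves(a, b)


def test_intensity_subgroups_rank_local_peak_velocity():
    """With well-separated intensity variation, subgroup local models
    recover strictly increasing peak velocities."""
    truth = build_truth(size_sd=3.0, timing_sd=0.03, intensity_sd=0.25, sigma=0.3)
    data, _, _ = quick_cohort(truth, n=240, seed=31, dropout=0.1)
    gfit = fit_sitar(data, place_knots(np.log(data.ages), 5))
    assign = split_by_blup(gfit, "intensity", 3)
    fits = fit_local_models(data, assign, df=5, omit=("timing", "intensity"))
    pvs = [fit_landmarks(f).vel_peak for f in fits]
    assert np.all(np.diff(pvs) > 0)
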