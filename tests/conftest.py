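import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from sitarpy.data import GrowthData
from sitarpy.model import fit_sitar
from sitarpy.simulate import DesignSpec, TrueParams, make_mean_curve, simulate_cohort
from sitarpy.splines import place_knots

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def build_truth(
    size_sd=5.0,
    timing_sd=0.06,
    intensity_sd=0.12,
    sigma=0.5,
    corr=0.3,
    apv=13.8,
    pv=9.5,
    adult=175.0,
):
    """Compact growth-like generative truth for unit tests."""
    curve = make_mean_curve(adult, apv, pv, 5.4)
    c = np.array([[1, corr, corr], [corr, 1, corr], [corr, corr, 1]])
    sd = np.array([size_sd, timing_sd, intensity_sd])
    return TrueParams(curve, c * np.outer(sd, sd), sigma)


def quick_cohort(truth=None, n=60, seed=0, mode="cohort_sweeps", dropout=0.2):
    truth = truth or build_truth()
    design = DesignSpec(n=n, mode=mode, dropout=dropout, seed=seed)
    return simulate_cohort(truth, design) + (truth,)


@pytest.fixture(scope="session")
def small_truth():
    return build_truth()


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    """n=60 sweep-design cohort with known truth."""
    data, re_true, _ = quick_cohort(small_truth, n=60, seed=11)
    return data, re_true


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    data, _ = small_cohort
    spec = place_knots(np.log(data.ages), 5)
    return fit_sitar(data, spec)


@pytest.fixture(scope="session")
def dense_cohort(small_truth):
    """n=80 densely observed cohort (6-monthly, full follow-up)."""
    rng = np.random.default_rng(7)
    re = rng.multivariate_normal(np.zeros(3), small_truth.re_cov_true, size=80)
    ages0 = np.arange(7.25, 19.8, 0.5)
    rows = []
    for i in range(80):
        a = ages0 + rng.uniform(-0.1, 0.1, len(ages0))
        v = small_truth.subject_curve(a, *re[i]) + rng.normal(0, small_truth.sigma_r_true, len(a))
        rows.extend((f"D{i:03d}", aa, vv) for aa, vv in zip(a, v))
    data = GrowthData(pd.DataFrame(rows, columns=["id", "age", "value"]))
    truth_frame = pd.DataFrame(
        {"id": [f"D{i:03d}" for i in range(80)], "alpha": re[:, 0], "beta": re[:, 1], "gamma": re[:, 2]}
    )
    return data, truth_frame


@pytest.fixture(scope="session")
def dense_fit(dense_cohort):
    data, _ = dense_cohort
    spec = place_knots(np.log(data.ages), 6)
    return fit_sitar(data, spec)
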