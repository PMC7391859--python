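import numpy as np
import pandas as pd
import pytest

from sitarpy.data import GrowthData
from sitarpy.model import fit_sitar
from sitarpy.multimeasure import (
    EffectCorrelationMatrix,
    cross_measure_correlations,
    seriate,
    size_percent_sd,
)
from sitarpy.curves import value_at_age
from sitarpy.simulate import make_mean_curve
from sitarpy.splines import place_knots


def _two_trait_fits(rho=0.8, n=300, seed=13):
    """Two measurements whose size effects share correlation rho."""
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    curves = {
        "height": make_mean_curve(172.0, 13.5, 9.0, 5.3),
        "legs": make_mean_curve(80.0, 13.3, 4.5, 2.5),
    }
    sd_a = {"height": 6.0, "legs": 4.0}
    ages = np.linspace(8, 18, 8)
    fits = {}
    for j, (name, curve) in enumerate(curves.items()):
        rows = []
        for i in range(n):
            a = sd_a[name] * z[i, j]
            t = ages + rng.uniform(-0.2, 0.2, len(ages))
            v = curve.value(t) + a + rng.normal(0, 0.5, len(ages))
            rows.extend((f"S{i:04d}", tt, vv) for tt, vv in zip(t, v))
        data = GrowthData(pd.DataFrame(rows, columns=["id", "age", "value"]), measure=name)
        fits[name] = fit_sitar(data, place_knots(np.log(data.ages), 4))
    return fits


class TestCrossMeasureCorrelations:
    def test_recovers_generative_size_correlation(self):
        fits = _two_trait_fits(rho=0.8)
        ecm = cross_measure_correlations(fits, "size")
        assert ecm.matrix.loc["height", "legs"] == pytest.approx(0.8, abs=0.1)
        assert ecm.matrix.loc["height", "height"] == 1.0
        assert ecm.pair_n.loc["height", "legs"] == 300

    def test_symmetric_unit_diagonal_bounded(self):
        fits = _two_trait_fits(rho=0.3, n=80, seed=5)
        ecm = cross_measure_correlations(fits, "size")
        m = ecm.matrix.to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert np.all(np.abs(m) <= 1.0 + 1e-12)

    def test_too_few_shared_subjects_marks_missing(self):
        fits = _two_trait_fits(rho=0.5, n=40, seed=2)
        # disjoint ids: relabel one fit's blups
        other = fits["legs"]
        other.blups = {f"X{k}": v for k, v in other.blups.items()}
        ecm = cross_measure_correlations(fits, "size")
        assert np.isnan(ecm.matrix.loc["height", "legs"])

    def test_needs_two_measurements(self):
        with pytest.raises(ValueError):
            cross_measure_correlations({"only": None}, "size")


def _matrix(names, m):
    df = pd.DataFrame(np.asarray(m, float), index=names, columns=names)
    return EffectCorrelationMatrix("size", list(names), df, df * 0 + 100)


class TestSeriation:
    def test_two_by_two_order_stable(self):
        ecm = _matrix(["a", "b"], [[1, 0.5], [0.5, 1]])
        order, _ = seriate(ecm)
        assert order == ["a", "b"]

    def test_strongly_coupled_pair_becomes_adjacent(self):
        names = ["u", "v", "w", "x"]
        m = np.array(
            [
                [1.00, 0.25, 0.90, 0.22],
                [0.25, 1.00, 0.20, 0.02],
                [0.90, 0.20, 1.00, 0.28],
                [0.22, 0.02, 0.28, 1.00],
            ]
        )
        order, _ = seriate(_matrix(names, m))
        assert abs(order.index("u") - order.index("w")) == 1

    def test_block_diagonal_blocks_stay_contiguous(self):
        names = ["a1", "a2", "b1", "b2"]
        m = np.array(
            [
                [1.0, 0.8, 0.0, 0.0],
                [0.8, 1.0, 0.0, 0.0],
                [0.0, 0.0, 1.0, 0.7],
                [0.0, 0.0, 0.7, 1.0],
            ]
        )
        order, _ = seriate(_matrix(names, m))
        pos = {nm: order.index(nm) for nm in names}
        assert abs(pos["a1"] - pos["a2"]) == 1
        assert abs(pos["b1"] - pos["b2"]) == 1

    def test_output_is_pure_permutation(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(-0.5, 0.9, (5, 5))
        m = (a + a.T) / 2
        np.fill_diagonal(m, 1.0)
        ecm = _matrix(list("abcde"), m)
        _, out = seriate(ecm)
        assert sorted(out.matrix.to_numpy().ravel()) == pytest.approx(
            sorted(ecm.matrix.to_numpy().ravel())
        )

    def test_missing_entries_error(self):
        m = _matrix(["a", "b"], [[1, np.nan], [np.nan, 1]])
        with pytest.raises(ValueError, match="missing"):
            seriate(m)


class TestSizePercentSd:
    def test_definition_identity(self, small_fit):
        expected = 100.0 * np.sqrt(small_fit.re_cov[0, 0]) / value_at_age(small_fit, 19.0)
        assert size_percent_sd(small_fit) == pytest.approx(expected)

    def test_recovers_generative_ratio(self, dense_fit, small_truth):
        truth_pct = 100.0 * np.sqrt(small_truth.re_cov_true[0, 0]) / float(
            small_truth.mean_curve.value(19.0)
        )
        assert size_percent_sd(dense_fit) == pytest.approx(truth_pct, rel=0.15)
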