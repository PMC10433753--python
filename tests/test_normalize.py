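"""Cross-study normalization: unit conversion, scale factors, mean curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from gsiskit.normalize import (
    ExperimentalCurve,
    MeanCurve,
    compute_mean_curve,
    convert_units,
    curves_to_frame,
    fold_to_absolute,
    frame_to_curves,
    normalize_dataset,
    normalize_steady_state,
    ss_scale_factor,
    tc_scale_factor,
)


def curve(y, x=None, **kw):
    x = list(range(1, len(y) + 1)) if x is None else x
    defaults = dict(
        study_id="s", metabolite="g6p", measurement_type="absolute", unit="mM"
    )
    defaults.update(kw)
    return ExperimentalCurve(x=np.asarray(x, float), y=np.asarray(y, float), **defaults)


class TestUnitConversion:
    def test_islet_content_to_concentration(self):
        # 1 pmol/islet over 2 nl islet water = 0.5 mM
        c = convert_units(curve([1.0, 2.0], unit="pmol/islet"))
        np.testing.assert_allclose(c.y, [0.5, 1.0])
        assert c.unit == "mM"

    def test_identity_for_model_units(self):
        c = convert_units(curve([1.0, 2.0], unit="mM"))
        np.testing.assert_allclose(c.y, [1.0, 2.0])

    def test_unregistered_unit_raises_with_name(self):
        with pytest.raises(ValueError, match="arbitrary"):
            convert_units(curve([1.0, 2.0], unit="arbitrary"))


class TestFoldConversion:
    def test_elementwise_product(self):
        c = fold_to_absolute(curve([1, 2, 3], measurement_type="fold", unit="fold"), 0.1)
        np.testing.assert_allclose(c.y, [0.1, 0.2, 0.3])
        assert c.measurement_type == "absolute"

    def test_fold_one_maps_to_basal(self):
        c = fold_to_absolute(curve([1.0, 1.5], measurement_type="fold", unit="fold"), 0.37)
        assert c.y[0] == pytest.approx(0.37)

    def test_nonpositive_basal_rejected(self):
        with pytest.raises(ValueError):
            fold_to_absolute(curve([1, 2], measurement_type="fold", unit="fold"), 0.0)


class TestMeanCurve:
    def test_single_curve_is_identity(self):
        c = curve([1.0, 2.0, 3.0])
        m = compute_mean_curve([c])
        np.testing.assert_allclose(m(c.x), c.y)

    def test_equal_weight_average(self):
        m = compute_mean_curve([curve([1, 2, 3]), curve([3, 4, 5])])
        np.testing.assert_allclose(m.value, [2, 3, 4])

    def test_two_point_data_uses_linear_interpolation(self):
        m = compute_mean_curve([curve([1.0, 3.0], x=[1.0, 10.0])])
        assert m.kind == "linear"
        assert m(5.5) == pytest.approx(2.0)

    def test_evaluation_clamped_outside_domain(self):
        m = compute_mean_curve([curve([1.0, 2.0, 3.0])])
        assert m(0.1) == pytest.approx(1.0)
        assert m(99.0) == pytest.approx(3.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_mean_curve([])


class TestScaleFactor:
    def test_identity_when_curve_equals_mean(self):
        c = curve([1.0, 2.0, 3.0])
        m = compute_mean_curve([c])
        assert ss_scale_factor(c, m) == pytest.approx(1.0)

    def test_double_curve_halved(self):
        m = compute_mean_curve([curve([1.0, 2.0, 3.0])])
        assert ss_scale_factor(curve([2.0, 4.0, 6.0]), m) == pytest.approx(0.5)

    def test_worked_example_21_over_14(self):
        m = MeanCurve("g6p", np.array([1.0, 2, 3]), np.array([1.5, 3.0, 4.5]))
        assert ss_scale_factor(curve([1, 2, 3]), m) == pytest.approx(21 / 14)

    def test_all_zero_curve_rejected(self):
        m = MeanCurve("g6p", np.array([1.0, 2, 3]), np.array([1.5, 3.0, 4.5]))
        with pytest.raises(ValueError):
            ss_scale_factor(curve([0.0, 0.0, 0.0]), m)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_closed_form_matches_numeric_minimizer(self, seed):
        """f = ΣCC̄/ΣC² is the argmin of the squared offset to the mean."""
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 8)
        x = np.sort(rng.uniform(1, 35, n))
        x += np.arange(n) * 1e-3  # strictly increasing
        c = curve(rng.uniform(0.05, 5.0, n), x=x)
        m = MeanCurve("g6p", x, rng.uniform(0.05, 5.0, n))

        f_closed = ss_scale_factor(c, m)
        obj = lambda f: float(np.sum((f * c.y - m(c.x)) ** 2))
        res = minimize_scalar(obj, bounds=(1e-6, 1e3), method="bounded",
                              options={"xatol": 1e-12})
        assert f_closed == pytest.approx(res.x, rel=1e-6)
        assert obj(f_closed) <= obj(res.x) + 1e-12


class TestIterativeNormalization:
    def test_two_curve_hand_iteration(self):
        scaled, fs, mean = normalize_steady_state(
            [curve([1, 2, 3], study_id="a"), curve([2, 4, 6], study_id="b")]
        )
        assert fs.converged
        np.testing.assert_allclose(scaled[0].y, scaled[1].y)
        np.testing.assert_allclose(scaled[0].y, [1.5, 3.0, 4.5])
        assert fs.factors[("a", 0)] == pytest.approx(1.5)
        assert fs.factors[("b", 1)] == pytest.approx(0.75)

    def test_identical_curves_converge_immediately(self):
        scaled, fs, _ = normalize_steady_state([curve([1, 2, 3]), curve([1, 2, 3])])
        assert fs.iterations == 1
        assert all(f == pytest.approx(1.0) for f in fs.factors.values())

    def test_idempotence(self):
        scaled, _, _ = normalize_steady_state(
            [curve([1, 2, 3], study_id="a"), curve([2, 4, 6], study_id="b")]
        )
        _, fs2, _ = normalize_steady_state(scaled)
        assert all(abs(f - 1) < 1e-6 for f in fs2.factors.values())

    def test_post_convergence_factors_are_unity(self):
        rng = np.random.default_rng(3)
        curves = [
            curve(rng.uniform(0.5, 2.0) * np.array([1.0, 2.0, 3.0]), study_id=f"s{i}")
            for i in range(4)
        ]
        scaled, fs, mean = normalize_steady_state(curves)
        assert fs.converged
        for c in scaled:
            assert ss_scale_factor(c, mean) == pytest.approx(1.0, abs=1e-6)

    def test_dispersion_never_increases(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            base = rng.uniform(0.1, 3.0, 5).cumsum()
            curves = [
                curve(base * rng.lognormal(0, 0.4) * rng.lognormal(0, 0.05, 5),
                      study_id=f"s{i}")
                for i in range(4)
            ]
            scaled, _, _ = normalize_steady_state(curves)
            before = np.array([c.y for c in curves])
            after = np.array([c.y for c in scaled])
            cv = lambda a: np.mean(a.std(axis=0) / a.mean(axis=0))
            assert cv(after) <= cv(before) + 1e-12

    def test_equivariance_under_study_rescaling(self):
        """Scaling one input study by k changes its factor by ~1/k and leaves
        the normalized curves invariant up to a common scale."""
        base = [curve([1, 2, 3], study_id="a"), curve([1.2, 2.1, 3.3], study_id="b")]
        scaled1, fs1, _ = normalize_steady_state(base)
        k = 4.0
        mod = [curve(np.array([1, 2, 3.0]) * k, study_id="a"),
               curve([1.2, 2.1, 3.3], study_id="b")]
        scaled2, fs2, _ = normalize_steady_state(mod)
        common = scaled2[0].y[0] / scaled1[0].y[0]
        for c1, c2 in zip(scaled1, scaled2):
            np.testing.assert_allclose(c2.y, c1.y * common, rtol=1e-6)


class TestTimeCourseAnchoring:
    def _mean(self):
        return MeanCurve("g6p", np.array([1.0, 10.0, 35.0]), np.array([0.1, 0.4, 0.9]))

    def test_anchored_final_value_matches_mean(self):
        tc = curve([0.2, 0.5, 0.8], x=[0, 30, 60], x_type="time", inc_dose=10.0)
        f = tc_scale_factor(tc, self._mean())
        assert f == pytest.approx(0.5)
        assert (tc.y * f)[-1] == pytest.approx(0.4)

    def test_identity_when_already_anchored(self):
        tc = curve([0.2, 0.3, 0.4], x=[0, 30, 60], x_type="time", inc_dose=10.0)
        assert tc_scale_factor(tc, self._mean()) == pytest.approx(1.0)

    def test_zero_final_point_rejected(self):
        with pytest.raises(ValueError):
            tc_scale_factor(
                curve([0.2, 0.1, 0.0], x=[0, 30, 60], x_type="time", inc_dose=10.0),
                self._mean(),
            )


class TestSchema:
    def test_negative_measurements_rejected_at_load(self):
        with pytest.raises(ValueError, match="negative"):
            curve([1.0, -0.5])

    def test_csv_frame_round_trip(self):
        curves = [
            curve([1, 2, 3], study_id="a"),
            curve([0.2, 0.5], x=[0, 60], x_type="time", inc_dose=16.7, study_id="b"),
        ]
        back = frame_to_curves(curves_to_frame(curves))
        assert len(back) == 2
        by_id = {c.study_id: c for c in back}
        np.testing.assert_allclose(by_id["a"].y, [1, 2, 3])
        assert by_id["b"].x_type == "time"
        assert by_id["b"].inc_dose == 16.7

    def test_full_pipeline_reduces_cv(self):
        rng = np.random.default_rng(5)
        base = np.array([0.1, 0.25, 0.4, 0.6])
        curves = []
        for i in range(4):
            bias = rng.lognormal(0, 0.5)
            curves.append(curve(base * bias, x=[1, 5, 15, 30], study_id=f"s{i}"))
        curves.append(
            curve(base / base[0], x=[1, 5, 15, 30], study_id="s_fold",
                  measurement_type="fold", unit="fold", pre_dose=1.0)
        )
        out, rep = normalize_dataset(curves)
        info = rep["metabolites"]["g6p"]
        assert info["converged"]
        assert info["cv_after"] < info["cv_before"]
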