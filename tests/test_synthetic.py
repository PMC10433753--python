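"""Synthetic multi-study data generation and ground-truth recovery."""

import numpy as np
import pytest

from gsiskit.normalize import curves_to_frame, frame_to_curves, normalize_dataset
from gsiskit.synthetic import (
    StudySpec,
    default_study_specs,
    generate_ground_truth,
    generate_study_set,
    make_calibration_dataset,
    recovery_report,
)


@pytest.fixture(scope="module")
def truth(model):
    return generate_ground_truth(model)


class TestGroundTruth:
    def test_matches_steady_state_componentwise(self, model, truth):
        import gsiskit as gk
        from gsiskit._kernel import SPECIES_ORDER, compile_model
        from gsiskit.simulate import _integrate

        cm = compile_model(model)
        y_basal = _integrate(cm, cm.y0(), np.array([0.0, 60.0]), 3.0, 1e-8, 1e-10)[-1]
        y = gk.steady_state(model, 16.7, y0=y_basal)
        c = cm.concentrations(y, 16.7)
        row = truth.dose_response.loc[16.7]
        for met in ("g6p", "pyr", "atp", "adp"):
            assert row[met] == pytest.approx(c[SPECIES_ORDER.index(met)], rel=1e-6)

    def test_monotone_in_dose_for_intermediates(self, truth):
        for met in ("g6p", "fbp", "pep", "pyr", "lac"):
            vals = truth.dose_response[met].to_numpy()
            assert np.all(np.diff(vals) > 0), met

    def test_true_vmax_recorded(self, model, truth):
        assert len(truth.vmax_true) == 16
        assert truth.vmax_true["HEX1_Vmax"] == model.parameters()["HEX1_Vmax"]


class TestStudySet:
    def test_degenerate_noise_reproduces_truth(self, truth):
        spec = StudySpec("s1", bias_sigma_log=0.0, noise_cv=0.0)
        sset = generate_study_set(truth, [spec], seed=1)
        c = next(c for c in sset.curves if c.metabolite == "g6p")
        expected = np.interp(c.x, truth.doses, truth.dose_response["g6p"].to_numpy())
        np.testing.assert_allclose(c.y, expected, rtol=1e-12)
        assert sset.bias_factors["s1"] == pytest.approx(1.0)

    def test_fold_reporting_is_unity_at_pre_dose(self, truth):
        spec = StudySpec("s1", reporting="fold", unit="fold", noise_cv=0.0, pre_dose=2.8)
        sset = generate_study_set(truth, [spec], seed=2)
        for c in sset.curves:
            assert c.y[list(c.x).index(2.8)] == pytest.approx(1.0)

    def test_seeded_regeneration_is_bit_identical(self, truth):
        specs = default_study_specs(4)
        a = generate_study_set(truth, specs, seed=9)
        b = generate_study_set(truth, specs, seed=9)
        for ca, cb in zip(a.curves, b.curves):
            np.testing.assert_array_equal(ca.y, cb.y)
        assert a.bias_factors == b.bias_factors

    def test_noise_model_cv_calibration(self, truth):
        """Empirical CV of replicated samples matches the configured CV."""
        cv = 0.10
        rng_specs = [
            StudySpec(f"s{i}", bias_sigma_log=0.0, noise_cv=cv, doses=(1.0, 16.7),
                      metabolites=("g6p",))
            for i in range(10_000)
        ]
        sset = generate_study_set(truth, rng_specs, seed=123)
        vals = np.array([c.y[1] for c in sset.curves])
        emp_cv = vals.std() / vals.mean()
        assert emp_cv == pytest.approx(cv, rel=0.05)

    def test_schema_round_trip_into_normalize(self, truth):
        sset = generate_study_set(truth, default_study_specs(3), seed=4)
        back = frame_to_curves(curves_to_frame(sset.curves))
        assert len(back) == len(sset.curves)
        mets_a = sorted({c.metabolite for c in sset.curves})
        mets_b = sorted({c.metabolite for c in back})
        assert mets_a == mets_b


class TestRecovery:
    def test_noise_free_pipeline_recovers_truth(self, truth):
        specs = [
            StudySpec(f"s{i}", noise_cv=0.0) for i in range(5)
        ]
        sset = generate_study_set(truth, specs, seed=21)
        scaled, rep = normalize_dataset(sset.curves)
        info = rep["metabolites"]["g6p"]
        fs_obj = type("F", (), {})()
        fs_obj.factors = {
            (k.split("#")[0], int(k.split("#")[1])): v for k, v in info["factors"].items()
        }
        report = recovery_report(scaled, truth, sset.bias_factors, scale_factors=fs_obj)
        assert report["bias_recovery_spread"] < 0.05
        assert all(v < 1e-6 for v in report["curve_rmse_rel"].values())

    def test_report_deterministic(self, truth):
        specs = [StudySpec("s1", noise_cv=0.0)]
        sset = generate_study_set(truth, specs, seed=5)
        scaled, _ = normalize_dataset(sset.curves)
        r1 = recovery_report(scaled, truth, sset.bias_factors)
        r2 = recovery_report(scaled, truth, sset.bias_factors)
        assert r1 == r2


class TestCalibrationDataset:
    def test_noise_free_curves_lie_on_truth(self, model):
        curves, truth = make_calibration_dataset(model)
        key = (3.0, 16.7)
        df = truth.time_courses[key]
        c = next(
            c for c in curves if c.metabolite == "atp" and c.inc_dose == 16.7
        )
        np.testing.assert_allclose(c.y, df["atp"].to_numpy(), rtol=1e-12)

    def test_observables_exclude_rule_governed_cofactors(self, model):
        curves, _ = make_calibration_dataset(model)
        mets = {c.metabolite for c in curves}
        assert "nad" not in mets and "nadh" not in mets and "phos" not in mets
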