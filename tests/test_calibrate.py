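"""Calibration objective and hybrid optimizer behavior.

The heavy full-scale recovery run lives in the acceptance suite; here the
objective structure, the pattern search, and a reduced-dimension recovery
are exercised.
"""

import numpy as np
import pytest

import gsiskit as gk
from gsiskit.calibrate import (
    CalibrationProblem,
    fit,
    fit_global,
    fit_local,
    residual_cost,
)
from gsiskit.synthetic import make_calibration_dataset


@pytest.fixture(scope="module")
def toy_problem(model):
    """Small noise-free calibration problem on the reference model."""
    curves, _ = make_calibration_dataset(
        model, protocols=((3.0, 16.7),), metabolites=("g6p", "fbp", "pyr", "atp", "adp")
    )
    return CalibrationProblem(model, curves, restarts=2, evals_per_restart=400, seed=7)


class QuadraticStub:
    """1-parameter analytic surrogate with minimum at v = 3."""

    fitted_ids = ("v",)
    bounds = (1e-2, 5000.0)

    def cost(self, theta):
        return float((theta[0] - 3.0) ** 2)


class TestResidualCost:
    def test_zero_at_generating_parameters(self, toy_problem):
        assert toy_problem.cost(toy_problem._start) < 1e-6

    def test_single_residual_is_squared(self, model):
        from gsiskit.normalize import ExperimentalCurve

        curves, truth = make_calibration_dataset(
            model, protocols=((3.0, 16.7),), metabolites=("atp",)
        )
        c = curves[0]
        shifted = ExperimentalCurve(
            study_id=c.study_id,
            metabolite="atp",
            measurement_type="absolute",
            unit="mM",
            x=np.array([0.0, 60.0]),
            y=np.array([c.y[0], c.y[-1] + 2.0]),  # one residual of 2
            x_type="time",
            pre_dose=3.0,
            inc_dose=16.7,
        )
        prob = CalibrationProblem(model, [shifted])
        assert prob.cost(prob._start) == pytest.approx(4.0, abs=1e-3)

    def test_additive_over_experiments(self, model):
        curves, _ = make_calibration_dataset(
            model, protocols=((3.0, 10.0), (3.0, 30.0)), metabolites=("atp", "g6p")
        )
        a = [c for c in curves if c.inc_dose == 10.0]
        b = [c for c in curves if c.inc_dose == 30.0]
        theta = CalibrationProblem(model, curves)._start * 1.2
        ca = CalibrationProblem(model, a).cost(theta)
        cb = CalibrationProblem(model, b).cost(theta)
        cab = CalibrationProblem(model, curves).cost(theta)
        assert cab == pytest.approx(ca + cb, rel=1e-6)

    def test_out_of_bounds_rejected(self, toy_problem):
        bad = toy_problem._start.copy()
        bad[0] = 1e-5
        with pytest.raises(ValueError):
            residual_cost(bad, toy_problem)

    def test_truth_is_no_worse_than_perturbations(self, toy_problem):
        rng = np.random.default_rng(11)
        c0 = toy_problem.cost(toy_problem._start)
        for _ in range(10):
            pert = toy_problem._start * 10 ** rng.uniform(-0.2, 0.2, 16)
            assert toy_problem.cost(np.clip(pert, *toy_problem.bounds)) >= c0


class TestPatternSearch:
    def test_quadratic_converges_to_minimum(self):
        res = fit_local(QuadraticStub(), np.array([1.0]))
        assert res.parameters["v"] == pytest.approx(3.0, abs=1e-4)

    def test_start_at_minimum_is_returned(self):
        res = fit_local(QuadraticStub(), np.array([3.0]))
        assert res.parameters["v"] == pytest.approx(3.0, abs=1e-6)
        assert res.cost == pytest.approx(0.0, abs=1e-10)

    def test_final_cost_never_exceeds_start_cost(self, toy_problem):
        start = toy_problem._start * 1.5
        c_start = toy_problem.cost(start)
        res = fit_local(toy_problem, start, max_evals=300)
        assert res.cost <= c_start


class TestHybridFit:
    def test_seeded_global_search_is_deterministic(self, model):
        curves, _ = make_calibration_dataset(
            model, protocols=((3.0, 16.7),), metabolites=("atp", "g6p")
        )
        kwargs = dict(
            fitted_ids=("HEX1_Vmax", "PFK1_Vmax"), restarts=1, evals_per_restart=100
        )
        r1 = fit_global(CalibrationProblem(model, curves, seed=5, **kwargs))
        r2 = fit_global(CalibrationProblem(model, curves, seed=5, **kwargs))
        assert r1.cost == r2.cost
        assert r1.parameters == r2.parameters

    def test_two_parameter_recovery(self, model):
        """Reduced problem: two free Vmax, others at truth; the hybrid fit
        recovers both within 10% on noise-free data."""
        import copy

        work = copy.deepcopy(model)
        work._cache = None
        truth = {k: v for k, v in model.parameters().items()}
        curves, _ = make_calibration_dataset(model)
        prob = CalibrationProblem(
            work,
            curves,
            fitted_ids=("HEX1_Vmax", "PFK1_Vmax"),
            restarts=3,
            evals_per_restart=600,
            seed=7,
        )
        res = fit(prob)
        assert res.steady_state_reachable
        for pid, v in res.parameters.items():
            assert v / truth[pid] == pytest.approx(1.0, abs=0.10)
        lo, hi = prob.bounds
        assert all(lo <= v <= hi for v in res.parameters.values())
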