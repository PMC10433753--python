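"""Protocol simulation, steady states, dose scans, settling times."""

import numpy as np
import pandas as pd
import pytest

import gsiskit as gk
from gsiskit.simulate import Protocol, Trajectory, steady_state, time_to_steady_state


class TestProtocol:
    def test_default_pre_duration_is_60_min(self):
        assert Protocol(3.0, 16.7).pre_duration == 60.0

    def test_low_dose_preequilibrated_incubation_is_flat(self, model):
        """Pre-incubation and incubation at the same low dose: the system has
        saturated during pre-incubation, so incubation profiles are flat."""
        traj = gk.run_protocol(model, gk.Protocol(2.8, 2.8))
        inc = traj.incubation()
        for sid in ("g6p", "fbp", "pyr", "atp", "adp"):
            x = inc.species(sid)
            assert np.max(np.abs(x - x[0])) <= 0.01 * abs(x[0])

    def test_step_up_g6p_approaches_new_steady_state(self, model):
        traj = gk.run_protocol(model, gk.Protocol(3.0, 20.0))
        inc = traj.incubation()
        g6p = inc.species("g6p")
        y_ss = steady_state(model, 20.0)
        from gsiskit._kernel import SPECIES_ORDER, compile_model

        cm = compile_model(model)
        g6p_ss = cm.concentrations(y_ss, 20.0)[SPECIES_ORDER.index("g6p")]
        # rises from basal and converges to the steady-state limit; after the
        # early transient (which may overshoot) the deviation from the limit
        # decays monotonically
        assert g6p[0] < g6p_ss
        assert g6p[-1] == pytest.approx(g6p_ss, rel=1e-3)
        late = np.abs(g6p[inc.time >= 25.0] - g6p_ss)
        assert np.all(np.diff(late) <= 1e-6 + 1e-3 * late[:-1])

    def test_boundary_species_constant_within_each_phase(self, model):
        traj = gk.run_protocol(model, gk.Protocol(3.0, 16.7, 5.0, 5.0))
        for sid in ("lac_ext", "h2o", "h", "pyr_mito"):
            vals = traj.species(sid)
            assert np.all(vals == vals[0])

    def test_solver_tolerance_robustness(self, model):
        t1 = gk.run_protocol(model, gk.Protocol(3.0, 16.7, 20.0, 20.0), rtol=1e-8, atol=1e-10)
        t2 = gk.run_protocol(model, gk.Protocol(3.0, 16.7, 20.0, 20.0), rtol=1e-10, atol=1e-12)
        a = t1.concentrations.to_numpy()
        b = t2.concentrations.to_numpy()
        rel = np.max(np.abs(a - b) / np.maximum(np.abs(b), 1e-6))
        assert rel < 1e-5


class TestSteadyState:
    def test_fixed_point_returned_unchanged(self, model):
        from gsiskit._kernel import compile_model

        cm = compile_model(model)
        keep = [i for i, s in enumerate(cm.dyn_species) if s != "ins"]
        y = steady_state(model, 10.0)
        y2 = steady_state(model, 10.0, y0=y)
        assert np.allclose(y[keep], y2[keep], rtol=1e-6, atol=1e-9)

    def test_matches_long_integration_limit(self, model):
        y = steady_state(model, 10.0)
        traj = gk.run_protocol(model, gk.Protocol(10.0, 10.0, 60.0, 2000.0), report_dt=10.0)
        from gsiskit._kernel import compile_model

        cm = compile_model(model)
        final = traj.incubation().concentrations.iloc[-1]
        c_ss = cm.concentrations(y, 10.0)
        from gsiskit._kernel import SPECIES_ORDER

        for sid in ("g6p", "fbp", "pep", "atp", "adp"):
            assert final[sid] == pytest.approx(
                c_ss[SPECIES_ORDER.index(sid)], rel=1e-5
            )

    def test_residual_below_tolerance(self, model):
        from gsiskit._kernel import compile_model

        cm = compile_model(model)
        y = steady_state(model, 16.7, tol=1e-8)
        dy = cm.rhs(y, 0.0, 16.7)
        ins = cm.dyn_species.index("ins")
        dy = np.delete(dy, ins)
        assert np.max(np.abs(dy)) < 1e-8


class TestDoseResponseScan:
    def test_default_scan_doses(self, default_scan):
        assert len(default_scan) == 11
        np.testing.assert_allclose(default_scan["dose"].to_numpy(), np.linspace(1, 35, 11))

    def test_intermediates_strictly_positive(self, default_scan):
        from gsiskit.model import GLYCOLYTIC_INTERMEDIATES

        for sid in GLYCOLYTIC_INTERMEDIATES:
            assert np.all(default_scan[sid] > 0)

    def test_energy_state_rises_with_dose(self, default_scan):
        r = default_scan["atp_adp_ratio"].to_numpy()
        assert np.all(np.diff(r) > 0)
        assert r[-1] / r[0] > 2


class TestTimeToSteadyState:
    def _traj(self, t, values: dict):
        df = pd.DataFrame(values)
        return Trajectory(
            np.asarray(t, dtype=float),
            df,
            pd.DataFrame(np.zeros((len(df), 0))),
            np.array(["incubation"] * len(df)),
        )

    def test_constant_trajectory_settles_immediately(self):
        t = np.linspace(0, 60, 601)
        traj = self._traj(t, {"g6p": np.full_like(t, 0.3)})
        assert time_to_steady_state(traj) == 0.0

    def test_exponential_relaxation_settles_at_three_tau(self):
        tau = 7.0
        t = np.linspace(0, 80, 8001)
        x = 1.0 - np.exp(-t / tau)
        traj = self._traj(t, {"g6p": x})
        # |x - x_final| <= 0.05 at t ~= tau*ln(1/0.05) ~= 3*tau (long horizon
        # makes x_final ~= 1)
        assert time_to_steady_state(traj, rel_tol=0.05) == pytest.approx(
            tau * np.log(1 / 0.05), rel=0.05
        )

    def test_never_settling_reports_horizon_with_warning(self):
        t = np.linspace(0, 10, 101)
        x = np.zeros_like(t)
        x[-1] = 1.0  # deviation persists into the final grid step
        traj = self._traj(t, {"g6p": x})
        with pytest.warns(RuntimeWarning):
            out = time_to_steady_state(traj)
        assert out == t[-1]

    def test_model_step_settles_near_twenty_minutes(self, step_trajectory):
        t = time_to_steady_state(step_trajectory, rel_tol=0.05)
        assert 10.0 <= t <= 30.0


class TestBiphasicSecretion:
    def test_upward_step_produces_biphasic_irs(self, step_trajectory):
        inc = step_trajectory.incubation()
        fp = inc.fluxes["IRS_FP"].to_numpy()
        sp = inc.fluxes["IRS_SP"].to_numpy()
        assert fp.max() > 0.1  # transient first phase fires
        assert fp[-1] < 0.05 * fp.max()  # and decays away
        assert sp[-1] > 5 * sp[0]  # second phase rises to a plateau
        tail = sp[inc.time > inc.time[-1] - 10]
        assert np.max(np.abs(tail - tail[-1])) < 0.02 * abs(tail[-1])
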