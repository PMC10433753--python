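"""Condition-specific simulation of the GSIS model.

Experimental protocols are two-stage: a pre-incubation phase equilibrating
the system at one external glucose dose (60 min by default), followed by an
incubation phase at the stimulation dose.  The protocol lives in the
simulation driver — the external glucose boundary concentration is switched
between phases and the full state vector is handed over, with rule-governed
cofactors re-evaluating instantly at the dose switch.

Integration uses LSODA (stiff-capable) with rel tol 1e-8 / abs tol 1e-10 and
dense reporting output every 0.1 min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import odeint
from scipy.optimize import root

from ._kernel import REACTION_ORDER, CompiledModel, _jac_odeint, _rhs_odeint, compile_model
from .model import GLYCOLYTIC_INTERMEDIATES, ModelDefinition

__all__ = [
    "Protocol",
    "Trajectory",
    "SimulationError",
    "run_protocol",
    "steady_state",
    "dose_response_scan",
    "time_to_steady_state",
    "DEFAULT_RTOL",
    "DEFAULT_ATOL",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
REPORT_DT = 0.1  # min


class SimulationError(RuntimeError):
    """Raised when the ODE integrator or steady-state search fails."""


@dataclass
class Protocol:
    """Pre-incubation / incubation glucose protocol (doses mM, durations min)."""

    pre_dose: float
    inc_dose: float
    pre_duration: float = 60.0
    inc_duration: float = 60.0

    def validate(self) -> None:
        if not (self.pre_dose > 0 and self.inc_dose > 0):
            raise ValueError("glucose doses must be > 0")
        if not (self.pre_duration > 0 and self.inc_duration > 0):
            raise ValueError("durations must be > 0")


@dataclass
class Trajectory:
    """Simulated time course: concentrations (mM) and reaction fluxes.

    The pre-incubation phase carries negative times; the incubation phase is
    re-zeroed to t = 0 for reporting.
    """

    time: np.ndarray
    concentrations: pd.DataFrame  # time x species (all 25)
    fluxes: pd.DataFrame  # time x reactions (all 21)
    phase: np.ndarray = field(default=None)  # 'pre' | 'incubation'

    def species(self, sid: str) -> np.ndarray:
        return self.concentrations[sid].to_numpy()

    def incubation(self) -> "Trajectory":
        mask = self.phase == "incubation"
        return Trajectory(
            self.time[mask],
            self.concentrations.loc[mask].reset_index(drop=True),
            self.fluxes.loc[mask].reset_index(drop=True),
            self.phase[mask],
        )


def _integrate(
    cm: CompiledModel,
    y0: np.ndarray,
    t: np.ndarray,
    glc_ext: float,
    rtol: float,
    atol: float,
) -> np.ndarray:
    out, info = odeint(
        _rhs_odeint,
        y0,
        t,
        args=cm.odeint_args(glc_ext),
        Dfun=_jac_odeint,
        rtol=rtol,
        atol=atol,
        mxstep=50000,
        full_output=True,
    )
    if info["message"] != "Integration successful.":
        raise SimulationError(f"ODE integration failed: {info['message']}")
    return out


def _expand(cm: CompiledModel, t: np.ndarray, ys: np.ndarray, glc_ext: float):
    conc = np.empty((len(t), 25))
    flux = np.empty((len(t), 21))
    for i in range(len(t)):
        conc[i] = cm.concentrations(ys[i], glc_ext)
        flux[i] = cm.fluxes(ys[i], glc_ext)
    return conc, flux


def run_protocol(
    model: ModelDefinition,
    protocol: Protocol,
    *,
    y0: np.ndarray | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    report_dt: float = REPORT_DT,
    cofactor_rules: bool = True,
    datp: bool = True,
) -> Trajectory:
    """Two-stage integration of a pre-incubation/incubation protocol.

    ``cofactor_rules=False`` promotes phosphate and the pyridine nucleotides
    to dynamic states (NADHOX closes the redox loop); ``datp=False`` disables
    the adenine-pool adjustment flux.  Both switches exist for conservation
    analyses.
    """
    protocol.validate()
    cm = compile_model(model, rules_on=cofactor_rules, datp_on=datp)
    if y0 is None:
        y0 = cm.y0()

    from ._kernel import SPECIES_ORDER

    t_pre = np.arange(0.0, protocol.pre_duration + report_dt / 2, report_dt)
    ys_pre = _integrate(cm, y0, t_pre, protocol.pre_dose, rtol, atol)
    t_inc = np.arange(0.0, protocol.inc_duration + report_dt / 2, report_dt)
    ys_inc = _integrate(cm, ys_pre[-1], t_inc, protocol.inc_dose, rtol, atol)

    conc_pre, flux_pre = _expand(cm, t_pre, ys_pre, protocol.pre_dose)
    conc_inc, flux_inc = _expand(cm, t_inc, ys_inc, protocol.inc_dose)

    time = np.concatenate([t_pre - protocol.pre_duration, t_inc])
    conc = pd.DataFrame(np.vstack([conc_pre, conc_inc]), columns=SPECIES_ORDER)
    flux = pd.DataFrame(np.vstack([flux_pre, flux_inc]), columns=REACTION_ORDER)
    phase = np.array(["pre"] * len(t_pre) + ["incubation"] * len(t_inc))
    return Trajectory(time, conc, flux, phase)


def steady_state(
    model: ModelDefinition,
    glc: float,
    *,
    y0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_horizon: float = 1e4,
    chunk: float = 250.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    polish: bool = True,
) -> np.ndarray:
    """Steady state of the dynamic state vector at a fixed glucose dose.

    Integrates in chunks until the sup-norm of dx/dt falls below ``tol``
    (mM/min), then optionally polishes the metabolic states with a Newton
    solve.  Secreted insulin accumulates linearly and is excluded from the
    stationarity criterion.
    """
    cm = compile_model(model)
    y = cm.y0() if y0 is None else np.array(y0, dtype=float)
    ins_pos = cm.dyn_species.index("ins")
    mask = np.ones(len(y), dtype=bool)
    mask[ins_pos] = False

    elapsed = 0.0
    while elapsed < max_horizon:
        t = np.array([0.0, chunk])
        y = _integrate(cm, y, t, glc, rtol, atol)[-1]
        elapsed += chunk
        dy = cm.rhs(y, 0.0, glc)
        if np.max(np.abs(dy[mask])) < tol:
            break
    else:
        raise SimulationError(
            f"no steady state within {max_horizon} min at glc={glc} mM "
            f"(residual {np.max(np.abs(dy[mask])):.3g} mM/min)"
        )

    if polish:
        idx = np.where(mask)[0]

        def resid(z):
            yy = y.copy()
            yy[idx] = z
            return cm.rhs(yy, 0.0, glc)[idx]

        sol = root(resid, y[idx], method="hybr")
        if sol.success and np.all(y[idx] + 0 >= 0):
            cand = y.copy()
            cand[idx] = sol.x
            if np.all(cand[idx] >= 0) and np.max(
                np.abs(cm.rhs(cand, 0.0, glc)[mask])
            ) <= np.max(np.abs(dy[mask])):
                y = cand
    return y


def dose_response_scan(
    model: ModelDefinition,
    doses=None,
    *,
    pre_dose: float = 3.0,
    pre_duration: float = 60.0,
    tol: float = 1e-8,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> pd.DataFrame:
    """Steady-state glucose scan (default 11 doses, 1 to 35 mM).

    Each dose is solved after a basal pre-simulation (3 mM for 60 min);
    derived columns report the energy-state readouts and the insulin
    secretion flux.
    """
    if doses is None:
        doses = np.linspace(1.0, 35.0, 11)
    cm = compile_model(model)
    from ._kernel import SPECIES_ORDER

    t_pre = np.array([0.0, pre_duration])
    y_basal = _integrate(cm, cm.y0(), t_pre, pre_dose, rtol, atol)[-1]

    rows = []
    for d in np.asarray(doses, dtype=float):
        y = steady_state(model, d, y0=y_basal, tol=tol, rtol=rtol, atol=atol)
        c = cm.concentrations(y, d)
        f = cm.fluxes(y, d)
        row = dict(zip(SPECIES_ORDER, c))
        row["dose"] = d
        row["atp_adp_ratio"] = c[SPECIES_ORDER.index("atp")] / c[SPECIES_ORDER.index("adp")]
        row["atp_adp_total"] = c[SPECIES_ORDER.index("atp")] + c[SPECIES_ORDER.index("adp")]
        row["nadh_nad_ratio"] = c[SPECIES_ORDER.index("nadh")] / c[SPECIES_ORDER.index("nad")]
        row["nadh_nad_total"] = c[SPECIES_ORDER.index("nadh")] + c[SPECIES_ORDER.index("nad")]
        row["irs"] = f[REACTION_ORDER.index("IRS_FP")] + f[REACTION_ORDER.index("IRS_SP")]
        row["irs_fp"] = f[REACTION_ORDER.index("IRS_FP")]
        row["irs_sp"] = f[REACTION_ORDER.index("IRS_SP")]
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.set_index("dose", drop=False)


def time_to_steady_state(
    trajectory: Trajectory,
    rel_tol: float = 0.05,
    species: tuple[str, ...] = GLYCOLYTIC_INTERMEDIATES,
) -> float:
    """Earliest incubation time after which every tracked metabolite stays
    within ``rel_tol`` of its final value.

    Only species present in the trajectory are considered.  If some species
    never settles, the trajectory horizon is returned with a warning.
    """
    inc = trajectory.incubation() if trajectory.phase is not None else trajectory
    t = inc.time
    if len(t) < 2:
        return 0.0
    t_settle = 0.0
    settled = True
    for sid in species:
        if sid not in inc.concentrations.columns:
            continue
        x = inc.species(sid)
        xf = x[-1]
        scale = max(abs(xf), 1e-12)
        dev = np.abs(x - xf) / scale
        bad = np.nonzero(dev > rel_tol)[0]
        if len(bad) == 0:
            continue
        if bad[-1] >= len(t) - 2:  # still moving in the final grid step
            settled = False
            t_settle = t[-1]
            continue
        t_settle = max(t_settle, t[bad[-1] + 1])
    if not settled:
        warnings.warn("trajectory did not settle within its horizon", RuntimeWarning)
    return float(t_settle)
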