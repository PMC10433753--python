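"""Hybrid calibration of the 16 glycolytic Vmax parameters.

The objective is the unweighted sum of squared residuals between normalized
time-course observations and condition-specific model predictions: each
experiment is simulated with its own protocol (60-min pre-simulation at the
pre-incubation dose, then incubation), predictions are sampled at the
observed times, and residuals accumulate over experiments and metabolites.
Steady-state observations are treated as late-time observations of a
constant-dose protocol.

Optimization is hybrid: an evolution strategy ((μ,λ) scheme with
self-adaptive per-coordinate step sizes, intermediate recombination and one
elite survivor) restarted from random initial guesses inside the box bounds,
followed by a Hooke–Jeeves pattern search.  The local stage cascades over
the best global candidates, ranking them by how far short probes descend
before refining the most promising to convergence — the objective has
compensatory local basins whose bottoms the global stage cannot
distinguish.  Both stages operate in log10 parameter space since the Vmax
bounds [1e-2, 5000] span almost six decades.  Insulin-release parameters
are fitted in a separate decoupled stage against normalized
insulin-secretion data with the glycolytic parameters frozen.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import odeint
from scipy.optimize import least_squares

from ._kernel import REACTION_ORDER, _jac_odeint, _rhs_odeint, compile_model
from .model import DOSE_DOMAIN, FITTED_VMAX_IDS, ModelDefinition
from .simulate import SimulationError, steady_state

__all__ = [
    "CalibrationProblem",
    "FitResult",
    "residual_cost",
    "fit_global",
    "fit_local",
    "fit",
    "fit_irs",
    "DEFAULT_BOUNDS",
]

logger = logging.getLogger(__name__)

DEFAULT_BOUNDS = (1e-2, 5000.0)
FIT_RTOL = 1e-5
FIT_ATOL = 1e-8


@dataclass
class FitResult:
    parameters: dict
    cost: float
    per_restart_costs: list = field(default_factory=list)
    steady_state_reachable: bool = True
    n_evaluations: int = 0
    seed: int | None = None
    stage: str = "hybrid"
    candidates: list = field(default_factory=list)  # (cost, parameter dict), sorted

    def vector(self, ids) -> np.ndarray:
        return np.array([self.parameters[i] for i in ids])


@dataclass
class CalibrationProblem:
    """Dataset + fitted-parameter set + bounds + protocol mapping."""

    model: ModelDefinition
    curves: list
    fitted_ids: tuple = tuple(f"{r}_Vmax" for r in FITTED_VMAX_IDS)
    bounds: tuple = DEFAULT_BOUNDS
    restarts: int = 10
    evals_per_restart: int = 2000
    seed: int = 42
    pre_duration: float = 60.0
    ss_obs_time: float = 120.0  # late-time stand-in for steady-state points

    def __post_init__(self):
        cm = compile_model(self.model)
        self._cm = cm
        params = self.model.parameters()
        for pid in self.fitted_ids:
            if pid not in params:
                raise ValueError(f"fitted parameter {pid} not in the model")
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError("lower bound must be below upper bound")
        # vmax slot index per fitted id (position in the kernel vmax array)
        self._vmax_slots = np.array(
            [REACTION_ORDER.index(pid[: -len("_Vmax")]) for pid in self.fitted_ids]
        )
        self._start = np.array([params[pid] for pid in self.fitted_ids])

        # group observations by protocol (pre, inc)
        dyn_index = {s: i for i, s in enumerate(cm.dyn_species)}
        groups: dict[tuple[float, float], dict] = {}
        for c in self.curves:
            if c.metabolite not in dyn_index:
                continue  # rule-governed / derived observables are excluded
            if c.x_type == "time":
                key = (float(c.pre_dose), float(c.inc_dose))
                times = c.x
                values = c.y
            else:  # steady-state dose response -> late-time obs per dose
                for d, v in zip(c.x, c.y):
                    key = (float(c.pre_dose), float(d))
                    g = groups.setdefault(key, {"times": set(), "obs": []})
                    g["times"].add(self.ss_obs_time)
                    g["obs"].append((c.metabolite, self.ss_obs_time, float(v)))
                continue
            g = groups.setdefault(key, {"times": set(), "obs": []})
            g["times"].update(times.tolist())
            for t, v in zip(times, values):
                g["obs"].append((c.metabolite, float(t), float(v)))

        self._protocols = []
        for (pre, inc), g in groups.items():
            tgrid = np.array(sorted(g["times"]))
            if tgrid[0] > 0.0:
                tfull = np.concatenate([[0.0], tgrid])
            else:
                tfull = tgrid
            rows = []
            for met, t, v in g["obs"]:
                rows.append(
                    (dyn_index[met], int(np.searchsorted(tfull, t)), v)
                )
            met_idx = np.array([r[0] for r in rows], dtype=np.int64)
            t_idx = np.array([r[1] for r in rows], dtype=np.int64)
            vals = np.array([r[2] for r in rows])
            self._protocols.append((pre, inc, tfull, met_idx, t_idx, vals))
        if not self._protocols:
            raise ValueError("no usable observations in the dataset")

    # -- fast objective ----------------------------------------------------

    def _args(self, glc: float, vmax: np.ndarray) -> tuple:
        cm = self._cm
        return (
            glc,
            cm.c_template,
            cm.dyn_idx,
            cm.sub_ptr,
            cm.sub_idx,
            cm.sub_km,
            cm.prod_ptr,
            cm.prod_idx,
            cm.prod_km,
            vmax,
            cm.keq,
            cm.irrev,
            cm.srow,
            cm.scol,
            cm.sval,
            cm.atp_row,
            cm.rule_coeffs,
            cm.atptot_coeffs,
            DOSE_DOMAIN[0],
            DOSE_DOMAIN[1],
            cm.datp_f,
            cm.irs_p,
            cm.rules_on,
            cm.datp_on,
            cm.scratch,
        )

    def cost(self, theta: np.ndarray) -> float:
        """Sum-of-squares objective at a candidate Vmax vector."""
        vmax = self._cm.vmax.copy()
        vmax[self._vmax_slots] = theta
        total = 0.0
        y_start = self._cm.y0()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for pre, inc, tfull, met_idx, t_idx, vals in self._protocols:
                    ys, info = odeint(
                        _rhs_odeint,
                        y_start,
                        np.array([0.0, self.pre_duration]),
                        args=self._args(pre, vmax),
                        Dfun=_jac_odeint,
                        rtol=FIT_RTOL,
                        atol=FIT_ATOL,
                        mxstep=20000,
                        full_output=True,
                    )
                    if info["message"] != "Integration successful.":
                        return np.inf
                    ys2, info = odeint(
                        _rhs_odeint,
                        ys[-1],
                        tfull,
                        args=self._args(inc, vmax),
                        Dfun=_jac_odeint,
                        rtol=FIT_RTOL,
                        atol=FIT_ATOL,
                        mxstep=20000,
                        full_output=True,
                    )
                    if info["message"] != "Integration successful.":
                        return np.inf
                    pred = ys2[t_idx, met_idx]
                    if not np.all(np.isfinite(pred)):
                        return np.inf
                    total += float(np.sum((vals - pred) ** 2))
        except Exception as exc:  # integrator failure -> penalty
            logger.debug("integration failed at candidate: %s", exc)
            return np.inf
        return total

    def result_model(self, theta: np.ndarray) -> ModelDefinition:
        """Copy of the model with the candidate Vmax values applied."""
        import copy

        m = copy.deepcopy(self.model)
        m._cache = None
        for pid, v in zip(self.fitted_ids, theta):
            m.set_parameter(pid, float(v))
        return m


def residual_cost(params, problem: CalibrationProblem) -> float:
    """Public objective: params as vector (fitted order) or {id: value}."""
    if isinstance(params, dict):
        theta = np.array([params[pid] for pid in problem.fitted_ids])
    else:
        theta = np.asarray(params, dtype=float)
    lo, hi = problem.bounds
    if np.any(theta < lo) or np.any(theta > hi):
        raise ValueError("candidate parameters outside bounds")
    return problem.cost(theta)


# ---------------------------------------------------------------------------
# SRES-style evolution strategy
# ---------------------------------------------------------------------------


def _sres_run(
    cost_fn,
    n: int,
    lo_log: float,
    hi_log: float,
    max_evals: int,
    rng: np.random.Generator,
    pop: int = 20,
    cost_tol: float = 0.0,
):
    """One (mu,lambda) evolution-strategy run in log10 space.

    Self-adaptive per-coordinate step sizes with intermediate recombination
    of two parents and one elite survivor.  The initial population samples
    half the members uniformly on the natural parameter scale and half
    uniformly on the log scale, covering both the fast-kinetics and
    slow-kinetics corners of the box.  Returns (x_log, cost, evals).
    """
    lam = pop
    mu = max(2, lam // 4)
    tau_p = 1.0 / np.sqrt(2.0 * n)
    tau = 1.0 / np.sqrt(2.0 * np.sqrt(n))
    span = hi_log - lo_log

    X = np.empty((lam, n))
    half = lam // 2
    X[:half] = np.log10(rng.uniform(10.0**lo_log, 10.0**hi_log, size=(half, n)))
    X[half:] = rng.uniform(lo_log, hi_log, size=(lam - half, n))
    S = np.full((lam, n), 0.5)
    costs = np.array([cost_fn(x) for x in X])
    evals = lam
    bi = int(np.argmin(costs))
    best_x = X[bi].copy()
    best_c = float(costs[bi])

    while evals + lam <= max_evals and best_c > cost_tol:
        order = np.argsort(costs)
        parents = X[order[:mu]]
        psig = S[order[:mu]]
        Xn = np.empty_like(X)
        Sn = np.empty_like(S)
        Xn[0], Sn[0] = best_x, psig[0]  # elite survivor
        for k in range(1, lam):
            a, b = rng.integers(0, mu, size=2)
            xp = 0.5 * (parents[a] + parents[b])
            sp = np.sqrt(psig[a] * psig[b])
            s = sp * np.exp(tau_p * rng.normal() + tau * rng.normal(size=n))
            np.clip(s, 1e-8, span, out=s)
            Xn[k] = np.clip(xp + s * rng.normal(size=n), lo_log, hi_log)
            Sn[k] = s
        X, S = Xn, Sn
        costs = np.empty(lam)
        costs[0] = best_c  # elite carries its known cost
        for k in range(1, lam):
            costs[k] = cost_fn(X[k])
        evals += lam - 1
        i = int(np.argmin(costs))
        if costs[i] < best_c:
            best_c = float(costs[i])
            best_x = X[i].copy()
    return best_x, best_c, evals


def fit_global(problem: CalibrationProblem, seed: int | None = None) -> FitResult:
    """Restarted evolution-strategy search; keeps the best restart whose
    solution reaches a steady state at basal glucose."""
    seed = problem.seed if seed is None else seed
    n = len(problem.fitted_ids)
    lo, hi = problem.bounds
    lo_log, hi_log = np.log10(lo), np.log10(hi)

    def cost_log(x_log):
        return problem.cost(10.0**x_log)

    candidates = []
    total_evals = 0
    for r in range(problem.restarts):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), r]))
        x_log, c, ev = _sres_run(
            cost_log, n, lo_log, hi_log, problem.evals_per_restart, rng
        )
        total_evals += ev
        candidates.append((c, x_log))
        logger.info("restart %d/%d: cost %.6g", r + 1, problem.restarts, c)

    if all(not np.isfinite(c) for c, _ in candidates):
        raise SimulationError("all restarts failed to integrate")

    per_restart = [float(c) for c, _ in candidates]
    best = None
    ss_ok = False
    for c, x_log in sorted(candidates, key=lambda t: t[0]):
        if not np.isfinite(c):
            continue
        theta = 10.0**x_log
        try:
            steady_state(problem.result_model(theta), 3.0, max_horizon=4000.0, tol=1e-6)
            best, ss_ok = (c, x_log), True
            break
        except SimulationError:
            continue
    if best is None:  # no restart reached steady state; fall back to min cost
        best = min(((c, x) for c, x in candidates if np.isfinite(c)), key=lambda t: t[0])
    theta = 10.0 ** best[1]
    ranked = sorted(
        ((float(c), dict(zip(problem.fitted_ids, 10.0**x)))
         for c, x in candidates if np.isfinite(c)),
        key=lambda t: t[0],
    )
    return FitResult(
        parameters=dict(zip(problem.fitted_ids, theta)),
        cost=float(best[0]),
        per_restart_costs=per_restart,
        steady_state_reachable=ss_ok,
        n_evaluations=total_evals,
        seed=seed,
        stage="global",
        candidates=ranked,
    )


# ---------------------------------------------------------------------------
# Hooke–Jeeves pattern search
# ---------------------------------------------------------------------------


def _hooke_jeeves(cost_fn, x0, lo, hi, step0, step_tol, max_evals, cost_tol=0.0):
    """Derivative-free pattern search with exploratory + pattern moves and
    step halving; the cost sequence of accepted points is non-increasing.

    The objective is strongly anisotropic across parameters (flux-controlling
    steps versus near-equilibrium ones), so per-coordinate step sizes are
    seeded from a one-pass sensitivity probe and then halved jointly.
    """
    n = len(x0)
    x = np.clip(np.asarray(x0, dtype=float), lo, hi)
    fx = cost_fn(x)
    evals = 1

    # probe local sensitivity to precondition the poll steps
    probe = np.empty(n)
    d0 = 0.05
    for i in range(n):
        cand = x.copy()
        cand[i] = np.clip(cand[i] + d0, lo, hi)
        fc = cost_fn(cand)
        evals += 1
        probe[i] = max(abs(fc - fx), 1e-12)
    ref = np.median(probe)
    steps = float(step0) * np.clip(np.sqrt(ref / probe), 0.25, 8.0)
    scale = 1.0

    def explore(base, fbase):
        nonlocal evals
        xb = base.copy()
        fb = fbase
        for i in range(n):
            for s in (+steps[i] * scale, -steps[i] * scale):
                if evals >= max_evals:
                    return xb, fb
                cand = xb.copy()
                cand[i] = np.clip(cand[i] + s, lo, hi)
                if cand[i] == xb[i]:
                    continue
                fc = cost_fn(cand)
                evals += 1
                if fc < fb:
                    xb, fb = cand, fc
                    break
        return xb, fb

    while scale * np.max(steps) > step_tol and evals < max_evals and fx > cost_tol:
        xn, fn = explore(x, fx)
        if fn < fx:
            # pattern move: extrapolate along the improving direction
            while evals < max_evals and fn > cost_tol:
                xp = np.clip(xn + (xn - x), lo, hi)
                x, fx = xn, fn
                xe, fe = explore(xp, cost_fn(xp))
                evals += 1
                if fe < fx:
                    xn, fn = xe, fe
                else:
                    break
            x, fx = xn, fn
        else:
            scale *= 0.5
    return x, fx, evals


def fit_local(
    problem: CalibrationProblem,
    start,
    *,
    step0: float = 0.2,
    step_tol: float = 1e-6,
    max_evals: int = 20000,
    cost_tol: float = 0.0,
) -> FitResult:
    """Hooke–Jeeves refinement from a start vector (natural scale)."""
    if isinstance(start, dict):
        start = np.array([start[pid] for pid in problem.fitted_ids])
    start = np.asarray(start, dtype=float)
    lo, hi = problem.bounds
    if np.any(start < lo) or np.any(start > hi):
        raise ValueError("start point outside bounds")

    def cost_log(x_log):
        return problem.cost(10.0**x_log)

    x_log, c, evals = _hooke_jeeves(
        cost_log,
        np.log10(start),
        np.log10(lo),
        np.log10(hi),
        step0,
        step_tol,
        max_evals,
        cost_tol,
    )
    theta = 10.0**x_log
    return FitResult(
        parameters=dict(zip(problem.fitted_ids, theta)),
        cost=float(c),
        n_evaluations=evals,
        stage="local",
    )


def fit(
    problem: CalibrationProblem,
    seed: int | None = None,
    *,
    probe_evals: int = 3000,
    probe_candidates: int = 3,
    continue_candidates: int = 2,
    continue_evals: int = 9000,
    local_cost_tol: float = 1e-4,
) -> FitResult:
    """Hybrid calibration: restarted evolution strategy, then pattern search.

    The local stage cascades: short pattern-search probes rank the best
    global candidates by how far they descend, and the most promising are
    refined to convergence (with classic step-reset restarts).  Ranking by
    descent rather than by raw global cost matters because the objective has
    compensatory local basins whose bottoms the global stage cannot
    distinguish.  The local stage stops early once the objective falls below
    ``local_cost_tol`` (far inside the recovery tolerance on noise-free
    data).
    """
    g = fit_global(problem, seed=seed)
    lo, hi = problem.bounds
    lo_log, hi_log = np.log10(lo), np.log10(hi)

    def cost_log(x_log):
        return problem.cost(10.0**x_log)

    evals = g.n_evaluations
    probes: list[tuple[float, np.ndarray]] = []
    for c, params in g.candidates[:probe_candidates]:
        x0 = np.log10(np.array([params[pid] for pid in problem.fitted_ids]))
        xh, ch, ev = _hooke_jeeves(
            cost_log, x0, lo_log, hi_log, 0.2, 1e-6, probe_evals,
            cost_tol=local_cost_tol,
        )
        evals += ev
        probes.append((float(ch), xh))
        logger.info("local probe: %.6g -> %.6g", c, ch)
    probes.sort(key=lambda t: t[0])

    finals: list[tuple[float, np.ndarray]] = []
    for ch, xh in probes[:continue_candidates]:
        x, fx = xh.copy(), ch
        used = 0
        while used < continue_evals and fx > local_cost_tol:
            xn, fn, ev = _hooke_jeeves(
                cost_log, x, lo_log, hi_log, 0.2, 1e-6, continue_evals - used,
                cost_tol=local_cost_tol,
            )
            used += ev
            if fn < fx * (1.0 - 1e-6):
                x, fx = xn, fn
            else:
                break
        evals += used
        finals.append((float(fx), x))
        logger.info("local continuation: %.6g -> %.6g", ch, fx)
    finals.sort(key=lambda t: t[0])

    best_c, best_x = min(finals + probes, key=lambda t: t[0])
    if best_c > g.cost:
        best_c = g.cost
        best_x = np.log10(g.vector(problem.fitted_ids))
    theta = 10.0**best_x

    ss_ok = True
    try:
        steady_state(problem.result_model(theta), 3.0, max_horizon=4000.0, tol=1e-6)
    except SimulationError:
        ss_ok = False

    result = FitResult(
        parameters=dict(zip(problem.fitted_ids, theta)),
        cost=float(best_c),
        per_restart_costs=g.per_restart_costs,
        steady_state_reachable=ss_ok,
        n_evaluations=evals,
        seed=g.seed,
        stage="hybrid",
        candidates=g.candidates,
    )
    # update the problem's model in place with the best parameters
    for pid, v in result.parameters.items():
        problem.model.set_parameter(pid, float(v))
    return result


# ---------------------------------------------------------------------------
# Decoupled insulin-release parameter fit
# ---------------------------------------------------------------------------


def fit_irs(
    model: ModelDefinition,
    irs_dose_curve,
    *,
    doses=None,
) -> dict:
    """Fit the second-phase Hill parameters (Vmax_sp, Km_sp, n_sp) to a
    normalized insulin-secretion dose response, with glycolysis frozen.

    The model's steady-state ATP/ADP ratio at each dose provides the Hill
    input; the first-phase constants are untouched (they act only on
    transients, which steady-state dose responses do not constrain).
    Returns the fitted parameter dictionary and updates the model.
    """
    from ._kernel import SPECIES_ORDER

    cm = compile_model(model)
    x = np.asarray(irs_dose_curve.x, dtype=float)
    y = np.asarray(irs_dose_curve.y, dtype=float)
    i_atp = SPECIES_ORDER.index("atp")
    i_adp = SPECIES_ORDER.index("adp")
    ratios = []
    for d in x:
        yss = steady_state(model, float(d))
        c = cm.concentrations(yss, float(d))
        ratios.append(c[i_atp] / c[i_adp])
    r = np.asarray(ratios)

    def resid(p_log):
        vmax, km, n = 10.0**p_log
        rn = r**n
        return vmax * rn / (rn + km**n) - y

    p0 = np.log10([max(y.max(), 1e-6), np.median(r), 3.0])
    sol = least_squares(resid, p0, bounds=([-6, -3, 0], [3, 3, np.log10(8)]))
    vmax, km, n = 10.0**sol.x
    model.set_parameter("IRS_Vmax_sp", float(vmax))
    model.set_parameter("IRS_Km_sp", float(km))
    model.set_parameter("IRS_n_sp", float(max(n, 1.0)))
    return {"IRS_Vmax_sp": float(vmax), "IRS_Km_sp": float(km), "IRS_n_sp": float(max(n, 1.0))}
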