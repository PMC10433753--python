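"""Synthetic multi-study GSIS datasets with hidden ground truth.

The generator emulates the statistical structure of the curated islet
literature that the normalization and calibration stages assume: several
studies measuring overlapping metabolites at common glucose doses, each with
its own multiplicative reporting bias (log-normal, median 1), multiplicative
log-normal measurement noise, a choice between absolute and fold reporting,
and pre-incubation/incubation protocol metadata.  Ground truth (noise-free
reference curves, per-study bias factors, true Vmax values) is retained for
recovery tests.

Defaults mirror the common conditions of the curated studies: doses
{1, 2.8, 5, 10, 16.7, 20, 30} mM and 0-60 min time grids at 5-min steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernel import SPECIES_ORDER, compile_model
from .model import GLYCOLYTIC_INTERMEDIATES, ModelDefinition
from .normalize import ExperimentalCurve
from .simulate import Protocol, run_protocol, steady_state

__all__ = [
    "StudySpec",
    "SyntheticStudySet",
    "GroundTruth",
    "DEFAULT_DOSES",
    "DEFAULT_TIME_GRID",
    "generate_ground_truth",
    "generate_study_set",
    "default_study_specs",
    "make_calibration_dataset",
    "recovery_report",
]

DEFAULT_DOSES = (1.0, 2.8, 5.0, 10.0, 16.7, 20.0, 30.0)
DEFAULT_TIME_GRID = tuple(np.arange(0.0, 61.0, 5.0))
# the measured panel: cytosolic glucose, the glycolytic intermediates, and
# the adenine nucleotides
OBSERVABLE_METABOLITES = ("glc",) + GLYCOLYTIC_INTERMEDIATES + ("atp", "adp")


@dataclass
class StudySpec:
    """Reporting conventions of one emulated study."""

    study_id: str
    reporting: str = "absolute"  # absolute | fold
    unit: str = "mM"
    bias_sigma_log: float = 0.5  # log-normal bias, median 1
    noise_cv: float = 0.10  # multiplicative measurement noise
    doses: tuple = DEFAULT_DOSES
    time_grid: tuple = DEFAULT_TIME_GRID
    pre_dose: float = 3.0
    inc_dose: float = 16.7
    metabolites: tuple = OBSERVABLE_METABOLITES
    include_time_course: bool = False

    def validate(self) -> None:
        if self.reporting not in ("absolute", "fold"):
            raise ValueError(f"unknown reporting {self.reporting!r}")
        if self.noise_cv < 0 or self.bias_sigma_log < 0:
            raise ValueError("noise and bias dispersion must be >= 0")


@dataclass
class GroundTruth:
    """Noise-free reference curves and true parameter values."""

    doses: np.ndarray
    dose_response: pd.DataFrame  # dose x metabolite (steady state, mM)
    time_courses: dict  # (pre, inc) -> DataFrame time x metabolite
    vmax_true: dict
    seed: int | None = None


@dataclass
class SyntheticStudySet:
    curves: list
    truth: GroundTruth
    bias_factors: dict
    specs: list
    seed: int


def generate_ground_truth(
    model: ModelDefinition,
    doses=DEFAULT_DOSES,
    protocols: list[Protocol] | None = None,
    time_grid=DEFAULT_TIME_GRID,
) -> GroundTruth:
    """Simulate the reference model: steady-state dose response per observable
    metabolite plus protocol time courses, noise-free."""
    cm = compile_model(model)
    doses = np.asarray(doses, dtype=float)
    rows = []
    t_pre = np.array([0.0, 60.0])
    from .simulate import _integrate

    y_basal = _integrate(cm, cm.y0(), t_pre, 3.0, 1e-8, 1e-10)[-1]
    for d in doses:
        y = steady_state(model, d, y0=y_basal)
        c = cm.concentrations(y, d)
        rows.append({m: c[SPECIES_ORDER.index(m)] for m in OBSERVABLE_METABOLITES})
    dr = pd.DataFrame(rows, index=pd.Index(doses, name="dose"))

    tcs = {}
    for proto in protocols or []:
        traj = run_protocol(model, proto)
        inc = traj.incubation()
        grid = np.asarray(time_grid, dtype=float)
        data = {}
        for m in OBSERVABLE_METABOLITES:
            data[m] = np.interp(grid, inc.time, inc.species(m))
        tcs[(proto.pre_dose, proto.inc_dose)] = pd.DataFrame(
            data, index=pd.Index(grid, name="time")
        )

    vmax_true = {
        f"{r.id}_Vmax": r.kinetics.Vmax
        for r in model.reactions
        if r.kind == "modular"
    }
    return GroundTruth(doses, dr, tcs, vmax_true)


def default_study_specs(n_studies: int = 5, **overrides) -> list[StudySpec]:
    """A mixed panel: mostly absolute-reporting studies, some fold-reporting."""
    specs = []
    for i in range(n_studies):
        reporting = "fold" if i % 3 == 2 else "absolute"
        specs.append(
            StudySpec(
                study_id=f"study_{i+1:02d}",
                reporting=reporting,
                unit="fold" if reporting == "fold" else "mM",
                **overrides,
            )
        )
    return specs


def generate_study_set(
    truth: GroundTruth,
    specs: list[StudySpec],
    seed: int,
) -> SyntheticStudySet:
    """Sample per-study curves from ground truth: bias, noise, reporting."""
    if not specs:
        raise ValueError("no study specs supplied")
    rng = np.random.default_rng(seed)
    curves = []
    biases = {}
    for spec in specs:
        spec.validate()
        bias = float(rng.lognormal(mean=0.0, sigma=spec.bias_sigma_log))
        biases[spec.study_id] = bias
        for met in spec.metabolites:
            base = truth.dose_response[met].to_numpy()
            doses = np.asarray(spec.doses, dtype=float)
            y = np.interp(doses, truth.doses, base) * bias
            if spec.noise_cv > 0:
                sigma = np.sqrt(np.log1p(spec.noise_cv**2))
                y = y * rng.lognormal(0.0, sigma, size=y.shape)
            mtype, unit = "absolute", spec.unit
            if spec.reporting == "fold":
                basal = np.interp(spec.pre_dose, doses, y)
                if basal <= 0:
                    raise ValueError(
                        f"zero basal truth for {met}, cannot report fold"
                    )
                y = y / basal
                mtype, unit = "fold", "fold"
            curves.append(
                ExperimentalCurve(
                    study_id=spec.study_id,
                    metabolite=met,
                    measurement_type=mtype,
                    unit=unit,
                    x=doses,
                    y=y,
                    x_type="dose",
                    pre_dose=spec.pre_dose,
                    organism="synthetic",
                    weight=1.0,
                )
            )
            if spec.include_time_course:
                key = (spec.pre_dose, spec.inc_dose)
                if key in truth.time_courses:
                    tcy = truth.time_courses[key][met].to_numpy() * bias
                    if spec.noise_cv > 0:
                        sigma = np.sqrt(np.log1p(spec.noise_cv**2))
                        tcy = tcy * rng.lognormal(0.0, sigma, size=tcy.shape)
                    curves.append(
                        ExperimentalCurve(
                            study_id=spec.study_id,
                            metabolite=met,
                            measurement_type="absolute",
                            unit=spec.unit if spec.reporting == "absolute" else "mM",
                            x=np.asarray(spec.time_grid, dtype=float),
                            y=tcy,
                            x_type="time",
                            pre_dose=spec.pre_dose,
                            inc_dose=spec.inc_dose,
                            organism="synthetic",
                        )
                    )
    return SyntheticStudySet(curves, truth, biases, specs, seed)


def make_calibration_dataset(
    model: ModelDefinition,
    *,
    protocols: tuple = ((3.0, 16.7), (3.0, 30.0)),
    time_grid=DEFAULT_TIME_GRID,
    noise_cv: float = 0.0,
    seed: int = 0,
    metabolites=OBSERVABLE_METABOLITES,
) -> tuple[list, GroundTruth]:
    """Noise-free (or noisy) time-course dataset for Vmax calibration.

    One experiment per (pre, inc) protocol; observables are the glycolytic
    intermediates plus ATP and ADP, sampled on the incubation time grid.
    """
    protos = [Protocol(p, i) for p, i in protocols]
    truth = generate_ground_truth(model, protocols=protos, time_grid=time_grid)
    rng = np.random.default_rng(seed)
    curves = []
    for (pre, inc), df in truth.time_courses.items():
        for met in metabolites:
            y = df[met].to_numpy().copy()
            if noise_cv > 0:
                sigma = np.sqrt(np.log1p(noise_cv**2))
                y = y * rng.lognormal(0.0, sigma, size=y.shape)
            curves.append(
                ExperimentalCurve(
                    study_id=f"cal_{pre:g}_{inc:g}",
                    metabolite=met,
                    measurement_type="absolute",
                    unit="mM",
                    x=df.index.to_numpy(),
                    y=y,
                    x_type="time",
                    pre_dose=pre,
                    inc_dose=inc,
                    organism="synthetic",
                )
            )
    return curves, truth


def recovery_report(
    normalized_curves: list,
    truth: GroundTruth,
    bias_factors: dict,
    scale_factors=None,
    fit_result=None,
) -> dict:
    """Recovery metrics of the pipeline against hidden ground truth.

    Scale-factor recovery is measured up to a common scale (the product
    f_s * b_s should be constant across studies); curve error is the RMSE of
    each normalized curve against the truth curve after removing the common
    scale; Vmax recovery reports fitted/true ratios.
    """
    report: dict = {}
    if scale_factors is not None:
        prods = []
        for (sid, _), f in scale_factors.factors.items():
            if sid in bias_factors:
                prods.append(f * bias_factors[sid])
        if prods:
            prods = np.asarray(prods)
            report["bias_recovery_spread"] = float(
                (prods.max() - prods.min()) / prods.mean()
            )

    rmses = {}
    by_met: dict[str, list] = {}
    for c in normalized_curves:
        if c.x_type == "dose":
            by_met.setdefault(c.metabolite, []).append(c)
    for met, group in by_met.items():
        if met not in truth.dose_response.columns:
            continue
        t = np.concatenate(
            [np.interp(c.x, truth.doses, truth.dose_response[met].to_numpy()) for c in group]
        )
        v = np.concatenate([c.y for c in group])
        if np.sum(v * v) == 0:
            continue
        scale = float(np.sum(v * t) / np.sum(v * v))
        resid = v * scale - t
        rmses[met] = float(np.sqrt(np.mean(resid**2)) / max(np.mean(np.abs(t)), 1e-12))
    report["curve_rmse_rel"] = rmses

    if fit_result is not None:
        ratios = {}
        for name, true_v in truth.vmax_true.items():
            if name in fit_result.parameters:
                ratios[name] = fit_result.parameters[name] / true_v
        report["vmax_recovery_ratio"] = ratios
    return report
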