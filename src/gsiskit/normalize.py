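"""Cross-study normalization of heterogeneous GSIS measurements.

Metabolite measurements from different studies mix absolute concentrations,
fold changes relative to a basal condition, ratios and rates, reported in
incompatible units and with study-specific systematic biases.  The workflow
merges them into consistent absolute curves in four fixed stages per
metabolite:

1. unit normalization — convert reported units to mM (metabolites) or
   nmol/min/ml (insulin secretion) via registered conversion factors;
2. fold-to-absolute conversion — multiply fold curves by a basal
   concentration (reported basal, else the mean absolute curve at the
   experiment's pre-incubation dose, else the metabolite's Km);
3. steady-state normalization — per-curve multiplicative scale factors
   minimizing the squared distance to the weighted mean curve, iterated to
   convergence (the minimizer has the closed form f = Σ C·C̄ / Σ C²);
4. time-course anchoring — each time course is scaled so its final point
   matches the mean steady-state curve at the incubation dose.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "ExperimentalCurve",
    "MeanCurve",
    "ScaleFactorSet",
    "UNIT_CONVERSIONS",
    "convert_units",
    "fold_to_absolute",
    "compute_mean_curve",
    "ss_scale_factor",
    "normalize_steady_state",
    "tc_scale_factor",
    "normalize_dataset",
    "curves_to_frame",
    "frame_to_curves",
    "read_curves_csv",
    "write_curves_csv",
]

logger = logging.getLogger(__name__)

CSV_COLUMNS = [
    "study_id",
    "organism",
    "metabolite",
    "measurement_type",
    "unit",
    "pre_dose_mM",
    "inc_dose_mM",
    "x_type",
    "x_value",
    "y_value",
    "y_sd",
    "weight",
]


@dataclass
class ExperimentalCurve:
    """One study's dose-response or time course for one metabolite."""

    study_id: str
    metabolite: str
    measurement_type: str  # absolute | fold | ratio | rate
    unit: str
    x: np.ndarray  # mM (dose) or min (time), strictly increasing
    y: np.ndarray
    x_type: str = "dose"  # dose | time
    pre_dose: float = 3.0
    inc_dose: float | None = None
    organism: str = ""
    weight: float = 1.0
    y_sd: np.ndarray | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.size < 2:
            raise ValueError("x and y must have equal length >= 2")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")
        if np.any(self.y < 0):
            raise ValueError(
                f"negative measurement in {self.study_id}/{self.metabolite}"
            )
        if not self.weight > 0:
            raise ValueError("curve weight must be positive")

    def scaled(self, factor: float, note: str | None = None) -> "ExperimentalCurve":
        c = replace(self, y=self.y * factor)
        c.provenance = self.provenance + ([note] if note else [])
        return c


@dataclass
class MeanCurve:
    """Weighted-average reference curve on the union dose grid."""

    metabolite: str
    dose: np.ndarray
    value: np.ndarray
    kind: str = "spline"  # spline (shape-preserving pchip) | linear

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if len(self.dose) >= 3 and self.kind == "spline":
            self._interp = PchipInterpolator(self.dose, self.value, extrapolate=False)
        else:
            self.kind = "linear"
            self._interp = None

    def __call__(self, dose) -> np.ndarray:
        d = np.clip(np.asarray(dose, dtype=float), self.dose[0], self.dose[-1])
        if self._interp is not None:
            return np.asarray(self._interp(d))
        return np.interp(d, self.dose, self.value)


@dataclass
class ScaleFactorSet:
    factors: dict[tuple[str, int], float]
    iterations: int
    converged: bool

    def for_study(self, study_id: str) -> float:
        vals = [f for (sid, _), f in self.factors.items() if sid == study_id]
        return float(np.mean(vals)) if vals else 1.0


# ---------------------------------------------------------------------------
# Unit normalization
# ---------------------------------------------------------------------------

#: conversion factors to model units; islet measurements use the distribution
#: volume of water in the islet, 2 nl per islet.
ISLET_WATER_VOLUME_NL = 2.0
UNIT_CONVERSIONS: dict[str, tuple[float, str]] = {
    "mM": (1.0, "mM"),
    "mmol/l": (1.0, "mM"),
    "umol/ml": (1.0, "mM"),
    # 1 pmol/islet over 2 nl islet water = 0.5 mmol/l
    "pmol/islet": (1.0 / ISLET_WATER_VOLUME_NL, "mM"),
    "nmol/islet": (1e3 / ISLET_WATER_VOLUME_NL, "mM"),
    "nmol/min/ml": (1.0, "nmol/min/ml"),
    "fold": (1.0, "fold"),
}


def convert_units(
    curve: ExperimentalCurve,
    conversions: dict[str, tuple[float, str]] | None = None,
) -> ExperimentalCurve:
    """Convert a curve's values to model units via registered factors."""
    table = UNIT_CONVERSIONS if conversions is None else conversions
    if curve.unit not in table:
        raise ValueError(f"no unit conversion registered for unit {curve.unit!r}")
    factor, target = table[curve.unit]
    out = curve.scaled(factor, note=f"unit {curve.unit} -> {target} (x{factor:g})")
    out.unit = target
    return out


def fold_to_absolute(curve: ExperimentalCurve, basal: float) -> ExperimentalCurve:
    """Convert a fold curve to absolute concentrations via a basal value (mM)."""
    if curve.measurement_type != "fold":
        raise ValueError("curve is not a fold measurement")
    if not basal > 0:
        raise ValueError("basal concentration must be > 0")
    out = curve.scaled(basal, note=f"fold -> absolute (basal {basal:g} mM)")
    out.measurement_type = "absolute"
    out.unit = "mM"
    return out


def resolve_basal(
    curve: ExperimentalCurve,
    mean_absolute: MeanCurve | None,
    km_lookup: dict[str, float] | None = None,
) -> float:
    """Basal concentration for fold conversion: mean curve at the pre-dose,
    falling back to the metabolite's Km."""
    if mean_absolute is not None:
        return float(mean_absolute(curve.pre_dose))
    if km_lookup and curve.metabolite in km_lookup:
        return km_lookup[curve.metabolite]
    raise ValueError(
        f"no basal concentration obtainable for {curve.metabolite} "
        f"({curve.study_id})"
    )


# ---------------------------------------------------------------------------
# Steady-state normalization
# ---------------------------------------------------------------------------


def compute_mean_curve(curves: list[ExperimentalCurve]) -> MeanCurve:
    """Weighted average of absolute curves on the union of observed doses.

    At each grid dose the average runs over curves whose observed dose range
    covers it.  Interpolation is a shape-preserving piecewise cubic for >= 3
    grid points, linear for exactly 2.
    """
    if not curves:
        raise ValueError("no curves supplied")
    grid = np.unique(np.concatenate([c.x for c in curves]))
    vals = np.zeros_like(grid)
    wsum = np.zeros_like(grid)
    for c in curves:
        covered = (grid >= c.x[0]) & (grid <= c.x[-1])
        interp = np.interp(grid[covered], c.x, c.y)
        vals[covered] += c.weight * interp
        wsum[covered] += c.weight
    if np.any(wsum == 0):  # cannot happen with union grid, defensive
        raise ValueError("mean curve grid has uncovered doses")
    return MeanCurve(curves[0].metabolite, grid, vals / wsum)


def ss_scale_factor(curve: ExperimentalCurve, mean: MeanCurve) -> float:
    """Least-squares scale factor f = Σ C(d)·C̄(d) / Σ C(d)² over the curve's
    doses (the closed-form minimizer of the offset to the mean curve)."""
    c = curve.y
    m = mean(curve.x)
    denom = float(np.sum(c * c))
    if denom == 0:
        raise ValueError(f"all-zero curve {curve.study_id}/{curve.metabolite}")
    return float(np.sum(c * m) / denom)


def normalize_steady_state(
    curves: list[ExperimentalCurve],
    *,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[list[ExperimentalCurve], ScaleFactorSet, MeanCurve]:
    """Iteratively scale steady-state curves toward their common mean.

    Each pass recomputes the weighted mean curve and rescales every curve by
    its closed-form factor; passes repeat until every factor is within
    ``tol`` of 1 (or the iteration cap is reached, flagged non-converged).
    """
    if not curves:
        raise ValueError("no curves supplied")
    scaled = list(curves)
    total = {i: 1.0 for i in range(len(curves))}
    converged = False
    iterations = 0
    if len(curves) == 1:
        mean = compute_mean_curve(scaled)
        fs = ScaleFactorSet({(curves[0].study_id, 0): 1.0}, 0, True)
        return scaled, fs, mean
    for iterations in range(1, max_iter + 1):
        mean = compute_mean_curve(scaled)
        fs = np.array([ss_scale_factor(c, mean) for c in scaled])
        scaled = [c.scaled(f) for c, f in zip(scaled, fs)]
        for i, f in enumerate(fs):
            total[i] *= f
        # the overall scale is a gauge freedom of the objective; under noise
        # the raw factors retain a tiny common multiplicative component that
        # never vanishes, so convergence is judged on the factors' dispersion
        # around their common (geometric-mean) scale
        gauge = np.exp(np.mean(np.log(fs)))
        if max(abs(f / gauge - 1.0) for f in fs) < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "steady-state normalization did not converge in %d iterations", max_iter
        )
    mean = compute_mean_curve(scaled)
    factors = {
        (curves[i].study_id, i): total[i] for i in range(len(curves))
    }
    return scaled, ScaleFactorSet(factors, iterations, converged), mean


def tc_scale_factor(tc_curve: ExperimentalCurve, mean_ss: MeanCurve) -> float:
    """Time-course anchor factor f = C̄_ss(d_inc) / C_tc(t_last)."""
    if tc_curve.x_type != "time":
        raise ValueError("curve is not a time course")
    if tc_curve.inc_dose is None:
        raise ValueError("time course lacks an incubation dose")
    last = tc_curve.y[-1]
    if last <= 0:
        raise ValueError("zero final time-course value, cannot anchor")
    return float(mean_ss(tc_curve.inc_dose) / last)


# ---------------------------------------------------------------------------
# Whole-dataset driver + CSV schema
# ---------------------------------------------------------------------------


def normalize_dataset(
    curves: list[ExperimentalCurve],
    *,
    km_lookup: dict[str, float] | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[list[ExperimentalCurve], dict]:
    """Run the full per-metabolite pipeline; returns scaled curves + report."""
    out: list[ExperimentalCurve] = []
    report: dict = {"metabolites": {}}
    metabolites = sorted({c.metabolite for c in curves})
    for met in metabolites:
        group = [c for c in curves if c.metabolite == met]
        group = [
            convert_units(c) if c.unit not in ("mM", "nmol/min/ml", "fold") else c
            for c in group
        ]
        absolute_ss = [
            c for c in group if c.x_type == "dose" and c.measurement_type == "absolute"
        ]
        mean_abs = compute_mean_curve(absolute_ss) if absolute_ss else None
        resolved = []
        for c in group:
            if c.measurement_type == "fold":
                basal = resolve_basal(c, mean_abs, km_lookup)
                c = fold_to_absolute(c, basal)
            resolved.append(c)

        ss = [c for c in resolved if c.x_type == "dose"]
        tc = [c for c in resolved if c.x_type == "time"]
        cv_before = _dispersion(ss)
        if ss:
            ss_scaled, factors, mean = normalize_steady_state(
                ss, tol=tol, max_iter=max_iter
            )
        else:
            ss_scaled, factors, mean = [], ScaleFactorSet({}, 0, True), None
        tc_scaled = []
        for c in tc:
            if mean is not None:
                f = tc_scale_factor(c, mean)
                c = c.scaled(f, note=f"tc anchor (f={f:g})")
            tc_scaled.append(c)
        out.extend(ss_scaled + tc_scaled)
        report["metabolites"][met] = {
            "n_curves": len(group),
            "factors": {f"{k[0]}#{k[1]}": v for k, v in factors.factors.items()},
            "iterations": factors.iterations,
            "converged": factors.converged,
            "cv_before": cv_before,
            "cv_after": _dispersion(ss_scaled),
        }
    return out, report


def _dispersion(curves: list[ExperimentalCurve]) -> float | None:
    """Mean per-dose coefficient of variation across curves."""
    if len(curves) < 2:
        return None
    grid = np.unique(np.concatenate([c.x for c in curves]))
    cvs = []
    for d in grid:
        vals = [
            float(np.interp(d, c.x, c.y))
            for c in curves
            if c.x[0] <= d <= c.x[-1]
        ]
        if len(vals) >= 2 and np.mean(vals) > 0:
            cvs.append(np.std(vals) / np.mean(vals))
    return float(np.mean(cvs)) if cvs else None


def curves_to_frame(curves: list[ExperimentalCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for i in range(len(c.x)):
            rows.append(
                {
                    "study_id": c.study_id,
                    "organism": c.organism,
                    "metabolite": c.metabolite,
                    "measurement_type": c.measurement_type,
                    "unit": c.unit,
                    "pre_dose_mM": c.pre_dose,
                    "inc_dose_mM": c.inc_dose,
                    "x_type": c.x_type,
                    "x_value": c.x[i],
                    "y_value": c.y[i],
                    "y_sd": c.y_sd[i] if c.y_sd is not None else np.nan,
                    "weight": c.weight,
                }
            )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def frame_to_curves(df: pd.DataFrame) -> list[ExperimentalCurve]:
    curves = []
    keys = ["study_id", "metabolite", "x_type", "measurement_type", "pre_dose_mM", "inc_dose_mM"]
    work = df.copy()
    work["inc_dose_mM"] = work["inc_dose_mM"].astype(float)
    for key, grp in work.groupby(keys, dropna=False, sort=False):
        grp = grp.sort_values("x_value")
        sid, met, x_type, mtype, pre, inc = key
        y_sd = grp["y_sd"].to_numpy() if "y_sd" in grp and grp["y_sd"].notna().any() else None
        curves.append(
            ExperimentalCurve(
                study_id=str(sid),
                metabolite=str(met),
                measurement_type=str(mtype),
                unit=str(grp["unit"].iloc[0]),
                x=grp["x_value"].to_numpy(),
                y=grp["y_value"].to_numpy(),
                x_type=str(x_type),
                pre_dose=float(pre),
                inc_dose=None if pd.isna(inc) else float(inc),
                organism=str(grp["organism"].iloc[0]) if "organism" in grp else "",
                weight=float(grp["weight"].iloc[0]) if "weight" in grp and pd.notna(grp["weight"].iloc[0]) else 1.0,
                y_sd=y_sd,
            )
        )
    return curves


def read_curves_csv(path) -> list[ExperimentalCurve]:
    return frame_to_curves(pd.read_csv(path))


def write_curves_csv(curves: list[ExperimentalCurve], path) -> None:
    curves_to_frame(curves).to_csv(path, index=False)


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
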