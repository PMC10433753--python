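"""Compiled right-hand side of the GSIS ODE system.

The model structure is flattened into index arrays (CSR-style substrate /
product lists over a canonical 25-species concentration vector) so that one
generic numba kernel evaluates all modular and saturable rate laws, the
adenine-pool adjustment flux and the biphasic insulin-release flux.  The
kernel is shared by simulation, calibration and sensitivity analysis; a
compiled view is cached on the ModelDefinition and rebuilt cheaply whenever a
parameter changes.

Reaction order: the 16 modular-rate-law reactions, then ATPCONS, NADHOX,
DATP, IRS_FP, IRS_SP (21 columns).  Dynamic state: the 13 carbon
intermediates (glc..lac), atp, adp and secreted insulin; phosphate and the
pyridine nucleotides join the state only when the glucose assignment rules
are disabled (conservation tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .model import SPECIES_TABLE, MODULAR_REACTIONS, ModelDefinition

SPECIES_ORDER = list(SPECIES_TABLE)
SPECIES_INDEX = {sid: i for i, sid in enumerate(SPECIES_ORDER)}
REACTION_ORDER = list(MODULAR_REACTIONS) + ["ATPCONS", "NADHOX", "DATP", "IRS_FP", "IRS_SP"]

_I_PHOS = SPECIES_INDEX["phos"]
_I_ATP = SPECIES_INDEX["atp"]
_I_ADP = SPECIES_INDEX["adp"]
_I_GLCEXT = SPECIES_INDEX["glc_ext"]


@njit(cache=True)
def _polyval(coeffs, x):
    out = 0.0
    for c in coeffs:
        out = out * x + c
    return out


@njit(cache=True)
def _rhs_core(
    y,
    glc_ext,
    c_template,
    dyn_idx,
    sub_ptr,
    sub_idx,
    sub_km,
    prod_ptr,
    prod_idx,
    prod_km,
    vmax,
    keq,
    irrev,
    srow,
    scol,
    sval,
    atp_row,
    rule_coeffs,
    atptot_coeffs,
    dom_lo,
    dom_hi,
    datp_f,
    irs_p,
    rules_on,
    datp_on,
    scratch,
):
    # scratch: (25 + 21 + n_dyn) work array reused across calls
    n = dyn_idx.shape[0]
    c = scratch[:25]
    flux = scratch[25:46]
    dydt = scratch[46 : 46 + n]
    for i in range(25):
        c[i] = c_template[i]
    c[_I_GLCEXT] = glc_ext
    for i in range(n):
        c[dyn_idx[i]] = y[i]
    g = glc_ext
    if g < dom_lo:
        g = dom_lo
    elif g > dom_hi:
        g = dom_hi
    if rules_on:
        for k in range(3):
            c[_I_PHOS + k] = _polyval(rule_coeffs[k], g)

    for r in range(18, 21):
        flux[r] = 0.0
    for r in range(18):
        pa = 1.0
        da = 1.0
        for j in range(sub_ptr[r], sub_ptr[r + 1]):
            a = c[sub_idx[j]]
            if a < 0.0:
                a = 0.0
            a /= sub_km[j]
            pa *= a
            da *= 1.0 + a
        pb = 1.0
        db = 1.0
        for j in range(prod_ptr[r], prod_ptr[r + 1]):
            b = c[prod_idx[j]]
            if b < 0.0:
                b = 0.0
            b /= prod_km[j]
            pb *= b
            db *= 1.0 + b
        if irrev[r]:
            num = pa
        else:
            num = pa - pb / keq[r]
        flux[r] = vmax[r] * num / (da + db - 1.0)

    if datp_on:
        target = _polyval(atptot_coeffs, g)
        flux[18] = datp_f * (target - (c[_I_ATP] + c[_I_ADP]))

    datp_rate = 0.0
    for r in range(19):
        datp_rate += atp_row[r] * flux[r]

    adp = c[_I_ADP]
    if adp > 0.0:
        m = datp_rate
        if m < 0.0:
            m = 0.0
        flux[19] = irs_p[0] * m / (m + irs_p[1])
        ratio = c[_I_ATP] / adp
        rn = ratio ** irs_p[4]
        flux[20] = irs_p[2] * rn / (rn + irs_p[3] ** irs_p[4])

    for i in range(n):
        dydt[i] = 0.0
    for k in range(srow.shape[0]):
        dydt[srow[k]] += sval[k] * flux[scol[k]]
    return dydt, flux


@dataclass
class CompiledModel:
    """Flattened, kernel-ready view of a ModelDefinition."""

    model: ModelDefinition
    rules_on: bool
    datp_on: bool
    c_template: np.ndarray
    dyn_idx: np.ndarray
    dyn_species: list
    sub_ptr: np.ndarray
    sub_idx: np.ndarray
    sub_km: np.ndarray
    prod_ptr: np.ndarray
    prod_idx: np.ndarray
    prod_km: np.ndarray
    vmax: np.ndarray
    keq: np.ndarray
    irrev: np.ndarray
    S_full: np.ndarray
    S_dyn: np.ndarray
    srow: np.ndarray
    scol: np.ndarray
    sval: np.ndarray
    scratch: np.ndarray
    atp_row: np.ndarray
    rule_coeffs: np.ndarray
    atptot_coeffs: np.ndarray
    irs_p: np.ndarray
    datp_f: float

    def rhs(self, y: np.ndarray, t: float, glc_ext: float) -> np.ndarray:
        return _rhs_core(*self._args(y, glc_ext))[0].copy()

    def fluxes(self, y: np.ndarray, glc_ext: float) -> np.ndarray:
        return _rhs_core(*self._args(y, glc_ext))[1].copy()

    def _args(self, y, glc_ext):
        from .model import DOSE_DOMAIN

        return (
            np.asarray(y, dtype=np.float64),
            float(glc_ext),
            self.c_template,
            self.dyn_idx,
            self.sub_ptr,
            self.sub_idx,
            self.sub_km,
            self.prod_ptr,
            self.prod_idx,
            self.prod_km,
            self.vmax,
            self.keq,
            self.irrev,
            self.srow,
            self.scol,
            self.sval,
            self.atp_row,
            self.rule_coeffs,
            self.atptot_coeffs,
            DOSE_DOMAIN[0],
            DOSE_DOMAIN[1],
            self.datp_f,
            self.irs_p,
            self.rules_on,
            self.datp_on,
            self.scratch,
        )

    def odeint_args(self, glc_ext: float) -> tuple:
        """Positional extra args for scipy.integrate.odeint via _rhs_odeint."""
        a = self._args(np.zeros(1), glc_ext)
        return a[1:]

    def y0(self) -> np.ndarray:
        sp = self.model.species_by_id()
        return np.array(
            [sp[s].initial_concentration for s in self.dyn_species], dtype=np.float64
        )

    def concentrations(self, y: np.ndarray, glc_ext: float) -> np.ndarray:
        """Full 25-species concentration vector for a dynamic state."""
        from .model import DOSE_DOMAIN

        c = self.c_template.copy()
        c[_I_GLCEXT] = glc_ext
        c[self.dyn_idx] = y
        if self.rules_on:
            g = min(max(glc_ext, DOSE_DOMAIN[0]), DOSE_DOMAIN[1])
            for k, rule in enumerate(self.model.cofactor_rules):
                c[_I_PHOS + k] = _polyval_py(self.rule_coeffs[k], g)
        return c


def _polyval_py(coeffs, x):
    return float(np.polyval(coeffs, x))


def _rhs_odeint(y, t, *args):
    return _rhs_core(y, *args)[0]


@njit(cache=True)
def _jac_core(
    y,
    glc_ext,
    c_template,
    dyn_idx,
    sub_ptr,
    sub_idx,
    sub_km,
    prod_ptr,
    prod_idx,
    prod_km,
    vmax,
    keq,
    irrev,
    srow,
    scol,
    sval,
    atp_row,
    rule_coeffs,
    atptot_coeffs,
    dom_lo,
    dom_hi,
    datp_f,
    irs_p,
    rules_on,
    datp_on,
    scratch,
):
    """Finite-difference Jacobian evaluated entirely inside the kernel."""
    n = y.shape[0]
    f0, _ = _rhs_core(
        y, glc_ext, c_template, dyn_idx, sub_ptr, sub_idx, sub_km, prod_ptr,
        prod_idx, prod_km, vmax, keq, irrev, srow, scol, sval, atp_row,
        rule_coeffs, atptot_coeffs, dom_lo, dom_hi, datp_f, irs_p, rules_on,
        datp_on, scratch,
    )
    f0c = f0.copy()  # f0 is a view into scratch; the next call overwrites it
    J = np.empty((n, n))
    yp = y.copy()
    for j in range(n):
        h = 1e-7 * abs(y[j]) + 1e-10
        yp[j] = y[j] + h
        f1, _ = _rhs_core(
            yp, glc_ext, c_template, dyn_idx, sub_ptr, sub_idx, sub_km,
            prod_ptr, prod_idx, prod_km, vmax, keq, irrev, srow, scol, sval,
            atp_row, rule_coeffs, atptot_coeffs, dom_lo, dom_hi, datp_f,
            irs_p, rules_on, datp_on, scratch,
        )
        for i in range(n):
            J[i, j] = (f1[i] - f0c[i]) / h
        yp[j] = y[j]
    return J


def _jac_odeint(y, t, *args):
    return _jac_core(y, *args)


def _atptot_coefficients(model: ModelDefinition) -> np.ndarray:
    curve = model.datp.atptot_curve
    coeffs = getattr(curve, "coefficients", None)
    if coeffs is not None:
        return np.asarray(coeffs, dtype=np.float64)
    # generic callable: recover a polynomial representation by sampling
    from .model import DOSE_DOMAIN

    g = np.linspace(*DOSE_DOMAIN, 30)
    vals = np.array([curve(x) for x in g])
    return np.polyfit(g, vals, 5)


def compile_model(
    model: ModelDefinition, *, rules_on: bool = True, datp_on: bool = True
) -> CompiledModel:
    """Flatten a ModelDefinition into kernel arrays (cached on the model)."""
    cache = model._cache
    if (
        isinstance(cache, dict)
        and (rules_on, datp_on) in cache
    ):
        return cache[(rules_on, datp_on)]

    rxns = model.reactions_by_id()
    n_sat = 18
    sub_ptr = np.zeros(n_sat + 1, dtype=np.int64)
    prod_ptr = np.zeros(n_sat + 1, dtype=np.int64)
    sub_idx: list[int] = []
    sub_km: list[float] = []
    prod_idx: list[int] = []
    prod_km: list[float] = []
    vmax = np.zeros(n_sat)
    keq = np.ones(n_sat)
    irrev = np.zeros(n_sat, dtype=np.uint8)

    for r, rid in enumerate(REACTION_ORDER[:n_sat]):
        rd = rxns[rid]
        if rd.kind == "modular":
            k = rd.kinetics
            for sid, km in k.Km_substrates:
                sub_idx.append(SPECIES_INDEX[sid])
                sub_km.append(km)
            for sid, km in k.Km_products:
                prod_idx.append(SPECIES_INDEX[sid])
                prod_km.append(km)
            vmax[r] = k.Vmax
            # Γ uses raw concentrations: Πa·(1−Γ/Keq) = Πa − Πb/keq_eff with
            # keq_eff = Keq·ΠKms/ΠKmp (pre-scaled once here)
            kms_prod = np.prod([km for _, km in k.Km_substrates])
            kmp_prod = np.prod([km for _, km in k.Km_products]) if k.Km_products else 1.0
            keq[r] = k.Keq * kms_prod / kmp_prod
            irrev[r] = 1 if k.irreversible else 0
        else:  # saturable (ATPCONS / NADHOX)
            sub_idx.append(SPECIES_INDEX[rd.kinetics["substrate"]])
            sub_km.append(rd.kinetics["Km"])
            vmax[r] = rd.kinetics["Vm"]
            irrev[r] = 1
        sub_ptr[r + 1] = len(sub_idx)
        prod_ptr[r + 1] = len(prod_idx)

    S_full = np.zeros((25, 21))
    for r, rid in enumerate(REACTION_ORDER):
        for sid, coef in rxns[rid].stoichiometry.items():
            S_full[SPECIES_INDEX[sid], r] = coef

    sp = model.species_by_id()
    dyn_species = [
        sid
        for sid in SPECIES_ORDER
        if not sp[sid].boundary and (not sp[sid].rule_governed or not rules_on)
    ]
    dyn_idx = np.array([SPECIES_INDEX[s] for s in dyn_species], dtype=np.int64)
    S_dyn = np.ascontiguousarray(S_full[dyn_idx, :])
    srow, scol = np.nonzero(S_dyn)
    sval = S_dyn[srow, scol].copy()
    srow = srow.astype(np.int64)
    scol = scol.astype(np.int64)
    atp_row = np.ascontiguousarray(S_full[_I_ATP, :])

    c_template = np.zeros(25)
    for sid in SPECIES_ORDER:
        c_template[SPECIES_INDEX[sid]] = sp[sid].initial_concentration

    deg = max(rule.degree for rule in model.cofactor_rules)
    rule_coeffs = np.zeros((3, deg + 1))
    order = {"phos": 0, "nad": 1, "nadh": 2}
    for rule in model.cofactor_rules:
        k = order[rule.species_id]
        rule_coeffs[k, -(rule.degree + 1) :] = rule.coefficients

    irs_p = np.array(
        [model.irs.kd_fp, model.irs.Km_fp, model.irs.Vmax_sp, model.irs.Km_sp, model.irs.n_sp]
    )

    cm = CompiledModel(
        model=model,
        rules_on=rules_on,
        datp_on=datp_on,
        c_template=c_template,
        dyn_idx=dyn_idx,
        dyn_species=dyn_species,
        sub_ptr=sub_ptr,
        sub_idx=np.array(sub_idx, dtype=np.int64),
        sub_km=np.array(sub_km),
        prod_ptr=prod_ptr,
        prod_idx=np.array(prod_idx, dtype=np.int64),
        prod_km=np.array(prod_km),
        vmax=vmax,
        keq=keq,
        irrev=irrev,
        S_full=S_full,
        S_dyn=S_dyn,
        srow=srow,
        scol=scol,
        sval=sval,
        scratch=np.zeros(46 + len(dyn_species)),
        atp_row=atp_row,
        rule_coeffs=rule_coeffs,
        atptot_coeffs=_atptot_coefficients(model),
        irs_p=irs_p,
        datp_f=model.datp.f,
    )
    if not isinstance(model._cache, dict):
        model._cache = {}
    model._cache[(rules_on, datp_on)] = cm
    return cm
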