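"""Kinetic rate laws of the β-cell GSIS model.

Three rate-law families drive the model:

* the *modular rate law*, a generic reversible saturable kinetics used for all
  glycolytic reactions and transporters,

      ν = Vmax · Π a_i · (1 − Γ/Keq) / (Π(1+a_i) + Π(1+b_j) − 1)

  with normalized substrate concentrations a_i = S_i/Km_s,i, normalized product
  concentrations b_j = P_j/Km_p,j and the mass-action ratio Γ = Π P_j / Π S_i;

* the biphasic insulin-release flux, the sum of a dynamic first phase driven by
  the rate of change of ATP and a sustained second phase given by a Hill
  function of the ATP/ADP ratio;

* the total-adenine-nucleotide adjustment flux, a first-order relaxation of
  ATP+ADP toward the glucose-dependent steady-state target ATPtot(glc).

All concentrations are mM, time is minutes, metabolic fluxes are mM/min and
insulin release is nmol/min/ml β-cell volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ModularRateLawParams",
    "IRSParams",
    "DeltaATPParams",
    "modular_rate_flux",
    "irs_flux",
    "irs_flux_components",
    "datp_flux",
]


@dataclass
class ModularRateLawParams:
    """Parameters of one modular-rate-law reaction.

    ``Km_substrates`` / ``Km_products`` pair species ids with half-saturation
    constants (mM). ``Keq`` is the dimensionless equilibrium constant; for
    irreversible reactions the thermodynamic term is dropped from the rate but
    product saturation is kept in the denominator.
    """

    Vmax: float
    Km_substrates: list[tuple[str, float]]
    Km_products: list[tuple[str, float]] = field(default_factory=list)
    Keq: float = 1.0
    irreversible: bool = False

    def validate(self) -> None:
        if not self.Vmax > 0:
            raise ValueError(f"Vmax must be > 0, got {self.Vmax}")
        for sid, km in self.Km_substrates + self.Km_products:
            if not km > 0:
                raise ValueError(f"Km for {sid!r} must be > 0, got {km}")
        if not self.irreversible and not self.Keq > 0:
            raise ValueError(f"Keq must be > 0 for reversible kinetics, got {self.Keq}")


@dataclass
class IRSParams:
    """Parameters of the biphasic insulin-release flux.

    kd_fp
        proportionality constant of the first phase (nmol/min/ml).
    Km_fp
        half-maximal constant of the first phase, in units of dATP/dt (mM/min).
    Vmax_sp
        maximal second-phase release rate (nmol/min/ml).
    Km_sp
        ATP/ADP ratio at half-maximal second-phase release (dimensionless);
        displayed as ``IRS_Katp_ratio`` in sensitivity reports.
    n_sp
        Hill coefficient of the second phase; displayed as
        ``IRS_hillKatp_ratio``.
    """

    kd_fp: float
    Km_fp: float
    Vmax_sp: float
    Km_sp: float
    n_sp: float

    def validate(self) -> None:
        for name in ("kd_fp", "Km_fp", "Vmax_sp", "Km_sp", "n_sp"):
            if not getattr(self, name) > 0:
                raise ValueError(f"IRS parameter {name} must be > 0")
        if self.n_sp < 1:
            raise ValueError(f"Hill coefficient n_sp must be >= 1, got {self.n_sp}")


@dataclass
class DeltaATPParams:
    """First-order adjustment of the total adenine nucleotide pool.

    ``f`` (1/min) sets the relaxation rate of ATP+ADP toward the target curve
    ``atptot_curve``: a callable mapping external glucose (mM) to the observed
    steady-state ATP+ADP (mM), clamped to its fitting domain.
    """

    f: float
    atptot_curve: Callable[[float], float]

    def validate(self) -> None:
        if not self.f > 0:
            raise ValueError(f"DATP rate f must be > 0, got {self.f}")


def modular_rate_flux(
    substrate_concs: Sequence[float],
    product_concs: Sequence[float],
    params: ModularRateLawParams,
) -> float:
    """Evaluate the modular rate law for one reaction.

    The mass-action ratio Γ = Π P_j / Π S_i uses raw concentrations, so the
    thermodynamic numerator is evaluated in the algebraically equivalent
    product form ``Vmax·(Π a_i − Π P_j / (Π Km_s · Keq))`` rather than via Γ
    itself; zero substrate concentrations (where Γ is undefined) then give a
    finite (negative or zero) flux. For irreversible reactions the reverse
    term is dropped, but product saturation is kept in the denominator.
    """
    S = np.asarray(substrate_concs, dtype=float)
    P = np.asarray(product_concs, dtype=float)
    if np.any(S < 0) or np.any(P < 0):
        raise ValueError("concentrations must be non-negative")
    kms = np.array([km for _, km in params.Km_substrates], dtype=float)
    kmp = np.array([km for _, km in params.Km_products], dtype=float)
    if S.size != kms.size or P.size != kmp.size:
        raise ValueError("concentration / Km length mismatch")
    a = S / kms
    b = P / kmp if P.size else np.empty(0)
    prod_a = float(np.prod(a)) if a.size else 1.0
    denom = float(np.prod(1.0 + a)) + float(np.prod(1.0 + b)) - 1.0
    if params.irreversible:
        num = prod_a
    else:
        # Πa·(1 − Γ/Keq) with Γ = ΠP/ΠS, written without Γ:
        num = prod_a - float(np.prod(P)) / (float(np.prod(kms)) * params.Keq)
    return params.Vmax * num / denom


def irs_flux_components(
    datp_rate: float, atp: float, adp: float, params: IRSParams
) -> tuple[float, float]:
    """First- and second-phase insulin release fluxes, separately.

    The first phase saturates in the (clamped, non-negative) rate of change of
    ATP; the second phase is a Hill function of the ATP/ADP ratio.
    """
    if atp < 0:
        raise ValueError("atp must be non-negative")
    if adp <= 0:
        raise ValueError("ATP/ADP ratio undefined: adp must be > 0")
    m = max(datp_rate, 0.0)
    fp = params.kd_fp * m / (m + params.Km_fp)
    r = atp / adp
    rn = r**params.n_sp
    sp = params.Vmax_sp * rn / (rn + params.Km_sp**params.n_sp)
    return fp, sp


def irs_flux(datp_rate: float, atp: float, adp: float, params: IRSParams) -> float:
    """Total biphasic insulin release flux (nmol/min/ml)."""
    fp, sp = irs_flux_components(datp_rate, atp, adp, params)
    return fp + sp


def datp_flux(glc_ext: float, atp: float, adp: float, params: DeltaATPParams) -> float:
    """Signed adjustment flux driving ATP+ADP toward ATPtot(glc_ext)."""
    target = params.atptot_curve(glc_ext)
    return params.f * (target - (atp + adp))
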