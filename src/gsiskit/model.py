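"""Assembly of the β-cell glycolysis + insulin-secretion kinetic model.

The network couples glucose uptake (GLUT) and glycolysis down to pyruvate with
lactate export, mitochondrial pyruvate transport, an ATP-consumption load, and
a phenomenological biphasic insulin-release flux driven by the cellular energy
state (ATP/ADP ratio and dATP/dt).

The default census is fixed: 3 compartments, 25 species, 21 reactions and a
91-entry parameter ledger (49 Km + 16 Keq + 16 Vmax over the modular-rate-law
reactions, 2 NADHOX + 2 ATPCONS saturable constants, 1 pool-adjustment rate,
5 insulin-release constants). Phosphate, NAD and NADH are governed by
glucose-dependent polynomial assignment rules; external glucose and lactate,
mitochondrial pyruvate, water and protons are boundary species.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .ratelaws import DeltaATPParams, IRSParams, ModularRateLawParams

__all__ = [
    "Compartment",
    "SpeciesDef",
    "ReactionDef",
    "CofactorRule",
    "ModelDefinition",
    "aggregate_parameter_values",
    "build_model",
    "check_balances",
    "default_ledger",
    "read_ledger_csv",
    "write_ledger_csv",
    "MODULAR_REACTIONS",
    "FITTED_VMAX_IDS",
    "GLYCOLYTIC_INTERMEDIATES",
    "DOSE_DOMAIN",
]

# ---------------------------------------------------------------------------
# Census
# ---------------------------------------------------------------------------

DOSE_DOMAIN = (1.0, 35.0)  # mM external glucose covered by the data set

#: id -> (compartment, formula, charge, boundary, rule_governed)
SPECIES_TABLE: dict[str, tuple[str, str | None, int, bool, bool]] = {
    # cytosol (20)
    "glc": ("cyto", "C6H12O6", 0, False, False),
    "g6p": ("cyto", "C6H11O9P", -2, False, False),
    "f6p": ("cyto", "C6H11O9P", -2, False, False),
    "fbp": ("cyto", "C6H10O12P2", -4, False, False),
    "f26bp": ("cyto", "C6H10O12P2", -4, False, False),
    "dhap": ("cyto", "C3H5O6P", -2, False, False),
    "grap": ("cyto", "C3H5O6P", -2, False, False),
    "bpg13": ("cyto", "C3H4O10P2", -4, False, False),
    "pg3": ("cyto", "C3H4O7P", -3, False, False),
    "pg2": ("cyto", "C3H4O7P", -3, False, False),
    "pep": ("cyto", "C3H2O6P", -3, False, False),
    "pyr": ("cyto", "C3H3O3", -1, False, False),
    "lac": ("cyto", "C3H5O3", -1, False, False),
    "phos": ("cyto", "HPO4", -2, False, True),
    "nad": ("cyto", "C21H26N7O14P2", -1, False, True),
    "nadh": ("cyto", "C21H27N7O14P2", -2, False, True),
    "atp": ("cyto", "C10H12N5O13P3", -4, False, False),
    "adp": ("cyto", "C10H12N5O10P2", -3, False, False),
    "h2o": ("cyto", "H2O", 0, True, False),
    "h": ("cyto", "H", 1, True, False),
    # external / blood (4)
    "glc_ext": ("ext", "C6H12O6", 0, True, False),
    "lac_ext": ("ext", "C3H5O3", -1, True, False),
    "h_ext": ("ext", "H", 1, True, False),
    "ins": ("ext", None, 0, False, False),
    # mitochondrion (1)
    "pyr_mito": ("mito", "C3H3O3", -1, True, False),
}

#: the 16 reactions carrying modular rate laws and the fitted Vmax set:
#: id -> (stoichiometry, kinetic substrates, kinetic products, irreversible)
MODULAR_REACTIONS: dict[str, tuple[dict[str, int], list[str], list[str], bool]] = {
    "GLUT": ({"glc_ext": -1, "glc": 1}, ["glc_ext"], ["glc"], False),
    "HEX1": (
        {"glc": -1, "atp": -1, "g6p": 1, "adp": 1, "h": 1},
        ["glc", "atp"],
        ["g6p", "adp"],
        False,
    ),
    "PGI": ({"g6p": -1, "f6p": 1}, ["g6p"], ["f6p"], False),
    "PFK1": (
        {"f6p": -1, "atp": -1, "fbp": 1, "adp": 1, "h": 1},
        ["f6p", "atp"],
        ["fbp", "adp"],
        False,
    ),
    "PFK2": (
        {"f6p": -1, "atp": -1, "f26bp": 1, "adp": 1, "h": 1},
        ["f6p", "atp"],
        ["f26bp", "adp"],
        False,
    ),
    "FBP26": (
        {"f26bp": -1, "h2o": -1, "f6p": 1, "phos": 1},
        ["f26bp"],
        ["f6p", "phos"],
        False,
    ),
    "FBA": ({"fbp": -1, "dhap": 1, "grap": 1}, ["fbp"], ["dhap", "grap"], False),
    "TPI": ({"dhap": -1, "grap": 1}, ["dhap"], ["grap"], False),
    "GAPDH": (
        {"grap": -1, "nad": -1, "phos": -1, "bpg13": 1, "nadh": 1, "h": 1},
        ["grap", "nad", "phos"],
        ["bpg13", "nadh"],
        False,
    ),
    "PGK": (
        {"bpg13": -1, "adp": -1, "pg3": 1, "atp": 1},
        ["bpg13", "adp"],
        ["pg3", "atp"],
        False,
    ),
    "PGM": ({"pg3": -1, "pg2": 1}, ["pg3"], ["pg2"], False),
    "ENO": ({"pg2": -1, "pep": 1, "h2o": 1}, ["pg2"], ["pep"], False),
    "PK": (
        {"pep": -1, "adp": -1, "h": -1, "pyr": 1, "atp": 1},
        ["pep", "adp"],
        ["pyr", "atp"],
        False,
    ),
    "LDH": (
        {"pyr": -1, "nadh": -1, "h": -1, "lac": 1, "nad": 1},
        ["pyr", "nadh"],
        ["lac", "nad"],
        False,
    ),
    "LACT": ({"lac": -1, "lac_ext": 1}, ["lac"], ["lac_ext"], True),
    "PYRT": ({"pyr": -1, "pyr_mito": 1}, ["pyr"], ["pyr_mito"], True),
}

FITTED_VMAX_IDS = tuple(MODULAR_REACTIONS)  # the 16 calibrated Vmax parameters

GLYCOLYTIC_INTERMEDIATES = (
    "g6p",
    "f6p",
    "fbp",
    "f26bp",
    "dhap",
    "grap",
    "bpg13",
    "pg3",
    "pg2",
    "pep",
    "pyr",
    "lac",
)

# Mean steady-state dose responses of the rule-governed cofactors and of
# total adenine nucleotides: phosphate falls as sugar phosphates accumulate,
# NADH and ATP+ADP rise with glucose, NAD falls mildly.  Degree-3 polynomials
# through these curves define the assignment rules and the ATPtot target.
COFACTOR_DOSE_GRID = np.array([1.0, 2.8, 5.0, 10.0, 16.7, 20.0, 30.0, 35.0])
COFACTOR_MEAN_CURVES: dict[str, np.ndarray] = {
    "phos": np.array([4.20, 4.00, 3.80, 3.40, 3.00, 2.90, 2.60, 2.50]),
    "nad": np.array([0.500, 0.480, 0.450, 0.420, 0.400, 0.390, 0.370, 0.360]),
    "nadh": np.array([0.050, 0.060, 0.080, 0.110, 0.130, 0.135, 0.145, 0.150]),
}
ATPTOT_MEAN_CURVE = np.array([3.00, 3.15, 3.40, 3.80, 4.10, 4.20, 4.45, 4.55])


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Compartment:
    id: str
    volume: float  # litres
    role: str  # external/blood, cytosol, mitochondrion

    def validate(self) -> None:
        if not self.volume > 0:
            raise ValueError(f"compartment {self.id}: volume must be > 0")


@dataclass
class SpeciesDef:
    id: str
    compartment: str
    initial_concentration: float  # mM
    charge: int = 0
    formula: str | None = None
    boundary: bool = False
    rule_governed: bool = False

    def validate(self) -> None:
        if self.initial_concentration < 0:
            raise ValueError(f"species {self.id}: initial concentration < 0")


@dataclass
class CofactorRule:
    """Glucose-dependent assignment rule c = poly(glc_ext), clamped to the
    dose domain, for phosphate and the pyridine nucleotides."""

    species_id: str
    coefficients: np.ndarray  # highest power first (np.polyval convention)
    domain: tuple[float, float] = DOSE_DOMAIN

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, glc_ext: float) -> float:
        g = min(max(glc_ext, self.domain[0]), self.domain[1])
        return float(np.polyval(self.coefficients, g))

    def validate(self) -> None:
        grid = np.linspace(*self.domain, 200)
        vals = np.polyval(self.coefficients, grid)
        if np.any(vals <= 0):
            raise ValueError(
                f"cofactor rule for {self.species_id} non-positive on dose domain"
            )


@dataclass
class ReactionDef:
    id: str
    stoichiometry: dict[str, int]
    kinetics: object  # ModularRateLawParams | IRSParams | DeltaATPParams | dict
    pseudo: bool = False
    kind: str = "modular"  # modular | saturable | datp | irs_fp | irs_sp


@dataclass
class ModelDefinition:
    """The assembled GSIS model (structure + parameter values + rules)."""

    compartments: list[Compartment]
    species: list[SpeciesDef]
    reactions: list[ReactionDef]
    cofactor_rules: list[CofactorRule]
    irs: IRSParams
    datp: DeltaATPParams
    annotations: dict[str, dict[str, str]] = field(default_factory=dict)

    def species_by_id(self) -> dict[str, SpeciesDef]:
        return {s.id: s for s in self.species}

    def reactions_by_id(self) -> dict[str, ReactionDef]:
        return {r.id: r for r in self.reactions}

    def parameters(self) -> dict[str, float]:
        """Flat view of the 91-entry parameter ledger."""
        params: dict[str, float] = {}
        for r in self.reactions:
            if r.kind == "modular":
                k: ModularRateLawParams = r.kinetics
                params[f"{r.id}_Vmax"] = k.Vmax
                params[f"{r.id}_Keq"] = k.Keq
                for sid, km in k.Km_substrates:
                    params[f"{r.id}_Kms_{sid}"] = km
                for sid, km in k.Km_products:
                    params[f"{r.id}_Kmp_{sid}"] = km
            elif r.kind == "saturable":
                params[f"{r.id}_Vm"] = r.kinetics["Vm"]
                params[f"{r.id}_Km"] = r.kinetics["Km"]
        params["DATP_f"] = self.datp.f
        params["IRS_kd_fp"] = self.irs.kd_fp
        params["IRS_Km_fp"] = self.irs.Km_fp
        params["IRS_Vmax_sp"] = self.irs.Vmax_sp
        params["IRS_Km_sp"] = self.irs.Km_sp
        params["IRS_n_sp"] = self.irs.n_sp
        return params

    def set_parameter(self, name: str, value: float) -> None:
        """Update one ledger entry in place (invalidates compiled caches)."""
        rxns = self.reactions_by_id()
        if name == "DATP_f":
            self.datp.f = value
        elif name.startswith("IRS_"):
            attr = name[len("IRS_") :]
            if not hasattr(self.irs, attr):
                raise KeyError(name)
            setattr(self.irs, attr, value)
        else:
            rid, _, rest = name.partition("_")
            if rid not in rxns:
                raise KeyError(name)
            r = rxns[rid]
            if r.kind == "saturable" and rest in ("Vm", "Km"):
                r.kinetics[rest] = value
            elif r.kind == "modular":
                k: ModularRateLawParams = r.kinetics
                if rest == "Vmax":
                    k.Vmax = value
                elif rest == "Keq":
                    k.Keq = value
                elif rest.startswith("Kms_"):
                    sid = rest[4:]
                    k.Km_substrates = [
                        (s, value if s == sid else km) for s, km in k.Km_substrates
                    ]
                elif rest.startswith("Kmp_"):
                    sid = rest[4:]
                    k.Km_products = [
                        (s, value if s == sid else km) for s, km in k.Km_products
                    ]
                else:
                    raise KeyError(name)
            else:
                raise KeyError(name)
        self._cache = None

    _cache: object = None  # compiled kernel arrays (see _kernel.py)

    def validate(self) -> None:
        for c in self.compartments:
            c.validate()
        for s in self.species:
            s.validate()
        for rule in self.cofactor_rules:
            rule.validate()
        self.irs.validate()
        self.datp.validate()
        if len(self.compartments) != 3:
            raise ValueError(f"expected 3 compartments, got {len(self.compartments)}")
        if len(self.species) != 25:
            raise ValueError(f"expected 25 species, got {len(self.species)}")
        if len(self.reactions) != 21:
            raise ValueError(f"expected 21 reactions, got {len(self.reactions)}")
        n_params = len(self.parameters())
        if n_params != 91:
            raise ValueError(f"expected 91 parameters, got {n_params}")
        # ledger arithmetic: 49 Km + 16 Keq + 16 Vmax + 2 + 2 + 1 + 5
        names = self.parameters()
        n_km = sum(1 for n in names if "_Kms_" in n or "_Kmp_" in n)
        n_keq = sum(1 for n in names if n.endswith("_Keq"))
        n_vmax = sum(
            1 for n in names if n.endswith("_Vmax") and not n.startswith("IRS")
        )
        assert (n_km, n_keq, n_vmax) == (49, 16, 16), (n_km, n_keq, n_vmax)


# ---------------------------------------------------------------------------
# Parameter ledger
# ---------------------------------------------------------------------------

LEDGER_COLUMNS = [
    "reaction_id",
    "parameter_role",
    "species_id",
    "value",
    "unit",
    "source_note",
]

# Default kinetic constants.  Km values follow typical mammalian/islet enzyme
# ranges (GLUT2 ~17 mM, glucokinase ~8 mM, downstream enzymes 0.01-10 mM);
# Keq values follow standard transformed equilibrium constants for glycolysis;
# Vmax values are the package's calibrated defaults that reproduce the
# observed GSIS phenomenology and serve as ground truth for synthetic data.
_DEFAULT_LEDGER_CSV = """\
reaction_id,parameter_role,species_id,value,unit,source_note
GLUT,Vmax,,12.0,mM/min,calibrated default
GLUT,Keq,,1.0,dimensionless,facilitated transport
GLUT,Km,glc_ext,17.0,mM,GLUT2 range
GLUT,Km,glc,17.0,mM,GLUT2 range
HEX1,Vmax,,1.9,mM/min,calibrated default
HEX1,Keq,,2000.0,dimensionless,phosphorylation
HEX1,Km,glc,4.0,mM,glucokinase range
HEX1,Km,atp,0.1,mM,literature range
HEX1,Km,g6p,30.0,mM,weak product binding
HEX1,Km,adp,1.0,mM,literature range
PGI,Vmax,,8.0,mM/min,calibrated default
PGI,Keq,,0.36,dimensionless,isomerase equilibrium
PGI,Km,g6p,0.30,mM,literature range
PGI,Km,f6p,0.15,mM,literature range
PFK1,Vmax,,3.0,mM/min,calibrated default
PFK1,Keq,,800.0,dimensionless,phosphorylation
PFK1,Km,f6p,0.10,mM,literature range
PFK1,Km,atp,0.15,mM,literature range
PFK1,Km,fbp,5.0,mM,weak product binding
PFK1,Km,adp,0.5,mM,literature range
PFK2,Vmax,,0.05,mM/min,calibrated default
PFK2,Keq,,700.0,dimensionless,phosphorylation
PFK2,Km,f6p,0.03,mM,literature range
PFK2,Km,atp,0.15,mM,literature range
PFK2,Km,f26bp,0.05,mM,weak product binding
PFK2,Km,adp,0.5,mM,literature range
FBP26,Vmax,,0.15,mM/min,calibrated default
FBP26,Keq,,1000.0,dimensionless,hydrolysis
FBP26,Km,f26bp,0.10,mM,literature range
FBP26,Km,f6p,5.0,mM,weak product binding
FBP26,Km,phos,5.0,mM,weak product binding
FBA,Vmax,,8.0,mM/min,calibrated default
FBA,Keq,,0.40,mM,aldol cleavage (concentration units)
FBA,Km,fbp,0.30,mM,literature range
FBA,Km,dhap,2.0,mM,literature range
FBA,Km,grap,1.0,mM,literature range
TPI,Vmax,,20.0,mM/min,calibrated default
TPI,Keq,,0.045,dimensionless,triose equilibrium
TPI,Km,dhap,1.6,mM,literature range
TPI,Km,grap,0.5,mM,literature range
GAPDH,Vmax,,16.0,mM/min,calibrated default
GAPDH,Keq,,0.5,dimensionless,with phosphate
GAPDH,Km,grap,0.10,mM,literature range
GAPDH,Km,nad,0.05,mM,literature range
GAPDH,Km,phos,3.0,mM,literature range
GAPDH,Km,bpg13,0.10,mM,product binding
GAPDH,Km,nadh,0.05,mM,product binding
PGK,Vmax,,14.0,mM/min,calibrated default
PGK,Keq,,1800.0,dimensionless,toward ATP
PGK,Km,bpg13,0.02,mM,literature range
PGK,Km,adp,0.08,mM,literature range
PGK,Km,pg3,1.0,mM,product binding
PGK,Km,atp,0.40,mM,product binding
PGM,Vmax,,8.0,mM/min,calibrated default
PGM,Keq,,0.18,dimensionless,mutase equilibrium
PGM,Km,pg3,0.20,mM,literature range
PGM,Km,pg2,0.03,mM,literature range
ENO,Vmax,,8.0,mM/min,calibrated default
ENO,Keq,,5.0,dimensionless,enolase equilibrium
ENO,Km,pg2,0.04,mM,literature range
ENO,Km,pep,0.10,mM,literature range
PK,Vmax,,8.0,mM/min,calibrated default
PK,Keq,,10000.0,dimensionless,toward pyruvate
PK,Km,pep,0.30,mM,literature range
PK,Km,adp,0.15,mM,literature range
PK,Km,pyr,10.0,mM,weak product binding
PK,Km,atp,1.0,mM,product binding
LDH,Vmax,,5.0,mM/min,calibrated default
LDH,Keq,,10000.0,dimensionless,toward lactate
LDH,Km,pyr,0.30,mM,literature range
LDH,Km,nadh,0.01,mM,literature range
LDH,Km,lac,10.0,mM,weak product binding
LDH,Km,nad,0.20,mM,product binding
LACT,Vmax,,3.5,mM/min,calibrated default
LACT,Keq,,1.0,dimensionless,inert (irreversible export)
LACT,Km,lac,3.0,mM,monocarboxylate transport
LACT,Km,lac_ext,3.0,mM,monocarboxylate transport
PYRT,Vmax,,1.6,mM/min,calibrated default
PYRT,Keq,,1.0,dimensionless,inert (irreversible transport)
PYRT,Km,pyr,0.15,mM,mitochondrial carrier
PYRT,Km,pyr_mito,0.15,mM,mitochondrial carrier
ATPCONS,Vm,,7.0,mM/min,cellular ATP load
ATPCONS,Km,atp,4.0,mM,cellular ATP load
NADHOX,Vm,,20.0,mM/min,redox closure
NADHOX,Km,nadh,0.02,mM,redox closure
DATP,f,,0.15,1/min,pool adjustment rate
IRS,kd_fp,,3.0,nmol/min/ml,first-phase scale
IRS,Km_fp,,0.05,mM/min,first-phase half-max
IRS,Vmax_sp,,4.0,nmol/min/ml,second-phase max
IRS,Km_sp,,3.0,dimensionless,ATP/ADP half-max
IRS,n_sp,,3.0,dimensionless,Hill coefficient
"""

# Approximate steady state of the default model at 3 mM basal glucose; used as
# default initial concentrations (refined numerically during construction).
DEFAULT_INITIAL_CONCENTRATIONS: dict[str, float] = {
    "glc": 2.159,
    "g6p": 0.16855,
    "f6p": 0.049064,
    "fbp": 0.033274,
    "f26bp": 0.020907,
    "dhap": 0.33818,
    "grap": 0.013189,
    "bpg13": 0.0015348,
    "pg3": 0.14601,
    "pg2": 0.016884,
    "pep": 0.042387,
    "pyr": 0.059025,
    "lac": 0.73973,
    "atp": 0.58677,
    "adp": 2.616,
    "ins": 0.0,
    # boundary
    "glc_ext": 3.0,
    "lac_ext": 1.0,
    "h_ext": 4e-5,
    "h2o": 1.0,
    "h": 4e-5,
    "pyr_mito": 0.05,
    # rule-governed placeholders (overwritten by the rules at evaluation)
    "phos": 4.0,
    "nad": 0.48,
    "nadh": 0.06,
}


def default_ledger() -> pd.DataFrame:
    """The built-in kinetic parameter ledger (one row per parameter slot)."""
    return pd.read_csv(io.StringIO(_DEFAULT_LEDGER_CSV))


def read_ledger_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(LEDGER_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"ledger missing columns: {sorted(missing)}")
    return df


def write_ledger_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def aggregate_parameter_values(values: Iterable[float], slot: str = "") -> float:
    """Median aggregation of multiple reported values for one parameter slot."""
    vals = list(values)
    if not vals:
        raise ValueError(f"no values to aggregate for parameter slot {slot!r}")
    if any(v <= 0 for v in vals):
        raise ValueError(f"non-positive value in parameter slot {slot!r}")
    return float(median(vals))


# ---------------------------------------------------------------------------
# Build
# ---------------------------------------------------------------------------


def _ledger_lookup(df: pd.DataFrame) -> dict[tuple[str, str, str], float]:
    """Aggregate ledger rows (median per slot) into a slot -> value map."""
    out: dict[tuple[str, str, str], float] = {}
    sp = df["species_id"].fillna("")
    for (rid, role, sid), grp in df.groupby(
        [df["reaction_id"], df["parameter_role"], sp], sort=False
    ):
        out[(rid, role, sid)] = aggregate_parameter_values(
            grp["value"].tolist(), slot=f"{rid}/{role}/{sid}"
        )
    return out


def _require(lut: Mapping, key: tuple[str, str, str]) -> float:
    if key not in lut:
        rid, role, sid = key
        slot = f"{rid} {role}" + (f" ({sid})" if sid else "")
        raise ValueError(f"parameter ledger is missing a value for slot: {slot}")
    return lut[key]


def build_model(
    ledger: pd.DataFrame | None = None,
    *,
    initial_concentrations: Mapping[str, float] | None = None,
    cofactor_curves: Mapping[str, np.ndarray] | None = None,
    atptot_curve_values: np.ndarray | None = None,
    dose_grid: np.ndarray | None = None,
    poly_degree: int = 3,
) -> ModelDefinition:
    """Assemble the default GSIS model from a parameter ledger.

    Every Km/Keq/Vmax slot of the census must be present in the ledger
    (multiple rows per slot are median-aggregated).  Cofactor assignment
    rules and the ATPtot target are degree-``poly_degree`` least-squares
    polynomials through the supplied mean steady-state curves, clamped to the
    dose domain outside it.  Initial external glucose is the 3 mM basal dose.
    """
    if ledger is None:
        ledger = default_ledger()
    lut = _ledger_lookup(ledger)

    compartments = [
        Compartment("ext", 1.0e-12, "external/blood"),
        Compartment("cyto", 0.76e-12, "cytosol"),
        Compartment("mito", 0.12e-12, "mitochondrion"),
    ]

    inits = dict(DEFAULT_INITIAL_CONCENTRATIONS)
    if initial_concentrations:
        inits.update(initial_concentrations)
    species = [
        SpeciesDef(
            id=sid,
            compartment=comp,
            initial_concentration=inits[sid],
            charge=charge,
            formula=formula,
            boundary=boundary,
            rule_governed=ruled,
        )
        for sid, (comp, formula, charge, boundary, ruled) in SPECIES_TABLE.items()
    ]

    reactions: list[ReactionDef] = []
    for rid, (stoich, ksubs, kprods, irrev) in MODULAR_REACTIONS.items():
        params = ModularRateLawParams(
            Vmax=_require(lut, (rid, "Vmax", "")),
            Km_substrates=[(s, _require(lut, (rid, "Km", s))) for s in ksubs],
            Km_products=[(p, _require(lut, (rid, "Km", p))) for p in kprods],
            Keq=_require(lut, (rid, "Keq", "")),
            irreversible=irrev,
        )
        params.validate()
        reactions.append(ReactionDef(rid, dict(stoich), params, kind="modular"))

    atpcons_km_sid = "atp"
    reactions.append(
        ReactionDef(
            "ATPCONS",
            {"atp": -1, "h2o": -1, "adp": 1, "phos": 1, "h": 1},
            {
                "Vm": _require(lut, ("ATPCONS", "Vm", "")),
                "Km": _require(lut, ("ATPCONS", "Km", atpcons_km_sid)),
                "substrate": "atp",
            },
            kind="saturable",
        )
    )
    reactions.append(
        ReactionDef(
            "NADHOX",
            {"nadh": -1, "nad": 1, "h": 1},
            {
                "Vm": _require(lut, ("NADHOX", "Vm", "")),
                "Km": _require(lut, ("NADHOX", "Km", "nadh")),
                "substrate": "nadh",
            },
            pseudo=True,
            kind="saturable",
        )
    )

    grid = COFACTOR_DOSE_GRID if dose_grid is None else np.asarray(dose_grid, float)
    curves = dict(COFACTOR_MEAN_CURVES)
    if cofactor_curves:
        curves.update({k: np.asarray(v, float) for k, v in cofactor_curves.items()})
    rules = [
        CofactorRule(sid, np.polyfit(grid, curves[sid], poly_degree))
        for sid in ("phos", "nad", "nadh")
    ]

    atptot_vals = (
        ATPTOT_MEAN_CURVE if atptot_curve_values is None else np.asarray(atptot_curve_values)
    )
    atptot_coeffs = np.polyfit(grid, atptot_vals, poly_degree)
    lo, hi = DOSE_DOMAIN

    def atptot(glc: float, _c=atptot_coeffs) -> float:
        return float(np.polyval(_c, min(max(glc, lo), hi)))

    atptot.coefficients = atptot_coeffs  # type: ignore[attr-defined]

    datp = DeltaATPParams(f=_require(lut, ("DATP", "f", "")), atptot_curve=atptot)
    reactions.append(ReactionDef("DATP", {"atp": 1}, datp, pseudo=True, kind="datp"))

    irs = IRSParams(
        kd_fp=_require(lut, ("IRS", "kd_fp", "")),
        Km_fp=_require(lut, ("IRS", "Km_fp", "")),
        Vmax_sp=_require(lut, ("IRS", "Vmax_sp", "")),
        Km_sp=_require(lut, ("IRS", "Km_sp", "")),
        n_sp=_require(lut, ("IRS", "n_sp", "")),
    )
    reactions.append(ReactionDef("IRS_FP", {"ins": 1}, irs, pseudo=True, kind="irs_fp"))
    reactions.append(ReactionDef("IRS_SP", {"ins": 1}, irs, pseudo=True, kind="irs_sp"))

    annotations = {
        "HEX1": {"ec-code": "2.7.1.1", "kegg.reaction": "R00299"},
        "PGI": {"ec-code": "5.3.1.9", "kegg.reaction": "R00771"},
        "PFK1": {"ec-code": "2.7.1.11", "kegg.reaction": "R00756"},
        "PGK": {"ec-code": "2.7.2.3", "kegg.reaction": "R01512"},
        "PK": {"ec-code": "2.7.1.40", "kegg.reaction": "R00200"},
        "LDH": {"ec-code": "1.1.1.27", "kegg.reaction": "R00703"},
        "bpg13": {"kegg.compound": "C00236", "chebi": "CHEBI:16001"},
        "g6p": {"kegg.compound": "C00092"},
        "atp": {"kegg.compound": "C00002"},
        "adp": {"kegg.compound": "C00008"},
    }

    model = ModelDefinition(
        compartments=compartments,
        species=species,
        reactions=reactions,
        cofactor_rules=rules,
        irs=irs,
        datp=datp,
        annotations=annotations,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Balance checking
# ---------------------------------------------------------------------------

_ELEMENT_RE = __import__("re").compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    out: dict[str, int] = {}
    pos = 0
    for m in _ELEMENT_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        out[m.group(1)] = out.get(m.group(1), 0) + (int(m.group(2) or 1))
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return out


def check_balances(model: ModelDefinition) -> pd.DataFrame:
    """Element- and charge-balance report, one row per reaction.

    Pseudo reactions are exempt (flagged, not checked).  Species without a
    formula make their reactions 'unverifiable' rather than silently passing.
    """
    sp = model.species_by_id()
    rows = []
    for r in model.reactions:
        if r.pseudo:
            rows.append(
                {"reaction_id": r.id, "status": "exempt", "imbalance": "", "charge_imbalance": 0.0}
            )
            continue
        elements: dict[str, float] = {}
        charge = 0.0
        unverifiable = False
        for sid, coef in r.stoichiometry.items():
            s = sp[sid]
            if s.formula is None:
                unverifiable = True
                break
            for el, n in parse_formula(s.formula).items():
                elements[el] = elements.get(el, 0.0) + coef * n
            charge += coef * s.charge
        if unverifiable:
            rows.append(
                {"reaction_id": r.id, "status": "unverifiable", "imbalance": "", "charge_imbalance": float("nan")}
            )
            continue
        imb = {el: v for el, v in elements.items() if abs(v) > 1e-9}
        status = "balanced" if not imb and abs(charge) < 1e-9 else "imbalanced"
        rows.append(
            {
                "reaction_id": r.id,
                "status": status,
                "imbalance": ";".join(f"{el}:{v:+g}" for el, v in sorted(imb.items())),
                "charge_imbalance": charge,
            }
        )
    return pd.DataFrame(rows)
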