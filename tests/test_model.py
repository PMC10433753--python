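"""Model assembly: census, parameter ledger, balances, conservation."""

import numpy as np
import pytest

import gsiskit as gk
from gsiskit.model import (
    FITTED_VMAX_IDS,
    aggregate_parameter_values,
    check_balances,
    default_ledger,
)


class TestCensus:
    def test_counts(self, model):
        assert len(model.reactions) == 21
        assert len(model.species) == 25
        assert len(model.parameters()) == 91
        assert len(model.compartments) == 3

    def test_parameter_ledger_arithmetic(self, model):
        names = model.parameters()
        n_km = sum(1 for n in names if "_Kms_" in n or "_Kmp_" in n)
        n_keq = sum(1 for n in names if n.endswith("_Keq"))
        n_vmax = sum(1 for n in names if n.endswith("_Vmax") and not n.startswith("IRS"))
        n_sat = sum(1 for n in names if n in ("ATPCONS_Vm", "ATPCONS_Km", "NADHOX_Vm", "NADHOX_Km"))
        n_irs = sum(1 for n in names if n.startswith("IRS_"))
        assert (n_km, n_keq, n_vmax, n_sat, n_irs) == (49, 16, 16, 4, 5)
        assert n_km + n_keq + n_vmax + n_sat + n_irs + 1 == 91  # +1 DATP_f

    def test_sixteen_fitted_vmax(self):
        assert len(FITTED_VMAX_IDS) == 16

    def test_initial_external_glucose_is_basal(self, model):
        sp = model.species_by_id()
        assert sp["glc_ext"].initial_concentration == pytest.approx(3.0)
        assert sp["glc_ext"].boundary

    def test_compartment_roles(self, model):
        roles = sorted(c.role for c in model.compartments)
        assert roles == ["cytosol", "external/blood", "mitochondrion"]
        assert all(c.volume > 0 for c in model.compartments)

    def test_missing_ledger_slot_is_reported(self):
        led = default_ledger()
        led = led[~((led.reaction_id == "PGI") & (led.parameter_role == "Keq"))]
        with pytest.raises(ValueError, match="PGI Keq"):
            gk.build_model(led)


class TestAggregation:
    def test_singleton(self):
        assert aggregate_parameter_values([0.7]) == 0.7

    def test_median_of_odd_list(self):
        assert aggregate_parameter_values([1, 2, 10]) == 2

    def test_empty_raises_with_slot_name(self):
        with pytest.raises(ValueError, match="HEX1/Km"):
            aggregate_parameter_values([], slot="HEX1/Km")

    def test_ledger_rows_are_median_aggregated(self):
        led = default_ledger()
        extra = led[(led.reaction_id == "PGI") & (led.parameter_role == "Keq")].copy()
        led = __import__("pandas").concat(
            [led, extra.assign(value=0.2), extra.assign(value=10.0)], ignore_index=True
        )
        m = gk.build_model(led)
        # median of [0.36, 0.2, 10.0] = 0.36
        assert m.parameters()["PGI_Keq"] == pytest.approx(0.36)


class TestBalances:
    def test_all_non_pseudo_reactions_balanced(self, model):
        rep = check_balances(model).set_index("reaction_id")
        non_pseudo = [r.id for r in model.reactions if not r.pseudo]
        for rid in non_pseudo:
            assert rep.loc[rid, "status"] == "balanced", rid

    def test_pseudo_reactions_exempt(self, model):
        rep = check_balances(model).set_index("reaction_id")
        for rid in ("DATP", "IRS_FP", "IRS_SP", "NADHOX"):
            assert rep.loc[rid, "status"] == "exempt"

    def test_constructed_charge_violation_detected(self, model):
        import copy

        broken = copy.deepcopy(model)
        broken._cache = None
        hex1 = broken.reactions_by_id()["HEX1"]
        del hex1.stoichiometry["h"]
        rep = check_balances(broken).set_index("reaction_id")
        assert rep.loc["HEX1", "status"] == "imbalanced"
        assert rep.loc["HEX1", "charge_imbalance"] != 0

    def test_missing_formula_is_unverifiable(self, model):
        import copy

        broken = copy.deepcopy(model)
        broken._cache = None
        broken.species_by_id()["glc"].formula = None
        rep = check_balances(broken).set_index("reaction_id")
        assert rep.loc["HEX1", "status"] == "unverifiable"


class TestMoietyConservation:
    def test_adenine_pool_conserved_without_datp(self, model):
        traj = gk.run_protocol(model, gk.Protocol(3.0, 20.0, 10.0, 10.0), datp=False)
        tot = traj.species("atp") + traj.species("adp")
        assert np.max(np.abs(tot - tot[0])) < 1e-8

    def test_pyridine_pool_conserved_without_rules(self, model):
        traj = gk.run_protocol(
            model, gk.Protocol(3.0, 20.0, 10.0, 10.0), cofactor_rules=False, datp=False
        )
        nadtot = traj.species("nad") + traj.species("nadh")
        atptot = traj.species("atp") + traj.species("adp")
        assert np.max(np.abs(nadtot - nadtot[0])) < 1e-8
        assert np.max(np.abs(atptot - atptot[0])) < 1e-8

    def test_cofactor_rules_positive_on_dose_domain(self, model):
        for rule in model.cofactor_rules:
            g = np.linspace(1.0, 35.0, 100)
            assert np.all(np.polyval(rule.coefficients, g) > 0)
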