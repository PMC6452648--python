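"""Reaction network, Gibbs energies under conditions, coupling, potentials."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syntropyr import thermo
from syntropyr.thermo import ConditionSet, Constants, R_KJ


@pytest.mark.parametrize(
    "eq, dg0",
    [("eq1", -69.5), ("eq2", -41.0), ("eq3", -164.0), ("eq4", -131.0),
     ("eq5", -295.0), ("eq6", +28.0)],
)
def test_standard_reaction_energies(reactions, eq, dg0):
    assert reactions[eq].dg0_prime == pytest.approx(dg0)


def test_h2s_pathway_range_stored_with_midpoint(reactions):
    eq1 = reactions["eq1"]
    assert eq1.dg0_prime_range == (-75.0, -64.0)
    assert eq1.dg0_prime == pytest.approx(sum(eq1.dg0_prime_range) / 2)


@pytest.mark.parametrize("eq", ["eq2", "eq3", "eq4", "eq5"])
def test_iron_and_sulfur_balance(reactions, eq):
    assert reactions[eq].is_balanced(("Fe", "S"))


def test_reaction_validation_rejects_one_sided_stoichiometry():
    with pytest.raises(ValueError):
        thermo.Reaction("bad", {thermo.H2: Fraction(1)}, 0.0)


class TestReactionQuotient:
    def test_standard_state_gives_unity(self, reactions):
        assert thermo.reaction_quotient(reactions["eq6"], ConditionSet()) == pytest.approx(1.0)

    def test_feasibility_conditions(self, reactions, feasibility_conditions):
        # (1e-6 * 1e-4) / 5e-3 by hand
        q = thermo.reaction_quotient(reactions["eq6"], feasibility_conditions)
        assert q == pytest.approx(2e-8)

    def test_h2s_pathway_quotient(self, reactions):
        cond = ConditionSet(activities={"H2": 1e-4, "H2S": 5e-3})
        assert thermo.reaction_quotient(reactions["eq2"], cond) == pytest.approx(0.02)

    def test_solids_and_water_excluded(self, reactions):
        # FeS/FeS2 activities must not alter Q
        cond = ConditionSet(activities={"H2": 0.5, "H2S": 0.1, "FeS": 42.0})
        base = ConditionSet(activities={"H2": 0.5, "H2S": 0.1})
        assert thermo.reaction_quotient(reactions["eq2"], cond) == pytest.approx(
            thermo.reaction_quotient(reactions["eq2"], base)
        )

    def test_nonpositive_activity_names_species(self, reactions):
        with pytest.raises(ValueError, match="H2S"):
            ConditionSet(activities={"H2S": -1.0})


class TestDeltaG:
    def test_standard_state_returns_dg0(self, reactions):
        for rxn in reactions.values():
            assert thermo.delta_g(rxn, ConditionSet()) == pytest.approx(rxn.dg0_prime)

    def test_sulfide_oxidation_under_syntrophic_conditions(
        self, reactions, feasibility_conditions
    ):
        # oracle: 28 + (8.314e-3 * 298.15) * ln(2e-8)
        expected = 28.0 + R_KJ * 298.15 * math.log(2e-8)
        dg = thermo.delta_g(reactions["eq6"], feasibility_conditions)
        assert dg == pytest.approx(expected, abs=1e-9)
        assert dg == pytest.approx(-15.94, abs=0.01)

    def test_rtlnq_antisymmetric_under_quotient_inversion(self, reactions):
        rxn = reactions["eq2"]
        cond = ConditionSet(activities={"H2": 1e-3, "H2S": 2.0})
        inv = ConditionSet(activities={"H2": 1e3, "H2S": 0.5})
        up = thermo.delta_g(rxn, cond) - rxn.dg0_prime
        down = thermo.delta_g(rxn, inv) - rxn.dg0_prime
        assert up == pytest.approx(-down)

    def test_doubling_formula_unit_doubles_delta_g(self, reactions):
        rxn = reactions["eq2"]
        cond = ConditionSet(activities={"H2": 1e-4, "H2S": 5e-3})
        assert thermo.delta_g(rxn.scaled(2), cond) == pytest.approx(
            2 * thermo.delta_g(rxn, cond)
        )


class TestCouple:
    def test_four_fold_h2s_pathway(self, reactions):
        quad = thermo.couple([(reactions["eq2"], 4)])
        assert quad.dg0_prime == pytest.approx(-164.0)
        assert quad.stoichiometry[thermo.H2] == Fraction(4)

    def test_syntrophic_net_reaction_cancels_hydrogen(self, reactions):
        net = thermo.couple([(reactions["eq2"], 4), (reactions["eq4"], 1)])
        assert net.dg0_prime == pytest.approx(-295.0)
        names = {sp.name: nu for sp, nu in net.stoichiometry.items()}
        assert "H2" not in names  # exact rational cancellation
        assert names == {
            "FeS": Fraction(-4), "H2S": Fraction(-4), "CO2": Fraction(-1),
            "FeS2": Fraction(4), "CH4": Fraction(1), "H2O": Fraction(2),
        }
        assert net.is_balanced(("Fe", "S"))

    def test_identity_coupling(self, reactions):
        out = thermo.couple([(reactions["eq2"], 1)])
        assert out.dg0_prime == reactions["eq2"].dg0_prime
        assert out.stoichiometry == dict(reactions["eq2"].stoichiometry)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            thermo.couple([])

    @given(m1=st.integers(1, 6), m2=st.integers(1, 6))
    @settings(derandomize=True, max_examples=25)
    def test_linearity_of_coupled_energies(self, m1, m2):
        rxns = thermo.standard_reactions()
        net = thermo.couple([(rxns["eq2"], m1), (rxns["eq4"], m2)])
        assert net.dg0_prime == pytest.approx(
            m1 * rxns["eq2"].dg0_prime + m2 * rxns["eq4"].dg0_prime
        )


class TestCriticalActivity:
    def test_hydrogen_window_for_sulfide_oxidation(self, reactions):
        cond = ConditionSet(activities={"H2S": 5e-3, "[S0]": 1e-6})
        # oracle: exp((-11 - 28)/RT) * (5e-3 / 1e-6)
        expected = math.exp((-11.0 - 28.0) / (R_KJ * 298.15)) * (5e-3 / 1e-6)
        a = thermo.critical_activity(reactions["eq6"], cond, "H2", -11.0)
        assert a == pytest.approx(expected)
        assert a == pytest.approx(7.3e-4, rel=0.01)

    def test_standard_state_threshold_gives_unit_activity(self, reactions):
        rxn = reactions["eq6"]
        a = thermo.critical_activity(rxn, ConditionSet(), "H2", rxn.dg0_prime)
        assert a == pytest.approx(1.0)

    def test_zero_coefficient_rejected(self, reactions):
        with pytest.raises((ValueError, KeyError)):
            thermo.critical_activity(reactions["eq6"], ConditionSet(), "CH4", -11.0)

    @given(
        h2s=st.floats(1e-6, 1.0), s0=st.floats(1e-9, 1e-3),
        thr=st.floats(-50.0, 10.0), temp=st.floats(275.0, 340.0),
    )
    @settings(derandomize=True, max_examples=250)
    def test_inversion_round_trip(self, h2s, s0, thr, temp):
        rxn = thermo.standard_reactions()["eq6"]
        cond = ConditionSet(temperature=temp, activities={"H2S": h2s, "[S0]": s0})
        a = thermo.critical_activity(rxn, cond, "H2", thr)
        assert thermo.delta_g(rxn, cond.with_activity("H2", a)) == pytest.approx(
            thr, abs=1e-9
        )


class TestCouplePotential:
    def test_pyrite_couple_matches_minus_620_mv(self, reactions):
        e = thermo.couple_potential(reactions["eq2"], 2)
        assert e == pytest.approx(-626.5, abs=0.5)
        assert e == pytest.approx(-620.0, rel=0.02)  # two significant figures

    def test_zero_energy_returns_hydrogen_reference(self, reactions):
        rxn = thermo.Reaction(
            "h2_ref", {thermo.H2S: Fraction(-1), thermo.S0: Fraction(1),
                       thermo.H2: Fraction(1)}, 0.0
        )
        assert thermo.couple_potential(rxn, 2) == Constants().E0_H2_pH7

    def test_reference_override(self, reactions):
        e = thermo.couple_potential(reactions["eq2"], 2, Constants(E0_H2_pH7=-410.0))
        assert e == pytest.approx(-410.0 - 41.0e6 / (2 * 96485.0) / 1e3 * 1e3, abs=0.1)
        assert e == pytest.approx(-622.5, abs=0.1)

    def test_invalid_electron_count(self, reactions):
        with pytest.raises(ValueError):
            thermo.couple_potential(reactions["eq2"], 0)
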