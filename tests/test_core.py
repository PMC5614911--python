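"""Reaction data model, propensity contract, validation, overrides."""

import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

from myomirnet.core import (
    NetworkConfigError,
    ParameterSet,
    Reaction,
    ReactionNetwork,
    Species,
    apply_overrides,
    propensity,
    validate_network,
)
from myomirnet.models import get_model


def _rxn(reactants, products=(), rate="k"):
    return Reaction("r", tuple(reactants), tuple(products), rate)


class TestPropensity:
    @pytest.mark.parametrize(
        "reactants,state,k,expected",
        [
            # zeroth order: constant synthesis flux (caption-printed rate)
            ((), {}, 0.08, 0.08),
            # empty substrate: first order with zero copies
            (("X",), {"X": 0}, 0.1, 0.0),
            # second order, distinct species, hand multiplication
            (("A", "B"), {"A": 10, "B": 5}, 2e-4, 1e-2),
            (("X",), {"X": 7}, 0.5, 3.5),
        ],
    )
    def test_mass_action_orders(self, reactants, state, k, expected):
        r = _rxn(reactants)
        assert propensity(r, state, {"k": k}) == pytest.approx(expected)

    def test_second_order_matches_symbolic_evaluation(self):
        """Cross-check k*x*y against an independent symbolic product."""
        k, x, y = sympy.symbols("k x y", positive=True)
        expr = k * x * y
        subs = {k: 2e-4, x: 10, y: 5}
        r = _rxn(("A", "B"))
        assert propensity(r, {"A": 10, "B": 5}, {"k": 2e-4}) == pytest.approx(
            float(expr.subs(subs))
        )

    def test_homodimer_convention(self):
        """2X -> ... uses k*x*(x-1)/2 (distinct-pair counting)."""
        r = _rxn(("X", "X"))
        assert propensity(r, {"X": 10}, {"k": 2.0}) == pytest.approx(90.0)
        assert propensity(r, {"X": 1}, {"k": 2.0}) == 0.0

    def test_unknown_parameter_is_configuration_error(self):
        with pytest.raises(NetworkConfigError, match="unknown parameter"):
            propensity(_rxn(("X",), rate="missing"), {"X": 1}, {"k": 1.0})

    def test_three_reactants_is_structural_error(self):
        r = Reaction("bad", ("A", "B", "C"), (), "k")
        with pytest.raises(NetworkConfigError, match="at most 2"):
            propensity(r, {"A": 1, "B": 1, "C": 1}, {"k": 1.0})

    @settings(derandomize=True, max_examples=60)
    @given(
        k=st.floats(1e-8, 1e2),
        x=st.integers(0, 10_000),
        y=st.integers(0, 10_000),
        c=st.integers(2, 7),
    )
    def test_linearity_in_count_and_rate(self, k, x, y, c):
        """Propensity is linear in each reactant count and in k."""
        r = _rxn(("A", "B"))
        p = propensity(r, {"A": x, "B": y}, {"k": k})
        assert propensity(r, {"A": c * x, "B": y}, {"k": k}) == pytest.approx(
            c * p
        )
        assert propensity(r, {"A": x, "B": y}, {"k": c * k}) == pytest.approx(
            c * p
        )


class TestValidateNetwork:
    def test_builder_outputs_are_clean(self, all_model_keys):
        for key in all_model_keys:
            assert validate_network(get_model(key)) == []

    def test_missing_species_named_in_issue(self, birth_death):
        net = birth_death.copy()
        net.add_reaction("bad", ["Q"], [], "a")
        issues = validate_network(net)
        assert len(issues) == 1 and "'Q'" in issues[0]

    def test_three_reactant_reaction_cites_order_limit(self, birth_death):
        net = birth_death.copy()
        net.reactions.append(Reaction("tri", ("X", "X", "X"), (), "a"))
        issues = validate_network(net)
        assert any("order limit" in i for i in issues)

    def test_unresolved_parameter_reported(self, birth_death):
        net = birth_death.copy()
        net.add_reaction("bad", ["X"], [], "nope")
        assert any("nope" in i for i in validate_network(net))

    def test_overlapping_conserved_groups_reported(self, gene_toggle):
        net = gene_toggle.copy()
        net.add_conserved("G_bound")
        assert any("disjoint" in i for i in validate_network(net))

    def test_gene_group_must_hold_single_copy(self, gene_toggle):
        net = gene_toggle.copy()
        sp = net.species[0]
        net.species[0] = Species(sp.id, sp.description, 2, sp.is_gene_state)
        assert any("expected 1" in i for i in validate_network(net))

    def test_idempotent_and_side_effect_free(self, birth_death):
        net = birth_death.copy()
        net.add_reaction("bad", ["Q"], [], "a")
        first = validate_network(net)
        second = validate_network(net)
        assert first == second

    def test_negative_initial_amount_rejected_at_construction(self):
        with pytest.raises(NetworkConfigError):
            Species("X", initial_amount=-1)


class TestApplyOverrides:
    HIGH_PAX3 = {
        "Pax3": 1000, "Pax3_mRNA": 400,
        "k_synPax3": 6.0e-5, "k_synPax3mRNA": 0.08,
    }

    def test_high_pax3_caption_values(self):
        net = apply_overrides(get_model("mir1"), self.HIGH_PAX3)
        assert net.get_species("Pax3").initial_amount == 1000
        assert net.get_species("Pax3_mRNA").initial_amount == 400
        assert net.parameters["k_synPax3"] == 6.0e-5
        assert net.parameters["k_synPax3mRNA"] == 0.08

    def test_high_mir181_caption_values(self):
        net = apply_overrides(
            get_model("mir181"), {"miR181": 1000, "k_synmiR181": 6e-4}
        )
        assert net.get_species("miR181").initial_amount == 1000
        assert net.parameters["k_synmiR181"] == 6e-4

    def test_empty_overrides_is_structural_identity(self):
        base = get_model("mir1")
        copy = apply_overrides(base, {})
        assert dict(copy.parameters) == dict(base.parameters)
        assert copy.initial_state() == base.initial_state()
        assert copy is not base

    def test_original_untouched_deep_copy(self):
        base = get_model("mir1")
        before = dict(base.parameters)
        apply_overrides(base, {"k_synPax3": 99.0})
        assert dict(base.parameters) == before

    def test_inverse_override_recovers_original_exactly(self):
        base = get_model("mir1")
        fwd = apply_overrides(base, self.HIGH_PAX3)
        inverse = {
            "Pax3": base.get_species("Pax3").initial_amount,
            "Pax3_mRNA": base.get_species("Pax3_mRNA").initial_amount,
            "k_synPax3": base.parameters["k_synPax3"],
            "k_synPax3mRNA": base.parameters["k_synPax3mRNA"],
        }
        back = apply_overrides(fwd, inverse)
        assert dict(back.parameters) == dict(base.parameters)
        assert back.initial_state() == base.initial_state()

    def test_unknown_key_lists_the_key(self):
        with pytest.raises(NetworkConfigError, match="k_bogus"):
            apply_overrides(get_model("mir1"), {"k_bogus": 1.0})


def test_parameter_set_require():
    p = ParameterSet({"k": 1.0})
    assert p.require("k") == 1.0
    with pytest.raises(NetworkConfigError):
        p.require("absent")
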