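"""Model library: structure, mechanisms, catalog, integrated consistency."""

import numpy as np
import pytest

from myomirnet.engines import simulate_ode
from myomirnet.models import (
    INTEGRATED_ADDED_GENE_STATES,
    MODEL_CATALOG,
    build_integrated_model,
    get_model,
    integrated_structure_diff,
    reaction_table,
    reduce_integrated,
)
from myomirnet.core import NetworkConfigError, validate_network

DAY = 86400.0


def _reaction_set(net):
    return {
        (r.id, tuple(sorted(r.reactants)), tuple(sorted(r.products)),
         r.rate_constant_name)
        for r in net.reactions
    }


class TestCatalog:
    def test_keys_and_biomodels_ids(self):
        assert sorted(MODEL_CATALOG) == [
            "integrated", "mir1", "mir143", "mir181", "mir378",
        ]
        ids = {e.biomodels_id for e in MODEL_CATALOG.values()}
        assert ids == {f"MODEL170411000{i}" for i in range(5)}

    def test_every_builder_validates(self, all_model_keys):
        for key in all_model_keys:
            net = get_model(key)
            assert validate_network(net) == []

    def test_gene_state_groups_start_at_one_copy(self, all_model_keys):
        for key in all_model_keys:
            net = get_model(key)
            init = net.initial_state()
            gene_ids = {s.id for s in net.species if s.is_gene_state}
            for group in net.conserved_groups:
                if group <= gene_ids:
                    assert sum(init[s] for s in group) == 1

    def test_unknown_key_lists_known(self):
        with pytest.raises(NetworkConfigError, match="mir378"):
            get_model("nope")

    def test_reaction_table_is_documented(self, all_model_keys):
        for key in all_model_keys:
            tab = reaction_table(get_model(key))
            assert list(tab.columns) == [
                "reaction", "reactants", "products", "rate_constant",
                "value", "note",
            ]
            assert len(tab) == len(get_model(key).reactions)


class TestMir1Mechanisms:
    def test_bound_transcript_is_translated(self):
        """The miR-1:Pax3-mRNA complex must still produce Pax3 protein."""
        net = get_model("mir1")
        translating = [
            r for r in net.reactions
            if r.reactants == ("miR1_Pax3_mRNA",)
            and "Pax3" in r.products and "miR1_Pax3_mRNA" in r.products
        ]
        assert len(translating) == 1
        # and at the same rate constant as free-transcript translation
        free = [r for r in net.reactions if r.id == "Pax3_translation"]
        assert translating[0].rate_constant_name == free[0].rate_constant_name

    def test_enhanced_decay_recycles_mir1(self):
        net = get_model("mir1")
        (decay,) = [
            r for r in net.reactions if r.id == "Pax3_mRNA_enhanced_decay"
        ]
        assert decay.products == ("miR1",)
        assert (
            net.parameters[decay.rate_constant_name]
            > net.parameters["k_degPax3mRNA"]
        )

    def test_basal_mir1_synthesis_is_myod_independent(self):
        net = get_model("mir1")
        (basal,) = [
            r for r in net.reactions if r.id == "miR1_synthesis_basal"
        ]
        assert basal.reactants == ()
        assert basal.rate_constant_name == "k_synmiR1"


class TestMir181Mechanisms:
    def test_bound_transcripts_cannot_translate(self):
        net = get_model("mir181")
        for complex_id in ("miR181_HoxA11_mRNA", "miR181_Sirt1_mRNA"):
            assert not any(
                complex_id in r.reactants
                and any(p in ("HoxA11", "Sirt1") for p in r.products)
                for r in net.reactions
            )

    def test_complex_decay_rate_equals_free_mrna_rate(self):
        """"Does not enhance degradation": same constant, miRNA recycled."""
        net = get_model("mir181")
        for gene in ("HoxA11", "Sirt1"):
            (cdecay,) = [
                r for r in net.reactions
                if r.id == f"miR181_{gene}_mRNA_decay"
            ]
            assert cdecay.rate_constant_name == f"k_deg{gene}mRNA"
            assert cdecay.products == ("miR181",)


class TestMir378Mechanisms:
    def test_three_state_gene_is_mutually_exclusive(self):
        net = get_model("mir378")
        # no reaction converts the MyoD-bound state into the Msc-bound one
        for r in net.reactions:
            assert not (
                "miR378_gene_MyoD" in r.reactants
                and "miR378_gene_Msc" in r.products
            )
        # synthesis only from the MyoD-bound state
        producing = [
            r for r in net.reactions
            if "miR378" in r.products and r.id == "miR378_synthesis"
        ]
        assert producing[0].reactants == ("miR378_gene_MyoD",)


class TestMir143Mechanisms:
    def test_il6_silences_and_mir143_uses_both_mechanisms(self):
        net = get_model("mir143")
        # no transcription from the IL-6-bound promoter
        assert not any(
            "miR143_gene_IL6" in r.reactants and "miR143" in r.products
            for r in net.reactions
        )
        # enhanced complex decay, faster than basal, recycling miR-143
        (cdecay,) = [
            r for r in net.reactions if r.id == "Igfbp5_mRNA_enhanced_decay"
        ]
        assert cdecay.products == ("miR143",)
        assert (
            net.parameters[cdecay.rate_constant_name]
            > net.parameters["k_degIgfbp5mRNA"]
        )
        # translation block: complex never produces Igfbp5
        assert not any(
            "miR143_Igfbp5_mRNA" in r.reactants and "Igfbp5" in r.products
            for r in net.reactions
        )

    def test_direct_igf2_route_is_slower_than_carrier_route(self):
        net = get_model("mir143")
        assert (
            net.parameters["k_actIGF1Rdirect"] < net.parameters["k_actIGF1R"]
        )


class TestIntegrated:
    def test_species_union_plus_declared_gene_states(self):
        missing, added = integrated_structure_diff()
        assert missing == set()
        assert added == set(INTEGRATED_ADDED_GENE_STATES)

    def test_single_shared_myod(self):
        net = build_integrated_model()
        assert net.species_ids.count("MyoD") == 1
        # MyoD synthesis only from the doubly-free gene
        producing = [r for r in net.reactions if "MyoD" in r.products
                     and not r.reactants]
        assert producing == []  # no constitutive source
        (syn,) = [r for r in net.reactions if r.id == "MyoD_synthesis"]
        assert syn.reactants == ("MyoD_gene",)

    def test_mir143_transcription_needs_myod_and_free_il6_site(self):
        net = build_integrated_model()
        (syn,) = [r for r in net.reactions if r.id == "miR143_synthesis"]
        assert syn.reactants == ("miR143_gene_MyoD",)

    @pytest.mark.parametrize("key", ["mir1", "mir181", "mir378", "mir143"])
    def test_reduction_recovers_submodel_structure(self, key):
        sub = get_model(key)
        red = reduce_integrated(key)
        assert _reaction_set(red) == _reaction_set(sub)
        assert dict(red.parameters) == dict(sub.parameters)
        assert red.initial_state() == sub.initial_state()

    @pytest.mark.parametrize("key", ["mir1", "mir181", "mir378", "mir143"])
    def test_reduction_reproduces_submodel_dynamics(self, key):
        """Severing the couplings recovers each sub-model's trajectory."""
        sub = get_model(key)
        red = reduce_integrated(key)
        a = simulate_ode(sub, 5 * DAY, 101)
        b = simulate_ode(red, 5 * DAY, 101)
        for s in sub.species_ids:
            va, vb = a.values[s], b.values[s]
            assert np.max(np.abs(va - vb) / (np.abs(va) + 1.0)) < 1e-5, s

    def test_conservation_groups_cover_every_gene_state(self):
        net = build_integrated_model()
        gene_ids = {s.id for s in net.species if s.is_gene_state}
        grouped = set().union(*net.conserved_groups)
        assert gene_ids <= grouped
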