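"""Species enumeration, multiplicative-factor composition and reaction
generation."""

from collections import Counter as TallyCounter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import foxosim as fx
from foxosim.config import PROCESSES, ConfigError
from foxosim.network import species_count

ALL_FLAGS = ("Pa", "Pb", "Pc", "Pd", "Pe", "Ac", "mUb", "pUb")


class TestEnumeration:
    def test_default_model_has_768_protein_species(self, default_network):
        assert default_network.n_protein_species == 768

    @pytest.mark.parametrize("kept,expected", [
        (["Pa"], 6), (["Pa", "Ac"], 12), (list(ALL_FLAGS), 768),
    ])
    def test_species_count_is_3_times_2_to_n(self, default_config, kept,
                                             expected):
        cfg = default_config.restrict_ptms(kept)
        assert len(fx.enumerate_species(cfg)) == expected

    def test_zero_ptm_classes_gives_three_species(self, default_config):
        cfg = default_config.restrict_ptms([])
        ids = [s.id for s in fx.enumerate_species(cfg)]
        assert ids == ["FOXO_cytoplasm", "FOXO_nucleus", "FOXO_dna_bound"]

    def test_blowup_guard_at_27_classes(self, default_config):
        cfg = fx.default_foxo_config()
        for i in range(19):  # 8 + 19 = 27 classes
            cfg.ptm_classes.append(fx.PTMClass(f"X{i}", "Akt", 1e-5))
        with pytest.raises(ConfigError, match="refusing"):
            fx.enumerate_species(cfg)
        # closed form still reports the would-be count (~1e8 species)
        assert species_count(27) == 402_653_184

    def test_canonical_ids_are_injective(self, default_network):
        assert len(set(default_network.species)) == len(default_network.species)

    def test_flags_appear_in_fixed_order_in_ids(self, default_config):
        states = fx.enumerate_species(default_config)
        full = [s for s in states if len(s.ptm_flags) == 8
                and s.compartment == "cytoplasm"]
        assert full[0].id == "FOXO_Pa_Pb_Pc_Pd_Pe_Ac_mUb_pUb_cytoplasm"


class TestEffectiveRate:
    @pytest.mark.parametrize("process,base,flags,expected", [
        ("polyub", 1e-3, {"Pa"}, 3e-3),
        ("nuc_to_cyt", 0.055, set(), 0.055),
        ("nuc_to_cyt", 0.055, {"Pa", "Pe"}, 0.055),  # JNK cancels Akt exactly
        ("polyub", 1e-3, {"Pa", "Pd", "Ac"}, 5.94e-4),
        ("cyt_to_nuc", 0.182, {"Pa"}, 0.0182),
    ])
    def test_composition(self, default_config, process, base, flags, expected):
        assert fx.effective_rate(process, base, flags, default_config) \
            == pytest.approx(expected)

    def test_unknown_process_rejected(self, default_config):
        with pytest.raises(ConfigError, match="process"):
            fx.effective_rate("teleport", 1.0, set(), default_config)

    @given(flags=st.sets(st.sampled_from(ALL_FLAGS)),
           process=st.sampled_from(PROCESSES),
           base=st.floats(1e-6, 10.0))
    def test_commutative_product_with_identity(self, flags, process, base):
        """MF composition is order-independent and empty-set neutral."""
        cfg = fx.default_foxo_config()
        rate = fx.effective_rate(process, base, flags, cfg)
        for ordering in (sorted(flags), sorted(flags, reverse=True)):
            assert fx.effective_rate(process, base, ordering, cfg) \
                == pytest.approx(rate)
        expected = base
        for f in flags:
            expected *= cfg.ptm_by_id()[f].mf_for(process)
        assert rate == pytest.approx(expected)
        assert fx.effective_rate(process, base, [], cfg) == base


class TestBuildNetwork:
    def test_pa_only_toy_reaction_census(self, pa_only_network):
        tally = TallyCounter(r.kind for r in pa_only_network.reactions)
        assert tally == {"ptm_add": 3, "ptm_remove": 3, "transport": 8,
                         "synthesis": 1}
        assert len(pa_only_network.reactions) == 15

    def test_exactly_one_synthesis_of_unmodified_cytoplasmic(self,
                                                             default_network):
        syn = [r for r in default_network.reactions if r.kind == "synthesis"]
        assert len(syn) == 1
        assert syn[0].reactants == ()
        assert syn[0].products == ("FOXO_cytoplasm",)
        assert syn[0].enzyme == "E2F1"

    def test_ptm_interconversion_out_degree_at_most_nine(self, default_network):
        out_degree = TallyCounter()
        for r in default_network.reactions:
            if r.kind in ("ptm_add", "ptm_remove", "polyub"):
                out_degree[r.reactants[0]] += 1
        assert max(out_degree.values()) <= 9
        # compartment permissions (Ac nuclear-only, pUb cytoplasm-only)
        # keep the realized maximum at 7 single-flag changes
        assert max(out_degree.values()) == 7

    def test_pub_species_only_await_degradation(self, default_network):
        pub_species = {s for s, flags in default_network.species_flags.items()
                       if "pUb" in flags}
        for r in default_network.reactions:
            if r.reactants and r.reactants[0] in pub_species:
                assert r.kind == "degradation"
                assert default_network.species_compartment[r.reactants[0]] \
                    == "cytoplasm"

    def test_degradation_and_polyub_cytoplasm_only(self, default_network):
        for r in default_network.reactions:
            if r.kind in ("degradation", "polyub"):
                comp = default_network.species_compartment[r.reactants[0]]
                assert comp == "cytoplasm"

    def test_acetylation_absent_from_cytoplasm(self, default_network):
        for r in default_network.reactions:
            if r.kind in ("ptm_add", "ptm_remove") and r.enzyme in ("CBP",
                                                                    "SIRT"):
                comp = default_network.species_compartment[r.reactants[0]]
                assert comp in ("nucleus", "dna_bound")

    def test_construction_is_deterministic(self, default_config):
        n1 = fx.build_network(default_config)
        n2 = fx.build_network(default_config)
        assert n1.species_table() == n2.species_table()
        assert n1.reaction_table() == n2.reaction_table()

    def test_conservative_subnetwork_stoichiometry(self, default_config):
        """With synthesis/polyub/degradation removed, every remaining
        reaction conserves total protein."""
        net = fx.build_network(default_config.without_genes())
        protein = set(net.species[:net.n_protein_species])
        for r in net.reactions:
            if r.kind in ("synthesis", "polyub", "degradation"):
                continue
            assert sum(s in protein for s in r.products) == \
                sum(s in protein for s in r.reactants)


class TestCounters:
    def test_total_ac_has_384_members(self, default_network):
        c = default_network.counter_by_name()["total_Ac"]
        assert len(c.member_species) == 384  # 2^7 x 3 compartments

    def test_zero_ptm_network_counters(self, default_config):
        net = fx.build_network(default_config.restrict_ptms([]).without_genes())
        names = set(net.counter_by_name())
        assert "total_Pa" not in names
        for comp in ("cytoplasm", "nucleus", "dna_bound"):
            assert len(net.counter_by_name()[f"total_{comp}"].member_species) \
                == 1

    def test_counter_equals_brute_force_member_sum(self, pa_only_network):
        settings = fx.SimulationSettings(t_end=30, record_every=1, seed=3,
                                         method="ssa")
        traj = fx.simulate_ssa(pa_only_network, settings)
        idx = pa_only_network.species_index()
        for c in pa_only_network.counters:
            members = [idx[s] for s in c.member_species]
            brute = traj.counts[:, members].sum(axis=1)
            assert np.array_equal(traj.counter(c.name), brute)

    def test_counters_never_react(self, default_network):
        counter_names = set(default_network.counter_by_name())
        for r in default_network.reactions:
            assert not counter_names & set(r.reactants + r.products)


class TestStimulatedTranscription:
    def _state(self, network, **counts):
        state = dict.fromkeys(network.species, 0.0)
        state.update(counts)
        return state

    def test_unmodified_dna_bound(self, default_network):
        state = self._state(default_network, FOXO_dna_bound=600)
        assert fx.stimulated_transcription_rate(default_network, state,
                                                gene="SOD2") \
            == pytest.approx(0.3 * 600)

    def test_empty_dna_gives_basal_only(self, default_network):
        state = self._state(default_network)
        assert fx.stimulated_transcription_rate(default_network, state,
                                                gene="SOD2") == 0.0
        assert fx.stimulated_transcription_rate(
            default_network, state, gene="SOD2", include_basal=True) \
            == pytest.approx(3.0)

    def test_pc_doubles_transcription(self, default_network):
        state = self._state(default_network, FOXO_Pc_dna_bound=100)
        assert fx.stimulated_transcription_rate(default_network, state,
                                                gene="SOD2") \
            == pytest.approx(0.3 * 2.0 * 100)
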