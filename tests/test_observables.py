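"""Derived observables: fractions, half-lives, steady states,
sensitivities, and the balanced-rescaling invariance."""

import numpy as np
import pytest

import foxosim as fx
from conftest import make_single_species_network, make_two_state_network
from foxosim.network import Counter, Reaction, ReactionNetwork
from foxosim.observables import SteadyStateError


def _ode(net, t_end, record_every=1.0):
    return fx.simulate_ode(net, fx.SimulationSettings(t_end=t_end,
                                                      record_every=record_every))


class TestLocalizationFractions:
    def test_all_cytoplasmic_at_t0(self, default_network):
        traj = _ode(default_network, 1, 1)
        fr = fx.localization_fractions(traj, 0.0)
        assert fr["cytoplasm"] == 1.0
        assert fr["nucleus"] == fr["dna_bound"] == 0.0
        assert fr["total_nuclear"] == 0.0

    def test_fractions_sum_to_one_along_trajectory(self):
        net = fx.build_network(fx.single_ptm_baseline(Akt=1e4).without_genes())
        traj = _ode(net, 60, 10)
        for t in traj.times:
            fr = fx.localization_fractions(traj, t)
            assert fr["cytoplasm"] + fr["nucleus"] + fr["dna_bound"] \
                == pytest.approx(1.0)
            assert fr["total_nuclear"] == pytest.approx(
                fr["nucleus"] + fr["dna_bound"])

    def test_basal_steady_state_partition(self):
        """Transport chain 0.182/0.055 and 0.25/0.125 puts ~9% in the
        cytoplasm and splits nuclear protein 1:2 free:DNA-bound."""
        net = fx.build_network(fx.single_ptm_baseline().without_genes())
        ss = fx.steady_state(net)
        vals = net.counter_values(ss)
        total = float(vals["total_foxo"])
        cyt = float(vals["total_cytoplasm"]) / total
        nuc = float(vals["total_nucleus"]) / total
        dna = float(vals["total_dna_bound"]) / total
        assert dna / (dna + nuc) == pytest.approx(2 / 3, abs=1e-4)
        assert (cyt, nuc, dna) == pytest.approx((0.092, 0.303, 0.605),
                                                abs=0.005)

    def test_zero_total_protein_is_an_error(self):
        net = make_single_species_network(k_decay=0.0, initial=0.0)
        net.counters = [
            Counter("total_foxo", frozenset(["X"])),
            Counter("total_cytoplasm", frozenset(["X"])),
            Counter("total_nucleus", frozenset()),
            Counter("total_dna_bound", frozenset()),
            Counter("total_nuclear", frozenset()),
        ]
        traj = _ode(net, 1, 1)
        with pytest.raises(ValueError, match="undefined"):
            fx.localization_fractions(traj, 0.0)


class TestPtmFraction:
    def test_no_enzymes_means_no_modification(self):
        net = fx.build_network(
            fx.single_ptm_baseline(SCF_MDM2=0).without_genes())
        traj = _ode(net, 100, 50)
        for flag in net.flag_order:
            assert fx.ptm_fraction(traj, flag, 100.0) == 0.0

    def test_kinase_fraction_near_equilibrium_value(self):
        """Akt=1e5 vs PP2A=1e4: k'a/k'b = 10, so ~91% carries the mark."""
        net = fx.build_network(
            fx.single_ptm_baseline(Akt=1e5, E2F1=0, SCF_MDM2=0).without_genes())
        traj = _ode(net, 200, 100)
        assert fx.ptm_fraction(traj, "Pa", 200.0) == pytest.approx(10 / 11,
                                                                   abs=0.01)

    def test_fraction_bounded(self):
        net = fx.build_network(fx.single_ptm_baseline(Akt=1e5).without_genes())
        traj = _ode(net, 50, 10)
        for t in traj.times[1:]:
            assert 0.0 <= fx.ptm_fraction(traj, "Pa", t) <= 1.0


class TestHalfLife:
    def test_pure_exponential_recovers_ln2_over_k(self):
        net = make_single_species_network(k_decay=0.1)
        traj = _ode(net, 20, 0.5)
        assert fx.time_to_half_initial(traj, "X") \
            == pytest.approx(np.log(2) / 0.1, rel=0.01)

    @pytest.mark.parametrize("k", [1e-4, 1e-3, 1e-2, 1e-1, 1.0])
    def test_recovery_across_rate_scales(self, k):
        net = make_single_species_network(k_decay=k)
        t_end = 2 * np.log(2) / k
        traj = _ode(net, t_end, t_end / 400)
        assert fx.time_to_half_initial(traj, "X") \
            == pytest.approx(np.log(2) / k, rel=0.01)

    def test_decay_to_nonzero_floor_is_longer_than_ln2_over_k(self):
        """212 + 788 e^-kt with k=2.6e-3 halves at ~388 min, not 267."""
        k = 2.6e-3
        # birth 212k and decay k from 1000 gives X(t) = 212 + 788 e^-kt
        net2 = make_single_species_network(k_decay=k, initial=1000,
                                           k_birth=212 * k)
        traj2 = _ode(net2, 800, 1)
        expected = -np.log((500 - 212) / 788) / k
        assert fx.time_to_half_initial(traj2, "X") \
            == pytest.approx(expected, rel=0.01)
        assert expected > np.log(2) / k

    def test_increasing_observable_returns_none(self):
        net = make_single_species_network(k_decay=0.0, initial=10,
                                          k_birth=5.0)
        traj = _ode(net, 50, 1)
        assert fx.time_to_half_initial(traj, "X") is None

    def test_nonpositive_initial_is_an_error(self):
        net = make_single_species_network(k_decay=0.1, initial=0.0)
        traj = _ode(net, 10, 1)
        with pytest.raises(ValueError, match="initial"):
            fx.time_to_half_initial(traj, "X")


class TestSteadyState:
    def test_symmetric_exchange_splits_equally(self):
        net = make_two_state_network(k_fwd=0.2, k_back=0.2, initial_a=1000)
        ss = fx.steady_state(net, t_start=100)
        assert ss == pytest.approx([500.0, 500.0], rel=1e-5)

    def test_birth_death_count_is_influx_over_k(self):
        net = make_single_species_network(k_decay=0.05, initial=0,
                                          k_birth=10.0)
        ss = fx.steady_state(net, t_start=100)
        assert ss[0] == pytest.approx(10.0 / 0.05, rel=1e-6)

    def test_basal_total_nuclear_fraction(self):
        net = fx.build_network(fx.single_ptm_baseline().without_genes())
        ss = fx.steady_state(net)
        vals = net.counter_values(ss)
        frac = float(vals["total_nuclear"]) / float(vals["total_foxo"])
        assert frac == pytest.approx(0.908, abs=0.005)

    def test_integration_matches_direct_linear_solve(self):
        """Independent oracle: sparse solve of the affine system."""
        net = fx.build_network(fx.single_ptm_baseline(Akt=1e4, CBP=500))
        x_int = fx.steady_state(net)
        x_solve = fx.linear_steady_state(net)
        assert np.max(np.abs(x_int - x_solve) / (1 + np.abs(x_solve))) < 1e-4

    def test_unbounded_growth_raises(self):
        net = fx.build_network(
            fx.single_ptm_baseline(Akt=1e5, Proteasome=0, SCF_MDM2=0)
            .without_genes())
        with pytest.raises(SteadyStateError, match="steady state"):
            fx.steady_state(net, t_start=500, t_cap=1e4)


class TestScaledSensitivities:
    def test_birth_death_elasticities_are_plus_minus_one(self):
        """At steady state X = k_in/k_out: dlnX/dlnk_in = 1, /dlnk_out = -1."""
        net = make_single_species_network(k_decay=0.05, initial=200,
                                          k_birth=10.0)
        recs = fx.scaled_sensitivities(net, ["synthesis", "degradation"],
                                       ["X"], time=2000.0)
        by_param = {r.parameter: r.scaled_sensitivity for r in recs}
        assert by_param["synthesis"] == pytest.approx(1.0, abs=1e-3)
        assert by_param["degradation"] == pytest.approx(-1.0, abs=1e-3)

    def test_zero_flux_parameter_has_zero_sensitivity(self):
        net = make_single_species_network(k_decay=0.01, initial=500,
                                          enzyme="E", enzyme_count=0.0,
                                          k_birth=1.0)
        recs = fx.scaled_sensitivities(net, ["E"], ["X"], time=100.0)
        assert recs[0].scaled_sensitivity == pytest.approx(0.0, abs=1e-9)

    def test_undefined_below_floor(self):
        net = make_single_species_network(k_decay=1.0, initial=0.0)
        recs = fx.scaled_sensitivities(net, ["degradation"], ["X"], time=10.0)
        assert recs[0].scaled_sensitivity is None

    def test_transport_sensitivities_bounded_by_one(self):
        """High-Akt regime: transport elasticities of FOXO observables
        have magnitude up to ~1, not more."""
        net = fx.build_network(
            fx.single_ptm_baseline(Akt=1e5).without_genes())
        recs = fx.scaled_sensitivities(
            net, ["transport"], ["total_foxo", "total_nuclear"], time=360.0)
        for r in recs:
            assert abs(r.scaled_sensitivity) <= 1.1


class TestBalancedRescaling:
    @staticmethod
    def _observables(scale):
        cfg = fx.single_ptm_baseline(Akt=1e5)
        pa = cfg.ptm_by_id()["Pa"]
        pa.k_add *= scale
        pa.k_remove *= scale
        net = fx.build_network(cfg)
        ss = fx.steady_state(net)
        v = net.counter_values(ss)
        i = net.species_index()["SOD2_mrna_nuc"]
        return np.array([float(v["total_cytoplasm"]),
                         float(v["total_nuclear"]),
                         float(v["total_foxo"]), ss[i]])

    def test_kinase_phosphatase_rescaling_leaves_steady_state(self):
        """Multiplying k_add and k_remove of a PTM pair by the same factor
        leaves steady-state localization and transcription (nearly)
        unchanged: the invariance is exact only in the limit where
        modification is fast against transport and turnover, so a small
        residual remains and shrinks as the pair is scaled further up."""
        base = self._observables(1.0)
        up5 = self._observables(5.0)
        up25 = self._observables(25.0)
        dev5 = np.abs(up5 / base - 1)
        dev25 = np.abs(up25 / up5 - 1)
        assert np.all(dev5 < 0.05)
        assert np.all(dev25 <= dev5 + 1e-6)
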