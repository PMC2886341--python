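import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import foxosim as fx
from foxosim.network import Counter, Reaction, ReactionNetwork

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_config():
    return fx.default_foxo_config()


@pytest.fixture(scope="session")
def default_network(default_config):
    return fx.build_network(default_config)


@pytest.fixture(scope="session")
def pa_only_network():
    """Pa-only toy: 6 protein species, genes off."""
    cfg = fx.default_foxo_config().restrict_ptms(["Pa"]).without_genes()
    return fx.build_network(cfg)


def make_single_species_network(k_decay: float, initial: float = 1000.0,
                                enzyme: str | None = None,
                                enzyme_count: float = 1.0,
                                k_birth: float = 0.0) -> ReactionNetwork:
    """Minimal birth-death network for closed-form oracles."""
    reactions = []
    if k_decay > 0:
        reactions.append(Reaction("r00000_degradation", "degradation",
                                  ("X",), (), k_decay, enzyme=enzyme))
    if k_birth > 0:
        reactions.append(Reaction("r00001_synthesis", "synthesis",
                                  (), ("X",), k_birth))
    enzymes = {enzyme: enzyme_count} if enzyme else {}
    return ReactionNetwork(
        species=["X"], n_protein_species=1, reactions=reactions,
        enzymes=enzymes, initial_counts=np.array([initial]),
        counters=[Counter("total", frozenset(["X"]))])


def make_two_state_network(k_fwd: float, k_back: float,
                           initial_a: float = 1000.0) -> ReactionNetwork:
    """A <-> B interconversion (pseudo-first-order constants)."""
    reactions = [
        Reaction("r00000_ptm_add", "ptm_add", ("A",), ("B",), k_fwd),
        Reaction("r00001_ptm_remove", "ptm_remove", ("B",), ("A",), k_back),
    ]
    return ReactionNetwork(
        species=["A", "B"], n_protein_species=2, reactions=reactions,
        enzymes={}, initial_counts=np.array([initial_a, 0.0]),
        counters=[Counter("total", frozenset(["A", "B"]))])
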