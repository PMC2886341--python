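"""Expansion of a model configuration into a flat species/reaction network.

Every combination of the enabled PTM flags, in each of the three
compartments, becomes one chemical species; reactions change exactly one
flag (or one compartment) at a time.  Pre-existing flags modulate rates
multiplicatively: the effective rate of a process is its basal rate times
the product of the multiplicative factors (MFs) of the flags present.

Counter variables (total protein, per-PTM totals, per-compartment totals)
are non-reacting observables: sums of subsets of species counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import COMPARTMENTS, PROCESSES, ConfigError, ModelConfig

__all__ = [
    "SpeciesState",
    "Reaction",
    "Counter",
    "ReactionNetwork",
    "enumerate_species",
    "species_count",
    "effective_rate",
    "build_network",
    "add_counters",
    "stimulated_transcription_rate",
]

#: Hard guard against combinatorial blow-up (3 * 2**24 ~ 5e7 species).
MAX_PTM_CLASSES = 24

REACTION_KINDS = (
    "ptm_add", "ptm_remove", "transport", "synthesis", "polyub",
    "degradation", "transcription_basal", "transcription_stimulated",
    "mrna_export", "translation", "mrna_degradation", "protein_degradation",
)


@dataclass(frozen=True)
class SpeciesState:
    """One chemical species of the regulated protein: (PTM flag set, compartment)."""

    ptm_flags: frozenset
    compartment: str
    id: str

    @staticmethod
    def make(flags, compartment: str, flag_order) -> "SpeciesState":
        flags = frozenset(flags)
        parts = ["FOXO"] + [f for f in flag_order if f in flags] + [compartment]
        return SpeciesState(flags, compartment, "_".join(parts))


@dataclass(frozen=True)
class Reaction:
    """An elementary (zero- or first-order) mass-action reaction.

    Propensity = rate_constant x (enzyme copy number if enzyme set, else 1)
    x product of reactant counts.  ``rate_constant`` already includes the
    multiplicative factors of the reactant's PTM flags.
    """

    id: str
    kind: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_constant: float
    enzyme: str | None = None


@dataclass(frozen=True)
class Counter:
    """A non-reacting observable: the sum of the member species' counts."""

    name: str
    member_species: frozenset


@dataclass
class ReactionNetwork:
    species: list[str]                      # canonical order, proteins first
    n_protein_species: int
    reactions: list[Reaction]
    enzymes: dict[str, float]               # copy numbers (mutable by events)
    initial_counts: np.ndarray              # aligned with species
    counters: list[Counter] = field(default_factory=list)
    flag_order: tuple[str, ...] = ()
    species_flags: dict[str, frozenset] = field(default_factory=dict)
    species_compartment: dict[str, str] = field(default_factory=dict)

    def species_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.species)}

    def counter_by_name(self) -> dict[str, Counter]:
        return {c.name: c for c in self.counters}

    def counter_values(self, counts: np.ndarray) -> dict[str, float]:
        """Evaluate every counter on a state vector (or trajectory rows)."""
        idx = self.species_index()
        out = {}
        for c in self.counters:
            members = [idx[s] for s in c.member_species]
            out[c.name] = np.asarray(counts)[..., members].sum(axis=-1)
        return out

    # -- tab-separated dumps ---------------------------------------------------

    def species_table(self) -> str:
        lines = ["id\tflags\tcompartment\tinitial_count"]
        for i, sid in enumerate(self.species):
            flags = self.species_flags.get(sid)
            flag_str = (",".join(f for f in self.flag_order if f in flags)
                        if flags is not None else "")
            comp = self.species_compartment.get(sid, "")
            lines.append(f"{sid}\t{flag_str}\t{comp}\t{self.initial_counts[i]:g}")
        return "\n".join(lines) + "\n"

    def reaction_table(self) -> str:
        lines = ["id\tkind\treactants\tproducts\tenzyme\trate_constant"]
        for r in self.reactions:
            lines.append("\t".join([
                r.id, r.kind, "+".join(r.reactants) or "-",
                "+".join(r.products) or "-", r.enzyme or "-",
                f"{r.rate_constant:.12g}"]))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------


def species_count(n_ptm_classes: int, n_compartments: int = 3) -> int:
    """Closed-form species count 3 * 2**N (used by the blow-up guard)."""
    return n_compartments * 2 ** n_ptm_classes


def enumerate_species(config: ModelConfig) -> list[SpeciesState]:
    """All protein species for the configured PTM classes, canonically ordered.

    Ordering: flag bitmask ascending (bit i = i-th configured class), then
    compartment in (cytoplasm, nucleus, dna_bound).  The unmodified
    cytoplasmic species is therefore always first.
    """
    flag_order = tuple(p.id for p in config.ptm_classes)
    n = len(flag_order)
    if n > MAX_PTM_CLASSES:
        raise ConfigError(
            f"{n} PTM classes would generate {species_count(n):,} species "
            f"(limit {MAX_PTM_CLASSES} classes = "
            f"{species_count(MAX_PTM_CLASSES):,}); refusing to enumerate")
    out = []
    for mask in range(2 ** n):
        flags = frozenset(flag_order[i] for i in range(n) if mask >> i & 1)
        for comp in COMPARTMENTS:
            out.append(SpeciesState.make(flags, comp, flag_order))
    return out


def effective_rate(process: str, base_rate: float, ptm_flags, config: ModelConfig
                   ) -> float:
    """base_rate x product of MF(flag, process) over the flags present.

    The product is commutative and empty flags return the base rate
    unchanged; flags without a configured MF for the process contribute 1.
    """
    if process not in PROCESSES:
        raise ConfigError(f"unknown process {process!r}")
    if base_rate < 0:
        raise ConfigError(f"base rate must be >= 0, got {base_rate}")
    by_id = config.ptm_by_id()
    rate = base_rate
    for flag in ptm_flags:
        try:
            rate *= by_id[flag].mf_for(process)
        except KeyError:
            raise ConfigError(f"unknown PTM flag {flag!r}") from None
    return rate


# ---------------------------------------------------------------------------


def build_network(config: ModelConfig) -> ReactionNetwork:
    """Expand the configuration into the complete flat reaction network.

    For every protein species: PTM addition/removal in the permitted
    compartments, polyubiquitination in the cytoplasm, degradation of the
    cytoplasmic polyubiquitinated forms, first-order transport
    cytoplasm<->nucleus and nucleus<->DNA-bound; one synthesis reaction
    producing unmodified cytoplasmic protein; and, per target gene, basal
    and FOXO-stimulated transcription, mRNA export, translation, and mRNA /
    protein degradation.

    Polyubiquitinated species are terminal by default (``config.pub_terminal``):
    they neither translocate nor undergo further PTM changes.
    """
    flag_order = tuple(p.id for p in config.ptm_classes)
    states = enumerate_species(config)
    protein_ids = [s.id for s in states]
    by_key = {(s.ptm_flags, s.compartment): s.id for s in states}

    degrading_flags = {p.id for p in config.ptm_classes if p.degrades}
    tr = config.transport
    transport_hops = {
        "cytoplasm": [("nucleus", "cyt_to_nuc", tr.cyt_to_nuc)],
        "nucleus": [("cytoplasm", "nuc_to_cyt", tr.nuc_to_cyt),
                    ("dna_bound", "nuc_to_dna", tr.nuc_to_dna)],
        "dna_bound": [("nucleus", "dna_to_nuc", tr.dna_to_nuc)],
    }

    reactions: list[Reaction] = []
    seq = 0

    def emit(kind, reactants, products, rate, enzyme=None):
        nonlocal seq
        if not (rate >= 0) or math.isnan(rate) or math.isinf(rate):
            raise ConfigError(f"non-finite rate for {kind} reaction: {rate}")
        reactions.append(Reaction(
            id=f"r{seq:05d}_{kind}", kind=kind, reactants=tuple(reactants),
            products=tuple(products), rate_constant=rate, enzyme=enzyme))
        seq += 1

    for s in states:
        terminal = config.pub_terminal and (s.ptm_flags & degrading_flags)
        if terminal:
            # pUb-flagged species only await degradation in the cytoplasm
            if s.compartment == "cytoplasm":
                emit("degradation", [s.id], [], config.syn_deg.k_deg,
                     enzyme=config.syn_deg.deg_enzyme)
            continue

        for p in config.ptm_classes:
            if p.id not in s.ptm_flags and s.compartment in p.add_compartments:
                product = by_key[(s.ptm_flags | {p.id}, s.compartment)]
                if p.degrades:
                    rate = effective_rate("polyub", p.k_add, s.ptm_flags, config)
                    emit("polyub", [s.id], [product], rate, enzyme=p.add_enzyme)
                else:
                    emit("ptm_add", [s.id], [product], p.k_add,
                         enzyme=p.add_enzyme)
            elif (p.id in s.ptm_flags and p.remove_enzyme is not None
                  and s.compartment in p.remove_compartments):
                product = by_key[(s.ptm_flags - {p.id}, s.compartment)]
                emit("ptm_remove", [s.id], [product], p.k_remove,
                     enzyme=p.remove_enzyme)

        for dest, process, base in transport_hops[s.compartment]:
            rate = effective_rate(process, base, s.ptm_flags, config)
            emit("transport", [s.id], [by_key[(s.ptm_flags, dest)]], rate)

        if not config.pub_terminal and s.ptm_flags & degrading_flags \
                and s.compartment == "cytoplasm":
            emit("degradation", [s.id], [], config.syn_deg.k_deg,
                 enzyme=config.syn_deg.deg_enzyme)

    # exactly one synthesis reaction: unmodified protein, cytoplasm
    unmodified_cyt = by_key[(frozenset(), "cytoplasm")]
    emit("synthesis", [], [unmodified_cyt], config.syn_deg.k_syn,
         enzyme=config.syn_deg.syn_enzyme)

    gene_ids: list[str] = []
    for g in config.genes:
        mn, mc, pc = f"{g.name}_mrna_nuc", f"{g.name}_mrna_cyt", f"{g.name}_protein"
        gene_ids += [mn, mc, pc]
        emit("transcription_basal", [], [mn], g.k_basalt)
        for s in states:
            if s.compartment != "dna_bound":
                continue
            if config.pub_terminal and s.ptm_flags & degrading_flags:
                continue
            rate = effective_rate("transcription", g.k_transcr,
                                  s.ptm_flags, config)
            emit("transcription_stimulated", [s.id], [s.id, mn], rate)
        emit("mrna_export", [mn], [mc], g.k_exp)
        emit("translation", [mc], [mc, pc], g.k_transl)
        emit("mrna_degradation", [mc], [], g.k_mdeg)
        emit("protein_degradation", [pc], [], g.k_pdeg)

    species = protein_ids + gene_ids
    initial = np.zeros(len(species))
    index = {sid: i for i, sid in enumerate(species)}
    if config.initial_state:
        for sid, count in config.initial_state.items():
            if sid not in index:
                raise ConfigError(f"initial_state: unknown species {sid!r}")
            initial[index[sid]] = count
    else:
        initial[index[unmodified_cyt]] = config.initial_protein_count

    net = ReactionNetwork(
        species=species,
        n_protein_species=len(protein_ids),
        reactions=reactions,
        enzymes=config.enzyme_map(),
        initial_counts=initial,
        flag_order=flag_order,
        species_flags={s.id: s.ptm_flags for s in states},
        species_compartment={s.id: s.compartment for s in states},
    )
    return add_counters(net, config)


def add_counters(network: ReactionNetwork, config: ModelConfig
                 ) -> ReactionNetwork:
    """Attach the standard counters (idempotent; replaces existing ones).

    total_foxo, total_<flag> for every PTM class, per-compartment totals,
    and total_nuclear = nucleus + dna_bound.
    """
    protein = network.species[: network.n_protein_species]
    counters = [Counter("total_foxo", frozenset(protein))]
    for flag in network.flag_order:
        members = frozenset(s for s in protein
                            if flag in network.species_flags[s])
        counters.append(Counter(f"total_{flag}", members))
    for comp in COMPARTMENTS:
        members = frozenset(s for s in protein
                            if network.species_compartment[s] == comp)
        counters.append(Counter(f"total_{comp}", members))
    nuclear = frozenset(s for s in protein
                        if network.species_compartment[s] in
                        ("nucleus", "dna_bound"))
    counters.append(Counter("total_nuclear", nuclear))
    network.counters = counters
    return network


def stimulated_transcription_rate(network: ReactionNetwork, state,
                                  gene: str | None = None,
                                  include_basal: bool = False) -> float:
    """FOXO-stimulated nuclear mRNA production rate (molecules/min) for one gene.

    Sums k_transcr x MF(transcription, flags) x count over the DNA-bound
    species, read off the network's transcription_stimulated reactions.
    ``state`` maps species id -> count (or is a vector in species order).
    With ``include_basal`` the zero-order basal production is added.
    """
    if not isinstance(state, dict):
        state = dict(zip(network.species, np.asarray(state)))
    if gene is None:
        gene_products = sorted({r.products[-1] for r in network.reactions
                                if r.kind == "transcription_stimulated"})
        if not gene_products:
            return 0.0
        target = gene_products[0]
    else:
        target = f"{gene}_mrna_nuc"
    rate = sum(r.rate_constant * state.get(r.reactants[0], 0.0)
               for r in network.reactions
               if r.kind == "transcription_stimulated"
               and r.products[-1] == target)
    if include_basal:
        rate += sum(r.rate_constant for r in network.reactions
                    if r.kind == "transcription_basal"
                    and r.products[-1] == target)
    return rate
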