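"""SBML Level 3 Version 2 serialization of reaction networks, plus a
compact human-readable shorthand dialect.

Scope: the mass-action subset this model family emits — every kinetic law
is a product of one local rate parameter, an optional (global) enzyme
parameter and at most one reactant/modifier species; substance units are
items (molecule counts).  Enzymes are global parameters, dosing events are
SBML events with time-triggered assignments, and counters are parameters
governed by assignment rules summing species (never reacting species).

The shorthand dialect follows the published SBML-shorthand layout
(@model/@compartments/@species/@parameters/@rules/@reactions/@events
sections); the @rules section for counter sums is a dialect extension.
"""

from __future__ import annotations

import re

import numpy as np
from lxml import etree

from .config import COMPARTMENTS, DoseEvent
from .network import Counter, Reaction, ReactionNetwork

__all__ = [
    "write_sbml",
    "read_sbml",
    "write_shorthand",
    "read_shorthand",
    "networks_equal",
    "SbmlError",
]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
TIME_URL = "http://www.sbml.org/sbml/symbols/time"

_RESERVED_COUNTERS = {"total_foxo", "total_cytoplasm", "total_nucleus",
                      "total_dna_bound", "total_nuclear"}


class SbmlError(ValueError):
    """Malformed, inconsistent or unsupported (non-mass-action) document."""


def _species_compartment(network: ReactionNetwork, sid: str) -> str:
    comp = network.species_compartment.get(sid)
    if comp is not None:
        return comp
    if sid.endswith("_mrna_nuc"):
        return "nucleus"
    return "cytoplasm"        # cytoplasmic mRNA and gene protein


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def _m(tag: str) -> str:
    return f"{{{MATHML_NS}}}{tag}"


def _math_product(parent, factors):
    """<math><apply><times/>ci...</apply></math> (or a single ci/cn)."""
    math = etree.SubElement(parent, _m("math"), nsmap={None: MATHML_NS})
    if len(factors) == 1:
        node, text = factors[0]
        etree.SubElement(math, _m(node)).text = text
    else:
        apply_el = etree.SubElement(math, _m("apply"))
        etree.SubElement(apply_el, _m("times"))
        for node, text in factors:
            etree.SubElement(apply_el, _m(node)).text = text
    return math


def write_sbml(network: ReactionNetwork,
               events: list[DoseEvent] | None = None,
               model_id: str = "foxo_ptm_model") -> str:
    """Serialize a network (and dosing events) to an SBML L3V2 document.

    Deterministic output: same network -> byte-identical document.
    """
    for r in network.reactions:
        if not np.isfinite(r.rate_constant) or r.rate_constant < 0:
            raise SbmlError(
                f"unserializable rate for {r.id}: {r.rate_constant}")

    root = etree.Element(f"{{{SBML_NS}}}sbml",
                         nsmap={None: SBML_NS}, level="3", version="2")
    model = etree.SubElement(root, f"{{{SBML_NS}}}model", id=model_id,
                             substanceUnits="item", timeUnits="minute",
                             extentUnits="item")

    loc = etree.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    for comp in COMPARTMENTS:
        etree.SubElement(loc, f"{{{SBML_NS}}}compartment", id=comp,
                         spatialDimensions="3", size="1", constant="true")

    los = etree.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    index = network.species_index()
    for sid in network.species:
        etree.SubElement(
            los, f"{{{SBML_NS}}}species", id=sid,
            compartment=_species_compartment(network, sid),
            initialAmount=repr(float(network.initial_counts[index[sid]])),
            hasOnlySubstanceUnits="true", boundaryCondition="false",
            constant="false")

    lop = etree.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
    for name in sorted(network.enzymes):
        etree.SubElement(lop, f"{{{SBML_NS}}}parameter", id=name,
                         value=repr(float(network.enzymes[name])),
                         constant="false")
    for c in network.counters:
        etree.SubElement(lop, f"{{{SBML_NS}}}parameter", id=c.name,
                         constant="false")

    if network.counters:
        lor = etree.SubElement(model, f"{{{SBML_NS}}}listOfRules")
        for c in network.counters:
            rule = etree.SubElement(lor, f"{{{SBML_NS}}}assignmentRule",
                                    variable=c.name)
            members = sorted(c.member_species, key=index.__getitem__)
            math = etree.SubElement(rule, _m("math"), nsmap={None: MATHML_NS})
            if len(members) == 1:
                etree.SubElement(math, _m("ci")).text = members[0]
            else:
                apply_el = etree.SubElement(math, _m("apply"))
                etree.SubElement(apply_el, _m("plus"))
                for m in members:
                    etree.SubElement(apply_el, _m("ci")).text = m

    lorx = etree.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for r in network.reactions:
        rx = etree.SubElement(lorx, f"{{{SBML_NS}}}reaction", id=r.id,
                              reversible="false")
        # catalytic species (appearing on both sides) become modifiers
        catalytic = set(r.reactants) & set(r.products)
        reactants = [s for s in r.reactants if s not in catalytic]
        products = [s for s in r.products if s not in catalytic]
        if reactants:
            lst = etree.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
            for s in reactants:
                etree.SubElement(lst, f"{{{SBML_NS}}}speciesReference",
                                 species=s, stoichiometry="1", constant="true")
        if products:
            lst = etree.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
            for s in products:
                etree.SubElement(lst, f"{{{SBML_NS}}}speciesReference",
                                 species=s, stoichiometry="1", constant="true")
        if catalytic:
            lst = etree.SubElement(rx, f"{{{SBML_NS}}}listOfModifiers")
            for s in sorted(catalytic):
                etree.SubElement(lst, f"{{{SBML_NS}}}modifierSpeciesReference",
                                 species=s)
        kl = etree.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
        factors = [("ci", "k")]
        if r.enzyme is not None:
            factors.append(("ci", r.enzyme))
        for s in r.reactants:
            factors.append(("ci", s))
        _math_product(kl, factors)
        llp = etree.SubElement(kl, f"{{{SBML_NS}}}listOfLocalParameters")
        etree.SubElement(llp, f"{{{SBML_NS}}}localParameter", id="k",
                         value=repr(float(r.rate_constant)))

    if events:
        loe = etree.SubElement(model, f"{{{SBML_NS}}}listOfEvents")
        for i, ev in enumerate(sorted(events, key=lambda e: (e.time, e.enzyme))):
            el = etree.SubElement(loe, f"{{{SBML_NS}}}event", id=f"e{i}",
                                  useValuesFromTriggerTime="true")
            trig = etree.SubElement(el, f"{{{SBML_NS}}}trigger",
                                    initialValue="false", persistent="true")
            math = etree.SubElement(trig, _m("math"), nsmap={None: MATHML_NS})
            apply_el = etree.SubElement(math, _m("apply"))
            etree.SubElement(apply_el, _m("geq"))
            csym = etree.SubElement(apply_el, _m("csymbol"),
                                    encoding="text", definitionURL=TIME_URL)
            csym.text = " t "
            etree.SubElement(apply_el, _m("cn")).text = repr(float(ev.time))
            lea = etree.SubElement(el, f"{{{SBML_NS}}}listOfEventAssignments")
            ea = etree.SubElement(lea, f"{{{SBML_NS}}}eventAssignment",
                                  variable=ev.enzyme)
            math = etree.SubElement(ea, _m("math"), nsmap={None: MATHML_NS})
            etree.SubElement(math, _m("cn")).text = repr(
                float(ev.new_copy_number))

    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True).decode()


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _parse_math_product(math_el) -> list:
    """Flatten a mass-action math tree into [(kind, value), ...] factors."""
    children = [c for c in math_el if isinstance(c.tag, str)]
    if len(children) != 1:
        raise SbmlError("kinetic-law math must contain a single expression")
    node = children[0]
    tag = etree.QName(node).localname
    if tag in ("ci", "cn"):
        return [(tag, node.text.strip())]
    if tag != "apply":
        raise SbmlError(f"unsupported math element <{tag}>")
    ops = [c for c in node if isinstance(c.tag, str)]
    if not ops or etree.QName(ops[0]).localname != "times":
        raise SbmlError("non-mass-action kinetic law (expected a product)")
    factors = []
    for c in ops[1:]:
        ctag = etree.QName(c).localname
        if ctag not in ("ci", "cn"):
            raise SbmlError(f"non-mass-action factor <{ctag}>")
        factors.append((ctag, c.text.strip()))
    return factors


def _decode_species(sid: str, flag_order):
    """Recover (flags, compartment) from a canonical protein species id."""
    if not sid.startswith("FOXO"):
        return None
    for comp in COMPARTMENTS:
        suffix = "_" + comp
        if sid.endswith(suffix):
            middle = sid[len("FOXO"):-len(suffix)].strip("_")
            flags = frozenset(middle.split("_")) if middle else frozenset()
            unknown = flags - set(flag_order)
            if unknown:
                raise SbmlError(f"species {sid!r}: unknown flags {sorted(unknown)}")
            return flags, comp
    raise SbmlError(f"species {sid!r}: no compartment suffix")


def read_sbml(document: str) -> tuple[ReactionNetwork, list[DoseEvent]]:
    """Parse a document produced by :func:`write_sbml` (or equivalent).

    Round trip: ``read_sbml(write_sbml(n, e))`` equals ``(n, e)`` up to
    canonical ordering.  Raises :class:`SbmlError` on non-mass-action
    kinetic laws or dangling references.
    """
    root = etree.fromstring(document.encode()
                            if isinstance(document, str) else document)
    ns = {"s": SBML_NS, "m": MATHML_NS}
    model = root.find("s:model", ns)
    if model is None:
        raise SbmlError("no <model> element")

    species_ids, initial = [], []
    for sp in model.findall("s:listOfSpecies/s:species", ns):
        species_ids.append(sp.get("id"))
        initial.append(float(sp.get("initialAmount", "0")))
    known = set(species_ids)

    param_values = {}
    for p in model.findall("s:listOfParameters/s:parameter", ns):
        param_values[p.get("id")] = (float(p.get("value"))
                                     if p.get("value") is not None else None)

    counters: list[Counter] = []
    for rule in model.findall("s:listOfRules/s:assignmentRule", ns):
        name = rule.get("variable")
        factors = []
        math = rule.find("m:math", ns)
        children = [c for c in math if isinstance(c.tag, str)]
        node = children[0]
        if etree.QName(node).localname == "ci":
            members = [node.text.strip()]
        else:
            ops = [c for c in node if isinstance(c.tag, str)]
            if etree.QName(ops[0]).localname != "plus":
                raise SbmlError(f"rule for {name!r} is not a species sum")
            members = [c.text.strip() for c in ops[1:]]
        missing = set(members) - known
        if missing:
            raise SbmlError(f"counter {name!r} references missing species "
                            f"{sorted(missing)}")
        counters.append(Counter(name, frozenset(members)))

    counter_names = {c.name for c in counters}
    enzymes = {name: val for name, val in param_values.items()
               if name not in counter_names}

    reactions: list[Reaction] = []
    for rx in model.findall("s:listOfReactions/s:reaction", ns):
        rid = rx.get("id")
        reactants = [sr.get("species") for sr in
                     rx.findall("s:listOfReactants/s:speciesReference", ns)]
        products = [sr.get("species") for sr in
                    rx.findall("s:listOfProducts/s:speciesReference", ns)]
        modifiers = [sr.get("species") for sr in
                     rx.findall("s:listOfModifiers/s:modifierSpeciesReference",
                                ns)]
        for sid in reactants + products + modifiers:
            if sid not in known:
                raise SbmlError(f"reaction {rid!r} references missing species "
                                f"{sid!r}")
        kl = rx.find("s:kineticLaw", ns)
        if kl is None:
            raise SbmlError(f"reaction {rid!r} has no kinetic law")
        local = {lp.get("id"): float(lp.get("value")) for lp in
                 kl.findall("s:listOfLocalParameters/s:localParameter", ns)}
        factors = _parse_math_product(kl.find("m:math", ns))
        k = None
        enzyme = None
        law_species = []
        for kind, value in factors:
            if kind == "cn":
                raise SbmlError(f"reaction {rid!r}: literal constants in "
                                f"kinetic laws are unsupported")
            if value in local:
                k = local[value]
            elif value in known:
                law_species.append(value)
            elif value in enzymes:
                enzyme = value
            else:
                raise SbmlError(f"reaction {rid!r}: unknown symbol {value!r}")
        if k is None:
            raise SbmlError(f"reaction {rid!r}: no local rate parameter")
        expected = sorted(reactants + modifiers)
        if sorted(law_species) != expected:
            raise SbmlError(f"reaction {rid!r}: kinetic law species "
                            f"{law_species} do not match reactants {expected}")
        kind = rid.split("_", 1)[1] if "_" in rid else "reaction"
        # modifiers are catalytic: reactant in the propensity, restored on
        # both sides of the reconstructed reaction
        all_reactants = tuple(modifiers) if modifiers else tuple(reactants)
        all_products = tuple(modifiers) + tuple(products) if modifiers \
            else tuple(products)
        reactions.append(Reaction(id=rid, kind=kind, reactants=all_reactants,
                                  products=all_products, rate_constant=k,
                                  enzyme=enzyme))

    events = []
    for ev in model.findall("s:listOfEvents/s:event", ns):
        trig_math = ev.find("s:trigger/m:math/m:apply", ns)
        if trig_math is None:
            raise SbmlError("event without trigger")
        ops = [c for c in trig_math if isinstance(c.tag, str)]
        if etree.QName(ops[0]).localname != "geq":
            raise SbmlError("only time >= T triggers are supported")
        time = float(ops[2].text.strip())
        for ea in ev.findall("s:listOfEventAssignments/s:eventAssignment", ns):
            var = ea.get("variable")
            if var not in enzymes:
                raise SbmlError(f"event assigns unknown parameter {var!r}")
            cn = ea.find("m:math/m:cn", ns)
            events.append(DoseEvent(time=time, enzyme=var,
                                    new_copy_number=float(cn.text.strip())))
    events.sort(key=lambda e: (e.time, e.enzyme))

    # reconstruct protein-species metadata from canonical ids
    flag_counters = [c.name[len("total_"):] for c in counters
                     if c.name.startswith("total_")
                     and c.name not in _RESERVED_COUNTERS]
    flag_order = tuple(flag_counters)
    species_flags, species_comp = {}, {}
    n_protein = 0
    for sid in species_ids:
        decoded = _decode_species(sid, flag_order)
        if decoded is not None:
            species_flags[sid], species_comp[sid] = decoded
            n_protein += 1

    net = ReactionNetwork(
        species=species_ids, n_protein_species=n_protein, reactions=reactions,
        enzymes=enzymes, initial_counts=np.asarray(initial, dtype=float),
        counters=counters, flag_order=flag_order,
        species_flags=species_flags, species_compartment=species_comp)
    return net, events


# ---------------------------------------------------------------------------
# shorthand dialect
# ---------------------------------------------------------------------------


def write_shorthand(network: ReactionNetwork,
                    events: list[DoseEvent] | None = None,
                    model_id: str = "foxo_ptm_model") -> str:
    """Emit the compact shorthand dialect for a network.

    Converting shorthand -> network -> shorthand is stable (idempotent
    after one round).
    """
    for r in network.reactions:
        if not np.isfinite(r.rate_constant) or r.rate_constant < 0:
            raise SbmlError(f"unserializable rate for {r.id}: {r.rate_constant}")
    index = network.species_index()
    lines = [f"@model:3.1.1={model_id}", " s=item, t=minute, e=item"]
    lines.append("@compartments")
    for comp in COMPARTMENTS:
        lines.append(f" {comp}=1")
    lines.append("@species")
    for sid in network.species:
        amount = float(network.initial_counts[index[sid]])
        comp = _species_compartment(network, sid)
        lines.append(f" {comp}:[{sid}]={amount:.17g} s")
    lines.append("@parameters")
    for name in sorted(network.enzymes):
        lines.append(f" {name}={float(network.enzymes[name]):.17g}")
    if network.counters:
        lines.append("@rules")
        for c in network.counters:
            members = sorted(c.member_species, key=index.__getitem__)
            lines.append(f" {c.name}=" + "+".join(members))
    lines.append("@reactions")
    for r in network.reactions:
        lines.append(f"@r={r.id}")
        lhs = "+".join(r.reactants) if r.reactants else ""
        rhs = "+".join(r.products) if r.products else ""
        lines.append(f" {lhs}->{rhs}")
        factors = ["k"]
        if r.enzyme is not None:
            factors.append(r.enzyme)
        factors.extend(r.reactants)
        lines.append(f" {'*'.join(factors)} : k={r.rate_constant:.17g}")
    if events:
        lines.append("@events")
        for i, ev in enumerate(sorted(events, key=lambda e: (e.time, e.enzyme))):
            lines.append(f" e{i}= t>={ev.time:g} : "
                         f"{ev.enzyme}={ev.new_copy_number:g}")
    return "\n".join(lines) + "\n"


_SPECIES_RE = re.compile(r"^(\w+):\[([\w]+)\]=([-\d.eE+]+)(?:\s+\w+)?$")


def read_shorthand(text: str) -> tuple[ReactionNetwork, list[DoseEvent]]:
    """Parse the shorthand dialect back into (network, events)."""
    section = None
    species_ids: list[str] = []
    initial: list[float] = []
    species_comp_doc: dict[str, str] = {}
    params: dict[str, float] = {}
    counters: list[Counter] = []
    reactions: list[Reaction] = []
    events: list[DoseEvent] = []
    pending: dict | None = None

    def flush_reaction():
        nonlocal pending
        if pending is None:
            return
        if "k" not in pending or "reactants" not in pending:
            raise SbmlError(f"incomplete reaction stanza {pending.get('id')!r}")
        rid = pending["id"]
        kind = rid.split("_", 1)[1] if "_" in rid else "reaction"
        reactions.append(Reaction(
            id=rid, kind=kind, reactants=pending["reactants"],
            products=pending["products"], rate_constant=pending["k"],
            enzyme=pending.get("enzyme")))
        pending = None

    for raw in text.splitlines():
        line = raw.rstrip()
        if not line.strip():
            continue
        if line.startswith("@model"):
            section = "model"
            continue
        if line.startswith("@compartments"):
            section = "compartments"
            continue
        if line.startswith("@species"):
            section = "species"
            continue
        if line.startswith("@parameters"):
            section = "parameters"
            continue
        if line.startswith("@rules"):
            section = "rules"
            continue
        if line.startswith("@reactions"):
            section = "reactions"
            continue
        if line.startswith("@events"):
            flush_reaction()
            section = "events"
            continue
        if line.startswith("@r="):
            flush_reaction()
            pending = {"id": line[3:].strip()}
            section = "reactions"
            continue

        body = line.strip()
        if section == "species":
            m = _SPECIES_RE.match(body)
            if not m:
                raise SbmlError(f"bad species line: {body!r}")
            comp, sid, amount = m.group(1), m.group(2), float(m.group(3))
            species_ids.append(sid)
            initial.append(amount)
            species_comp_doc[sid] = comp
        elif section == "parameters":
            name, _, val = body.partition("=")
            params[name.strip()] = float(val)
        elif section == "rules":
            name, _, rhs = body.partition("=")
            counters.append(Counter(name.strip(),
                                    frozenset(rhs.strip().split("+"))))
        elif section == "reactions" and pending is not None:
            if "->" in body and "reactants" not in pending:
                lhs, _, rhs = body.partition("->")
                pending["reactants"] = tuple(
                    s for s in lhs.strip().split("+") if s)
                pending["products"] = tuple(
                    s for s in rhs.strip().split("+") if s)
            else:
                law, _, local = body.partition(":")
                name, _, val = local.partition("=")
                if name.strip() != "k":
                    raise SbmlError(f"bad local parameter in {pending['id']!r}")
                pending["k"] = float(val)
                symbols = [s for s in law.strip().split("*") if s != "k"]
                for sym in symbols:
                    if sym not in pending["reactants"]:
                        pending["enzyme"] = sym
        elif section == "events":
            m = re.match(r"^\w+=\s*t\s*>=\s*([-\d.eE+]+)\s*:\s*(\w+)\s*="
                         r"\s*([-\d.eE+]+)$", body)
            if not m:
                raise SbmlError(f"bad event line: {body!r}")
            events.append(DoseEvent(time=float(m.group(1)), enzyme=m.group(2),
                                    new_copy_number=float(m.group(3))))
        elif section in ("model", "compartments"):
            continue
        else:
            raise SbmlError(f"unexpected line outside any section: {body!r}")
    flush_reaction()

    known = set(species_ids)
    for r in reactions:
        for sid in r.reactants + r.products:
            if sid not in known:
                raise SbmlError(
                    f"reaction {r.id!r} references missing species {sid!r}")
    for c in counters:
        missing = c.member_species - known
        if missing:
            raise SbmlError(f"counter {c.name!r} references missing species "
                            f"{sorted(missing)}")

    counter_names = {c.name for c in counters}
    enzymes = {n: v for n, v in params.items() if n not in counter_names}
    flag_order = tuple(c.name[len("total_"):] for c in counters
                       if c.name.startswith("total_")
                       and c.name not in _RESERVED_COUNTERS)
    species_flags, species_comp = {}, {}
    n_protein = 0
    for sid in species_ids:
        decoded = _decode_species(sid, flag_order)
        if decoded is not None:
            species_flags[sid], species_comp[sid] = decoded
            n_protein += 1

    net = ReactionNetwork(
        species=species_ids, n_protein_species=n_protein, reactions=reactions,
        enzymes=enzymes, initial_counts=np.asarray(initial, dtype=float),
        counters=counters, flag_order=flag_order,
        species_flags=species_flags, species_compartment=species_comp)
    events.sort(key=lambda e: (e.time, e.enzyme))
    return net, events


# ---------------------------------------------------------------------------


def networks_equal(a: ReactionNetwork, b: ReactionNetwork,
                   rel_tol: float = 1e-12) -> bool:
    """Structural equality up to canonical ordering (used for round trips)."""
    if list(a.species) != list(b.species):
        return False
    if not np.allclose(a.initial_counts, b.initial_counts, rtol=rel_tol):
        return False
    if dict(a.enzymes) != dict(b.enzymes):
        return False

    def reaction_key(r: Reaction):
        return (r.id, r.kind, tuple(sorted(r.reactants)),
                tuple(sorted(r.products)), r.enzyme)

    ra = sorted(a.reactions, key=lambda r: r.id)
    rb = sorted(b.reactions, key=lambda r: r.id)
    if len(ra) != len(rb):
        return False
    for x, y in zip(ra, rb):
        if reaction_key(x) != reaction_key(y):
            return False
        if not np.isclose(x.rate_constant, y.rate_constant, rtol=rel_tol):
            return False
    ca = {c.name: c.member_species for c in a.counters}
    cb = {c.name: c.member_species for c in b.counters}
    return ca == cb
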