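"""Declarative model configuration for the FOXO multi-PTM model.

The model is parameterized by a :class:`ModelConfig`: a set of collective
PTM classes (each a binary flag added/removed by an enzyme pair), enzyme
pools with copy numbers, first-order transport rates between the three
compartments (cytoplasm, nucleus, DNA-bound), synthesis/degradation
constants, FOXO-regulated target genes, initial conditions and timed
enzyme-dosing events.

All rate constants are in per-molecule per-minute units (counts, not
concentrations).  Second-order constants are always paired with an enzyme
copy number; only their product, the pseudo-first-order constant, is
experimentally constrained.
"""

from __future__ import annotations

import copy
import io
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "COMPARTMENTS",
    "PROCESSES",
    "PTMClass",
    "EnzymePool",
    "TransportRates",
    "SynthesisDegradation",
    "GeneTarget",
    "DoseEvent",
    "ModelConfig",
    "ConfigError",
    "default_foxo_config",
    "load_config",
    "loads_config",
    "dump_config",
    "validate_config",
]

#: The three subcellular compartments.  ``dna_bound`` is reachable only
#: from the nucleus.
COMPARTMENTS = ("cytoplasm", "nucleus", "dna_bound")

#: Process names that a PTM class may modulate via a multiplicative factor.
PROCESSES = (
    "cyt_to_nuc",
    "nuc_to_cyt",
    "nuc_to_dna",
    "dna_to_nuc",
    "polyub",
    "transcription",
)

#: Canonical order of the default collective PTM flags.
DEFAULT_FLAG_ORDER = ("Pa", "Pb", "Pc", "Pd", "Pe", "Ac", "mUb", "pUb")


class ConfigError(ValueError):
    """Raised for schema violations or dangling references in a config."""


@dataclass
class PTMClass:
    """One collective post-translational modification.

    A collective PTM groups all individual sites with the same functional
    effect (e.g. the three Akt sites) into a single binary flag.  The flag
    is added by ``add_enzyme`` and removed by ``remove_enzyme`` (if any)
    with mass-action kinetics; ``mf`` maps process names to the
    dimensionless multiplicative factor applied to that process's basal
    rate when the flag is present.
    """

    id: str
    add_enzyme: str
    k_add: float
    remove_enzyme: str | None = None
    k_remove: float = 0.0
    add_compartments: tuple[str, ...] = COMPARTMENTS
    remove_compartments: tuple[str, ...] = COMPARTMENTS
    mf: dict[str, float] = field(default_factory=dict)
    degrades: bool = False  # polyubiquitin-like flag marking for degradation

    def mf_for(self, process: str) -> float:
        if process not in PROCESSES:
            raise ConfigError(f"unknown process {process!r}")
        return self.mf.get(process, 1.0)


@dataclass
class EnzymePool:
    """A modifying enzyme (or pseudo-enzyme) with a copy number.

    Copy numbers are inputs of the model; dosing events change them in a
    piecewise-constant way.
    """

    name: str
    copy_number: float


@dataclass
class TransportRates:
    """First-order translocation rates (per minute) between compartments."""

    cyt_to_nuc: float = 0.182
    nuc_to_cyt: float = 0.055
    nuc_to_dna: float = 0.25
    dna_to_nuc: float = 0.125


@dataclass
class SynthesisDegradation:
    """Synthesis (zero-order via E2F1) and pUb-species degradation."""

    k_syn: float = 0.0055
    syn_enzyme: str = "E2F1"
    k_deg: float = 1e-4
    deg_enzyme: str = "Proteasome"


@dataclass
class GeneTarget:
    """A FOXO-regulated gene with transcription/translation kinetics.

    Stimulated transcription is catalysed by DNA-bound FOXO molecules at
    ``k_transcr`` per bound molecule per minute (modulated by the
    transcription MFs of the PTMs the molecule carries); ``k_basalt`` is a
    zero-order basal nuclear mRNA production.
    """

    name: str
    k_transcr: float = 0.3
    k_basalt: float = 3.0
    k_exp: float = 0.22
    k_transl: float = 1.23
    k_mdeg: float = 5.622
    k_pdeg: float = 1.9e-3


@dataclass(order=True)
class DoseEvent:
    """A timed step change of an enzyme copy number (minutes)."""

    time: float
    enzyme: str
    new_copy_number: float


@dataclass
class ModelConfig:
    ptm_classes: list[PTMClass] = field(default_factory=list)
    enzymes: list[EnzymePool] = field(default_factory=list)
    transport: TransportRates = field(default_factory=TransportRates)
    syn_deg: SynthesisDegradation = field(default_factory=SynthesisDegradation)
    genes: list[GeneTarget] = field(default_factory=list)
    initial_protein_count: int = 1000
    #: optional explicit species distribution at t=0, mapping canonical
    #: species id -> count; when empty, all protein starts unmodified in
    #: the cytoplasm.
    initial_state: dict[str, float] = field(default_factory=dict)
    events: list[DoseEvent] = field(default_factory=list)
    pre_equilibration_minutes: float = 0.0
    #: when True (default) pUb-flagged species are terminal: they do not
    #: translocate and accept no further PTM changes, only degradation.
    pub_terminal: bool = True

    # -- convenience accessors -------------------------------------------------

    def enzyme_map(self) -> dict[str, float]:
        return {e.name: e.copy_number for e in self.enzymes}

    def ptm_by_id(self) -> dict[str, PTMClass]:
        return {p.id: p for p in self.ptm_classes}

    def enzyme(self, name: str) -> EnzymePool:
        for e in self.enzymes:
            if e.name == name:
                return e
        raise ConfigError(f"unknown enzyme {name!r}")

    def restrict_ptms(self, ids) -> "ModelConfig":
        """Return a deep copy keeping only the named PTM classes."""
        keep = set(ids)
        unknown = keep - {p.id for p in self.ptm_classes}
        if unknown:
            raise ConfigError(f"unknown PTM classes {sorted(unknown)}")
        cfg = copy.deepcopy(self)
        cfg.ptm_classes = [p for p in cfg.ptm_classes if p.id in keep]
        return cfg

    def without_genes(self) -> "ModelConfig":
        """Return a deep copy with no target genes (protein network only)."""
        cfg = copy.deepcopy(self)
        cfg.genes = []
        return cfg

    def with_enzymes(self, **overrides: float) -> "ModelConfig":
        """Return a deep copy with the given enzyme copy numbers replaced."""
        cfg = copy.deepcopy(self)
        known = {e.name for e in cfg.enzymes}
        for name, count in overrides.items():
            if name not in known:
                raise ConfigError(f"unknown enzyme {name!r}")
        cfg.enzymes = [
            replace(e, copy_number=overrides.get(e.name, e.copy_number))
            for e in cfg.enzymes
        ]
        return cfg


# ---------------------------------------------------------------------------
# Built-in FOXO parameterization
# ---------------------------------------------------------------------------


def default_foxo_config() -> ModelConfig:
    """The built-in FOXO parameter set.

    Eight collective PTM flags: five phosphorylations (Pa by Akt/SGK, Pb by
    CDK2/CK1, Pc by AMPK, Pd by IKK, Pe by JNK/MST1, all removed by a single
    phosphatase PP2A), acetylation (CBP/P300 vs SIRT1, nuclear compartments
    only), monoubiquitination (E3 vs USP7) and one-step polyubiquitination
    (SCF/MDM2, cytoplasm only, no remover, marks for degradation).

    Pseudo-first-order constants at default enzyme levels: 0.5/min for the
    kinase/phosphatase pairs, 0.1/min for acetylation/deacetylation,
    0.2/min for mono-ubiquitination, 1e-3/min for polyubiquitination,
    0.1/min for degradation and 0.55 molecules/min for synthesis.
    """
    kin = dict(k_add=5e-5, k_remove=5e-5, remove_enzyme="PP2A")
    nuclear = ("nucleus", "dna_bound")
    ptms = [
        PTMClass("Pa", "Akt", mf={"nuc_to_cyt": 10, "cyt_to_nuc": 0.1,
                                  "nuc_to_dna": 0.5, "polyub": 3}, **kin),
        PTMClass("Pb", "CDK2", mf={"nuc_to_cyt": 2, "cyt_to_nuc": 0.5,
                                   "transcription": 0.1}, **kin),
        PTMClass("Pc", "AMPK", mf={"transcription": 2.0}, **kin),
        PTMClass("Pd", "IKK", mf={"nuc_to_cyt": 10, "cyt_to_nuc": 0.5,
                                  "polyub": 6}, **kin),
        PTMClass("Pe", "JNK", mf={"nuc_to_cyt": 0.1, "cyt_to_nuc": 10}, **kin),
        PTMClass("Ac", "CBP", k_add=1e-4, remove_enzyme="SIRT", k_remove=1e-4,
                 add_compartments=nuclear, remove_compartments=nuclear,
                 mf={"nuc_to_dna": 0.5, "polyub": 0.033}),
        PTMClass("mUb", "E3", k_add=2e-4, remove_enzyme="USP7", k_remove=2e-4,
                 mf={"nuc_to_cyt": 0.1, "cyt_to_nuc": 10}),
        PTMClass("pUb", "SCF_MDM2", k_add=1e-6, remove_enzyme=None,
                 k_remove=0.0, add_compartments=("cytoplasm",),
                 remove_compartments=(), degrades=True),
    ]
    enzymes = [
        EnzymePool("Akt", 1e4),
        EnzymePool("CDK2", 1e4),
        EnzymePool("AMPK", 1e4),
        EnzymePool("IKK", 1e4),
        EnzymePool("JNK", 1e4),
        EnzymePool("PP2A", 1e4),
        EnzymePool("CBP", 1e3),
        EnzymePool("SIRT", 1e3),
        EnzymePool("E3", 1e3),
        EnzymePool("USP7", 1e3),
        EnzymePool("SCF_MDM2", 1e3),
        EnzymePool("Proteasome", 1e3),
        EnzymePool("E2F1", 100),
    ]
    genes = [GeneTarget("SOD2"), GeneTarget("InsR")]
    return ModelConfig(ptm_classes=ptms, enzymes=enzymes, genes=genes)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_config(config: ModelConfig) -> list[str]:
    """Check all invariants; return one human-readable finding per violation.

    An empty list means the configuration is valid.  Nothing is raised.
    """
    findings: list[str] = []
    enzyme_names = {e.name for e in config.enzymes}

    seen_ids: set[str] = set()
    for p in config.ptm_classes:
        where = f"ptm_classes[{p.id}]"
        if p.id in seen_ids:
            findings.append(f"{where}: duplicate PTM class id")
        seen_ids.add(p.id)
        if p.k_add < 0:
            findings.append(f"{where}.k_add: must be >= 0, got {p.k_add}")
        if p.k_remove < 0:
            findings.append(f"{where}.k_remove: must be >= 0, got {p.k_remove}")
        if p.add_enzyme not in enzyme_names:
            findings.append(f"{where}.add_enzyme: unknown enzyme {p.add_enzyme!r}")
        if p.remove_enzyme is not None and p.remove_enzyme not in enzyme_names:
            findings.append(
                f"{where}.remove_enzyme: unknown enzyme {p.remove_enzyme!r}")
        for c in tuple(p.add_compartments) + tuple(p.remove_compartments):
            if c not in COMPARTMENTS:
                findings.append(f"{where}: unknown compartment {c!r}")
        for proc, factor in p.mf.items():
            if proc not in PROCESSES:
                findings.append(f"{where}.mf: unknown process {proc!r}")
            if not factor > 0:
                findings.append(
                    f"{where}.mf[{proc}]: multiplicative factor must be > 0, "
                    f"got {factor}")
        if p.degrades and p.remove_enzyme is not None:
            findings.append(
                f"{where}: degradation-enabling PTM must have no remover")

    for e in config.enzymes:
        if e.copy_number < 0:
            findings.append(
                f"enzymes[{e.name}].copy_number: must be >= 0, got {e.copy_number}")

    tr = config.transport
    for name in ("cyt_to_nuc", "nuc_to_cyt", "nuc_to_dna", "dna_to_nuc"):
        if not getattr(tr, name) > 0:
            findings.append(f"transport.{name}: must be > 0")

    sd = config.syn_deg
    if sd.k_syn < 0:
        findings.append(f"synthesis_degradation.k_syn: must be >= 0")
    if sd.k_deg < 0:
        findings.append(f"synthesis_degradation.k_deg: must be >= 0")
    for enz in (sd.syn_enzyme, sd.deg_enzyme):
        if enz not in enzyme_names:
            findings.append(
                f"synthesis_degradation: unknown enzyme {enz!r}")

    for g in config.genes:
        for fname in ("k_transcr", "k_basalt", "k_exp", "k_transl",
                      "k_mdeg", "k_pdeg"):
            if getattr(g, fname) < 0:
                findings.append(f"genes[{g.name}].{fname}: must be >= 0")

    if config.initial_protein_count < 0:
        findings.append("initial_protein_count: must be >= 0")
    for sid, count in config.initial_state.items():
        if count < 0:
            findings.append(f"initial_state[{sid}]: must be >= 0, got {count}")

    last: dict[str, float] = {}
    prev_t = None
    for ev in config.events:
        if ev.enzyme not in enzyme_names:
            findings.append(f"events: unknown enzyme {ev.enzyme!r}")
        if ev.new_copy_number < 0:
            findings.append(
                f"events[t={ev.time}, {ev.enzyme}]: copy number must be >= 0")
        if prev_t is not None and ev.time < prev_t:
            findings.append("events: must be sorted by time")
        if last.get(ev.enzyme) == ev.time:
            findings.append(
                f"events: two events on {ev.enzyme!r} at t={ev.time}")
        last[ev.enzyme] = ev.time
        prev_t = ev.time

    if config.pre_equilibration_minutes < 0:
        findings.append("pre_equilibration_minutes: must be >= 0")
    return findings


# ---------------------------------------------------------------------------
# Loading / serialization (YAML key-value trees)
# ---------------------------------------------------------------------------


def _as_float(value, where: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ConfigError(f"{where}: expected a number, got {value!r}") from None


def _merge_ptm(base: PTMClass | None, pid: str, doc: dict) -> PTMClass:
    p = copy.deepcopy(base) if base is not None else PTMClass(
        id=pid, add_enzyme="", k_add=0.0)
    allowed = {"add_enzyme", "remove_enzyme", "k_add", "k_remove",
               "add_compartments", "remove_compartments", "mf", "degrades",
               "enabled"}
    p.enabled = doc.pop("enabled", True)  # transient marker, read by loader
    for key, val in doc.items():
        if key not in allowed:
            raise ConfigError(f"ptm_classes[{pid}]: unknown field {key!r}")
        if key in ("k_add", "k_remove"):
            val = _as_float(val, f"ptm_classes[{pid}].{key}")
            if val < 0:
                raise ConfigError(
                    f"ptm_classes[{pid}].{key}: must be >= 0, got {val}")
        elif key in ("add_compartments", "remove_compartments"):
            val = tuple(val)
        elif key == "mf":
            val = {proc: _as_float(f, f"ptm_classes[{pid}].mf[{proc}]")
                   for proc, f in dict(val).items()}
        setattr(p, key, val)
    return p


def loads_config(text: str) -> ModelConfig:
    """Parse a YAML configuration document into a validated ModelConfig.

    Unspecified fields take their values from :func:`default_foxo_config`;
    an empty document yields the default configuration.
    """
    doc = yaml.safe_load(text) or {}
    if not isinstance(doc, dict):
        raise ConfigError("top level of a config document must be a mapping")
    known = {"ptm_classes", "enzymes", "transport", "synthesis_degradation",
             "genes", "initial", "events", "pre_equilibration_minutes",
             "pub_terminal"}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")

    cfg = default_foxo_config()

    if "ptm_classes" in doc:
        by_id = cfg.ptm_by_id()
        section = doc["ptm_classes"]
        if not isinstance(section, dict):
            raise ConfigError("ptm_classes: expected a mapping id -> fields")
        for pid, fields_doc in section.items():
            if fields_doc is None:
                fields_doc = {}
            merged = _merge_ptm(by_id.get(pid), pid, dict(fields_doc))
            if pid in by_id:
                cfg.ptm_classes[[p.id for p in cfg.ptm_classes].index(pid)] = merged
            else:
                if not merged.add_enzyme:
                    raise ConfigError(
                        f"ptm_classes[{pid}]: new class requires add_enzyme")
                cfg.ptm_classes.append(merged)
        kept = []
        for p in cfg.ptm_classes:
            if getattr(p, "enabled", True):
                kept.append(p)
            if hasattr(p, "enabled"):
                del p.enabled
        cfg.ptm_classes = kept

    if "enzymes" in doc:
        section = doc["enzymes"]
        if not isinstance(section, dict):
            raise ConfigError("enzymes: expected a mapping name -> copy number")
        by_name = {e.name: e for e in cfg.enzymes}
        for name, count in section.items():
            count = _as_float(count, f"enzymes[{name}]")
            if count < 0:
                raise ConfigError(f"enzymes[{name}]: must be >= 0, got {count}")
            if name in by_name:
                by_name[name].copy_number = count
            else:
                cfg.enzymes.append(EnzymePool(name, count))

    if "transport" in doc:
        for key, val in dict(doc["transport"]).items():
            if not hasattr(cfg.transport, key):
                raise ConfigError(f"transport: unknown field {key!r}")
            val = _as_float(val, f"transport.{key}")
            if not val > 0:
                raise ConfigError(f"transport.{key}: must be > 0, got {val}")
            setattr(cfg.transport, key, val)

    if "synthesis_degradation" in doc:
        for key, val in dict(doc["synthesis_degradation"]).items():
            if not hasattr(cfg.syn_deg, key):
                raise ConfigError(f"synthesis_degradation: unknown field {key!r}")
            if key in ("k_syn", "k_deg"):
                val = _as_float(val, f"synthesis_degradation.{key}")
                if val < 0:
                    raise ConfigError(
                        f"synthesis_degradation.{key}: must be >= 0, got {val}")
            setattr(cfg.syn_deg, key, val)

    if "genes" in doc:
        section = doc["genes"]
        if not isinstance(section, dict):
            raise ConfigError("genes: expected a mapping name -> fields")
        by_name = {g.name: g for g in cfg.genes}
        for gname, fields_doc in section.items():
            fields_doc = dict(fields_doc or {})
            if fields_doc.pop("enabled", True) is False:
                cfg.genes = [g for g in cfg.genes if g.name != gname]
                continue
            gene = by_name.get(gname) or GeneTarget(gname)
            for key, val in fields_doc.items():
                if not hasattr(gene, key) or key == "name":
                    raise ConfigError(f"genes[{gname}]: unknown field {key!r}")
                val = _as_float(val, f"genes[{gname}].{key}")
                if val < 0:
                    raise ConfigError(
                        f"genes[{gname}].{key}: must be >= 0, got {val}")
                setattr(gene, key, val)
            if gname not in by_name:
                cfg.genes.append(gene)

    if "initial" in doc:
        section = dict(doc["initial"])
        if "protein_count" in section:
            cfg.initial_protein_count = int(section.pop("protein_count"))
        if "state" in section:
            cfg.initial_state = {str(k): _as_float(v, f"initial.state[{k}]")
                                 for k, v in dict(section.pop("state")).items()}
        if section:
            raise ConfigError(f"initial: unknown fields {sorted(section)}")

    if "events" in doc:
        events = []
        for i, ev in enumerate(doc["events"]):
            ev = dict(ev)
            try:
                events.append(DoseEvent(
                    time=_as_float(ev.pop("time"), f"events[{i}].time"),
                    enzyme=str(ev.pop("enzyme")),
                    new_copy_number=_as_float(
                        ev.pop("copy_number"), f"events[{i}].copy_number")))
            except KeyError as exc:
                raise ConfigError(f"events[{i}]: missing field {exc}") from None
            if ev:
                raise ConfigError(f"events[{i}]: unknown fields {sorted(ev)}")
        cfg.events = sorted(events, key=lambda e: e.time)

    if "pre_equilibration_minutes" in doc:
        cfg.pre_equilibration_minutes = _as_float(
            doc["pre_equilibration_minutes"], "pre_equilibration_minutes")
    if "pub_terminal" in doc:
        cfg.pub_terminal = bool(doc["pub_terminal"])

    findings = validate_config(cfg)
    if findings:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(findings))
    return cfg


def load_config(source) -> ModelConfig:
    """Load a config from a path, file-like object, YAML string or mapping."""
    if isinstance(source, dict):
        return loads_config(yaml.safe_dump(source))
    if hasattr(source, "read"):
        return loads_config(source.read())
    text = str(source)
    if "\n" not in text and (text.endswith((".yml", ".yaml", ".json"))
                             or "/" in text):
        with open(text) as fh:
            return loads_config(fh.read())
    return loads_config(text)


def dump_config(config: ModelConfig) -> str:
    """Serialize a config to YAML; ``loads_config`` of the output round-trips."""
    doc = {
        "ptm_classes": {
            p.id: {
                "add_enzyme": p.add_enzyme,
                "remove_enzyme": p.remove_enzyme,
                "k_add": p.k_add,
                "k_remove": p.k_remove,
                "add_compartments": list(p.add_compartments),
                "remove_compartments": list(p.remove_compartments),
                "mf": dict(p.mf),
                "degrades": p.degrades,
            } for p in config.ptm_classes
        },
        "enzymes": {e.name: e.copy_number for e in config.enzymes},
        "transport": {k: getattr(config.transport, k)
                      for k in ("cyt_to_nuc", "nuc_to_cyt",
                                "nuc_to_dna", "dna_to_nuc")},
        "synthesis_degradation": {
            "k_syn": config.syn_deg.k_syn, "syn_enzyme": config.syn_deg.syn_enzyme,
            "k_deg": config.syn_deg.k_deg, "deg_enzyme": config.syn_deg.deg_enzyme,
        },
        "genes": {g.name: {k: getattr(g, k)
                           for k in ("k_transcr", "k_basalt", "k_exp",
                                     "k_transl", "k_mdeg", "k_pdeg")}
                  for g in config.genes},
        "initial": {"protein_count": config.initial_protein_count,
                    "state": dict(config.initial_state)},
        "events": [{"time": e.time, "enzyme": e.enzyme,
                    "copy_number": e.new_copy_number} for e in config.events],
        "pre_equilibration_minutes": config.pre_equilibration_minutes,
        "pub_terminal": config.pub_terminal,
    }
    out = io.StringIO()
    yaml.safe_dump(doc, out, sort_keys=True)
    return out.getvalue()
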