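"""Canned in-silico experiments: single-PTM dose responses, the Akt/JNK
antagonism time course, Akt x JNK localization scans, and the short/long
Akt-pulse protocol under low and high acetylation.

Each scenario starts from the built-in configuration with only the listed
enzyme overrides, optionally pre-equilibrates, applies its dosing
schedule, and reports trajectories plus a summary table.  Scenarios whose
read-out is a stationary property (dose-response curves, transcription
ratios) are evaluated on the deterministic steady state; time-course
scenarios run as ODE (ensemble mean) or as replicate SSA paths.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DoseEvent, ModelConfig, default_foxo_config
from .network import ReactionNetwork, build_network
from .observables import (localization_fractions, steady_state,
                          time_to_half_initial)
from .simulate import (SimulationSettings, Trajectory,
                       apply_pre_equilibration, simulate)

__all__ = ["Scenario", "SCENARIOS", "run_scenario", "single_ptm_baseline"]

#: enzymes that confer or remove PTMs; zeroed in single-PTM baselines
_MODIFYING = ("Akt", "CDK2", "AMPK", "IKK", "JNK", "CBP", "SIRT", "E3", "USP7")


def single_ptm_baseline(**overrides: float) -> ModelConfig:
    """Default config with all modifying enzymes off except the overrides.

    Phosphatase, polyubiquitination, degradation and synthesis machinery
    stay at their defaults (PP2A=1e4, SCF/MDM2=1e3, Proteasome=1e3,
    E2F1=100) unless overridden.
    """
    cfg = default_foxo_config()
    zeros = {name: 0.0 for name in _MODIFYING}
    zeros.update(overrides)
    return cfg.with_enzymes(**zeros)


@dataclass
class Scenario:
    name: str
    description: str
    arms: dict[str, dict[str, float]]           # arm name -> enzyme overrides
    pre_eq_minutes: float = 0.0
    events: list[DoseEvent] = field(default_factory=list)
    t_end: float = 0.0                          # 0 -> steady-state read-out
    record_every: float = 1.0
    observables: tuple[str, ...] = ("total_foxo", "total_cytoplasm",
                                    "total_nucleus", "total_dna_bound",
                                    "total_nuclear")


def _fig6_events() -> list[DoseEvent]:
    return [DoseEvent(360, "Akt", 1e5), DoseEvent(420, "Akt", 100),
            DoseEvent(540, "Akt", 1e5), DoseEvent(1260, "Akt", 100)]


SCENARIOS: dict[str, Scenario] = {}


def _register(s: Scenario) -> Scenario:
    SCENARIOS[s.name] = s
    return s


_register(Scenario(
    "fig4a", "steady-state nuclear fraction vs Akt activity",
    arms={f"Akt={v:g}": {"Akt": v} for v in (10, 1.75e3, 3e4, 6e5)}))
_register(Scenario(
    "fig4b", "nuclear-to-cytoplasmic redistribution on Akt activation",
    arms={"default": {"Akt": 2e3}}, pre_eq_minutes=120,
    events=[DoseEvent(0.0, "Akt", 2.5e4)], t_end=60))
_register(Scenario(
    "fig4c", "synthesis and degradation of total FOXO",
    arms={"Akt_high_no_proteasome": {"Akt": 1e5, "Proteasome": 0},
          "Akt_low": {"Akt": 100},
          "Akt_high": {"Akt": 1e5}},
    t_end=720, record_every=5))
_register(Scenario(
    "fig4d", "acetylation protects FOXO from degradation (synthesis off)",
    arms={"SIRT_high": {"SIRT": 1e3, "CBP": 10, "Akt": 1e5, "E2F1": 0},
          "SIRT_moderate": {"SIRT": 200, "CBP": 1e3, "Akt": 1e5, "E2F1": 0},
          "SIRT_low": {"SIRT": 10, "CBP": 1e3, "Akt": 1e5, "E2F1": 0}},
    t_end=720, record_every=5))
_register(Scenario(
    "fig4e", "IKK activation accelerates degradation",
    arms={"IKK_high": {"IKK": 1e5}, "IKK_low": {"IKK": 100}},
    t_end=720, record_every=5))
_register(Scenario(
    "fig4f", "acetylation state modulates transcription (ratios to 50:50)",
    arms={"balanced": {"CBP": 1e3, "SIRT": 1e3},
          "deacetylated": {"CBP": 10, "SIRT": 1e3},
          "acetylated": {"CBP": 1e3, "SIRT": 10}}))
_register(Scenario(
    "fig4g", "AMPK upregulates FOXO-stimulated transcription",
    arms={"AMPK_high": {"AMPK": 1e5}, "AMPK_low": {"AMPK": 100}}))
_register(Scenario(
    "fig5", "sequential Akt then JNK activation",
    arms={"default": {"Akt": 100, "JNK": 0, "PP2A": 1e4}},
    pre_eq_minutes=1440,
    events=[DoseEvent(60, "Akt", 5e4), DoseEvent(120, "JNK", 5e4)],
    t_end=360,
    observables=("total_foxo", "total_cytoplasm", "total_nucleus",
                 "total_dna_bound", "total_nuclear", "SOD2_mrna_nuc",
                 "SOD2_mrna_cyt", "SOD2_protein")))
_register(Scenario(
    "fig5_scan", "localization vs Akt and JNK at high and low phosphatase",
    arms={f"PP2A={pp:g}": {"PP2A": pp} for pp in (1e4, 100)}))
_register(Scenario(
    "fig6_lowAc", "short and long Akt pulses, low acetylation",
    arms={"lowAc": {"Akt": 100, "SIRT": 1e3, "CBP": 10}},
    pre_eq_minutes=2520, events=_fig6_events(), t_end=3420, record_every=5,
    observables=("total_foxo", "total_cytoplasm", "total_nucleus",
                 "total_dna_bound", "total_nuclear", "total_Ac",
                 "SOD2_mrna_nuc", "SOD2_mrna_cyt", "SOD2_protein")))
_register(Scenario(
    "fig6_highAc", "short and long Akt pulses, 99% acetylation",
    arms={"highAc": {"Akt": 100, "SIRT": 10, "CBP": 1e3}},
    pre_eq_minutes=2520, events=_fig6_events(), t_end=3420, record_every=5,
    observables=SCENARIOS["fig6_lowAc"].observables))
_register(Scenario(
    "fig6_highAc_alt", "Akt pulses, 90% acetylation (body-text variant)",
    arms={"highAc_alt": {"Akt": 100, "SIRT": 100, "CBP": 1e3}},
    pre_eq_minutes=2520, events=_fig6_events(), t_end=3420, record_every=5,
    observables=SCENARIOS["fig6_lowAc"].observables))


# ---------------------------------------------------------------------------


def _network_for_arm(scenario: Scenario, overrides: dict) -> ReactionNetwork:
    cfg = single_ptm_baseline(**overrides)
    return build_network(cfg)


def _pre_equilibrated(network: ReactionNetwork, minutes: float,
                      integer: bool) -> ReactionNetwork:
    if minutes <= 0:
        return network
    state = apply_pre_equilibration(network, duration=minutes, integer=integer)
    net = copy.copy(network)
    net.initial_counts = np.asarray(state, dtype=float)
    return net


def _run_arm(scenario: Scenario, network: ReactionNetwork, method: str,
             seed: int | None, replicates: int) -> list[Trajectory]:
    trajectories = []
    n_paths = replicates if method == "ssa" else 1
    for rep in range(n_paths):
        rep_seed = None if seed is None else seed + rep
        settings = SimulationSettings(
            t_end=scenario.t_end, record_every=scenario.record_every,
            seed=rep_seed, method=method)
        trajectories.append(simulate(network, settings, scenario.events))
    return trajectories


def _observable_frame(scenario: Scenario, traj: Trajectory) -> pd.DataFrame:
    df = pd.DataFrame({"time": traj.times})
    for name in scenario.observables:
        try:
            df[name] = traj.observable(name)
        except KeyError:
            continue
    return df


def run_scenario(name: str, seed: int | None = None, method: str = "ode",
                 replicates: int = 10) -> dict:
    """Execute a registered scenario; returns trajectory and summary tables.

    The result dict maps arm name -> DataFrame of recorded observables
    (mean over replicates for SSA), plus a "summary" DataFrame whose
    content depends on the scenario (steady-state fractions, half-lives,
    transcription ratios).
    """
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; known: "
                       f"{sorted(SCENARIOS)}")
    scenario = SCENARIOS[name]

    if name == "fig4a":
        rows = []
        for arm, overrides in scenario.arms.items():
            net = _network_for_arm(scenario, overrides)
            state = steady_state(net)
            vals = net.counter_values(state)
            total = float(vals["total_foxo"])
            rows.append({"arm": arm, "akt": overrides["Akt"],
                         "nuclear_fraction": float(vals["total_nuclear"]) / total,
                         "cytoplasmic_fraction":
                             float(vals["total_cytoplasm"]) / total})
        return {"summary": pd.DataFrame(rows)}

    if name in ("fig4f", "fig4g"):
        rows = []
        for arm, overrides in scenario.arms.items():
            net = _network_for_arm(scenario, overrides)
            state = steady_state(net)
            idx = net.species_index()
            vals = net.counter_values(state)
            rows.append({"arm": arm,
                         "sod2_mrna_nuclear": float(state[idx["SOD2_mrna_nuc"]]),
                         "total_foxo": float(vals["total_foxo"])})
        df = pd.DataFrame(rows)
        ref_arm = "balanced" if name == "fig4f" else "AMPK_low"
        # per-molecule transcription ratio, so arms with different steady
        # totals remain comparable
        df["mrna_per_foxo"] = df["sod2_mrna_nuclear"] / df["total_foxo"]
        ref = float(df.loc[df["arm"] == ref_arm, "mrna_per_foxo"].iloc[0])
        df["normalized_transcription"] = df["mrna_per_foxo"] / ref
        return {"summary": df}

    if name == "fig5_scan":
        akt_grid = (1e2, 1e3, 1e4, 1e5)
        jnk_grid = (0.0, 1e3, 1e4, 5e4)
        rows = []
        for arm, overrides in scenario.arms.items():
            pp2a = overrides["PP2A"]
            for akt in akt_grid:
                for jnk in jnk_grid:
                    net = _network_for_arm(
                        scenario, {"Akt": akt, "JNK": jnk, "PP2A": pp2a})
                    state = steady_state(net)
                    vals = net.counter_values(state)
                    total = float(vals["total_foxo"])
                    rows.append({
                        "pp2a": pp2a, "akt": akt, "jnk": jnk,
                        "nuclear_fraction":
                            float(vals["total_nuclear"]) / total,
                        "cytoplasmic_fraction":
                            float(vals["total_cytoplasm"]) / total})
        return {"summary": pd.DataFrame(rows)}

    # time-course scenarios
    result: dict = {}
    rows = []
    for arm, overrides in scenario.arms.items():
        net = _network_for_arm(scenario, overrides)
        net = _pre_equilibrated(net, scenario.pre_eq_minutes,
                                integer=(method == "ssa"))
        trajectories = _run_arm(scenario, net, method, seed, replicates)
        frames = [_observable_frame(scenario, t) for t in trajectories]
        mean = sum(f.drop(columns="time") for f in frames) / len(frames)
        mean.insert(0, "time", frames[0]["time"])
        result[arm] = mean

        traj = trajectories[0]
        row = {"arm": arm, "replicates": len(trajectories)}
        total0 = float(traj.counter("total_foxo")[0])
        totalT = float(np.mean([t.counter("total_foxo")[-1]
                                for t in trajectories]))
        row["total_foxo_t0"] = total0
        row["total_foxo_end"] = totalT
        row["total_foxo_end_over_t0"] = totalT / total0 if total0 else np.nan
        half = time_to_half_initial(trajectories[0], "total_foxo") \
            if total0 > 0 and totalT < total0 else None
        row["half_life_min"] = np.nan if half is None else half
        try:
            fr0 = localization_fractions(trajectories[0], traj.times[0])
            frT = localization_fractions(trajectories[0], traj.times[-1])
            row["nuclear_fraction_t0"] = fr0["total_nuclear"]
            row["nuclear_fraction_end"] = frT["total_nuclear"]
        except ValueError:
            pass
        rows.append(row)
    result["summary"] = pd.DataFrame(rows)
    return result
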