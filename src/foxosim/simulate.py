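"""Stochastic (exact SSA) and deterministic (ODE) simulation of a network.

All reactions in these networks are zero- or first-order, so the
deterministic rate equations are affine, dx/dt = A x + b, and the ODE
solution is exactly the ensemble mean of the stochastic process.  Timed
dosing events reset enzyme copy numbers piecewise-constantly; integration
(or the jump process) is restarted at each event time with the state
preserved.

One integer seed governs a whole SSA trajectory; identical seeds give
bit-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .config import DoseEvent, ModelConfig
from .network import ReactionNetwork

__all__ = [
    "SimulationSettings",
    "Trajectory",
    "SsaTruncationError",
    "simulate",
    "simulate_ssa",
    "simulate_ode",
    "apply_pre_equilibration",
    "rate_matrices",
]


class SsaTruncationError(RuntimeError):
    """Raised when the SSA step guard is exceeded before t_end."""

    def __init__(self, reached_time: float, max_steps: int):
        self.reached_time = reached_time
        super().__init__(
            f"SSA exceeded {max_steps} steps at t={reached_time:g} min")


@dataclass
class SimulationSettings:
    t_end: float
    record_every: float = 1.0
    seed: int | None = None
    method: str = "ode"              # "ssa" | "ode"
    rtol: float = 1e-8
    atol: float = 1e-8
    max_ssa_steps: int = 50_000_000


@dataclass
class Trajectory:
    """Recorded copy numbers on a time grid, plus counter evaluations."""

    times: np.ndarray                # strictly increasing, minutes
    counts: np.ndarray               # shape (len(times), n_species)
    network: ReactionNetwork
    method: str
    seed: int | None = None
    events_applied: list[DoseEvent] = field(default_factory=list)

    def species(self, sid: str) -> np.ndarray:
        return self.counts[:, self.network.species_index()[sid]]

    def counter(self, name: str) -> np.ndarray:
        c = self.network.counter_by_name()[name]
        idx = self.network.species_index()
        members = [idx[s] for s in c.member_species]
        return self.counts[:, members].sum(axis=1)

    def observable(self, name: str) -> np.ndarray:
        """Counter or single species, by name."""
        if name in self.network.counter_by_name():
            return self.counter(name)
        return self.species(name)

    def state_at(self, time: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.times - time)))
        if abs(self.times[i] - time) > 1e-9 * max(1.0, abs(time)):
            raise ValueError(f"t={time} not on the recording grid")
        return self.counts[i]

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.counts, columns=self.network.species)
        df.insert(0, "time", self.times)
        for c in self.network.counters:
            idx = self.network.species_index()
            members = [idx[s] for s in c.member_species]
            df[c.name] = self.counts[:, members].sum(axis=1)
        return df

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write(f"# method\t{self.method}\n")
            fh.write(f"# seed\t{'' if self.seed is None else self.seed}\n")
            df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# compiled representation
# ---------------------------------------------------------------------------


def _compile(network: ReactionNetwork):
    """Index reactions into flat arrays for fast propensity evaluation."""
    index = network.species_index()
    enzyme_names = sorted(network.enzymes)
    enzyme_idx = {n: i for i, n in enumerate(enzyme_names)}
    R = len(network.reactions)
    k = np.zeros(R)
    reactant = np.full(R, -1, dtype=np.int64)
    enz = np.full(R, -1, dtype=np.int64)
    stoich_rows, stoich_cols, stoich_vals = [], [], []
    for j, r in enumerate(network.reactions):
        k[j] = r.rate_constant
        if len(r.reactants) > 1:
            raise ValueError("network is not elementary (>1 reactant)")
        if r.reactants:
            reactant[j] = index[r.reactants[0]]
        if r.enzyme is not None:
            enz[j] = enzyme_idx[r.enzyme]
        delta: dict[int, float] = {}
        for sid in r.reactants:
            delta[index[sid]] = delta.get(index[sid], 0) - 1
        for sid in r.products:
            delta[index[sid]] = delta.get(index[sid], 0) + 1
        for i, d in delta.items():
            if d != 0:
                stoich_rows.append(i)
                stoich_cols.append(j)
                stoich_vals.append(float(d))
    S = sp.csc_matrix((stoich_vals, (stoich_rows, stoich_cols)),
                      shape=(len(network.species), R))
    return enzyme_names, enzyme_idx, k, reactant, enz, S


def _base_rates(k, enz, enzyme_counts):
    """k_j x enzyme copy number (1 where no enzyme)."""
    scale = np.ones_like(k)
    mask = enz >= 0
    scale[mask] = enzyme_counts[enz[mask]]
    return k * scale


def rate_matrices(network: ReactionNetwork, enzyme_counts: dict | None = None):
    """Affine rate equations dx/dt = A x + b for the current enzyme levels.

    Returns (A, b) with A sparse CSC.  Used by the ODE integrator and by
    direct steady-state solves.
    """
    enzyme_names, _, k, reactant, enz, S = _compile(network)
    counts_map = dict(network.enzymes)
    if enzyme_counts:
        counts_map.update(enzyme_counts)
    evec = np.array([counts_map[n] for n in enzyme_names])
    base = _base_rates(k, enz, evec)
    n = len(network.species)
    first_order = reactant >= 0
    # A = S_first diag(base_first) P^T  where P maps species -> reactions
    jr = np.nonzero(first_order)[0]
    P = sp.csc_matrix((base[jr], (jr, reactant[jr])),
                      shape=(len(k), n))
    A = (S @ P).tocsc()
    b = np.asarray(S[:, ~first_order] @ base[~first_order]).ravel()
    return A, b


# ---------------------------------------------------------------------------
# event plumbing
# ---------------------------------------------------------------------------


def _check_events(events, t_end):
    events = sorted(events or [], key=lambda e: e.time)
    seen = set()
    for ev in events:
        if (ev.enzyme, ev.time) in seen:
            raise ValueError(
                f"two events on {ev.enzyme!r} at t={ev.time}")
        seen.add((ev.enzyme, ev.time))
        if ev.new_copy_number < 0:
            raise ValueError("event copy number must be >= 0")
    return [e for e in events if e.time <= t_end]


# ---------------------------------------------------------------------------
# SSA (direct method)
# ---------------------------------------------------------------------------


def simulate_ssa(network: ReactionNetwork, settings: SimulationSettings,
                 events: list[DoseEvent] | None = None) -> Trajectory:
    """Exact stochastic simulation (Gillespie direct method).

    Propensity of reaction j is k_j x enzyme_count x reactant count.
    At each dosing event the state is preserved, the enzyme count reset
    and propensities recomputed; the pending waiting time is redrawn,
    which is exact because exponential waiting times are memoryless.
    """
    events = _check_events(events, settings.t_end)
    enzyme_names, enzyme_idx, k, reactant, enz, S = _compile(network)
    evec = np.array([network.enzymes[n] for n in enzyme_names], dtype=float)
    x = np.asarray(np.rint(network.initial_counts), dtype=np.int64).copy()
    if np.any(x < 0):
        raise ValueError("initial counts must be >= 0")

    rng = np.random.default_rng(settings.seed)
    grid = np.arange(0.0, settings.t_end + 1e-12, settings.record_every)
    if grid[-1] < settings.t_end:
        grid = np.append(grid, settings.t_end)
    recorded = np.empty((len(grid), len(x)))
    recorded[0] = x
    next_rec = 1

    # permute reactions so first-order ones are a contiguous prefix: the
    # propensity refresh then runs on slices, not fancy indices
    order = np.argsort(reactant < 0, kind="stable")
    k, reactant, enz = k[order], reactant[order], enz[order]
    S = S[:, order]
    n1 = int((reactant >= 0).sum())
    ridx = reactant[:n1]

    Scsc = S.tocsc()
    col_idx = [Scsc.indices[Scsc.indptr[j]:Scsc.indptr[j + 1]]
               for j in range(S.shape[1])]
    col_val = [Scsc.data[Scsc.indptr[j]:Scsc.indptr[j + 1]].astype(np.int64)
               for j in range(S.shape[1])]

    base = _base_rates(k, enz, evec)
    prop = base.copy()
    cumprop = np.empty_like(prop)
    xf = x.astype(float)

    t = 0.0
    pending = list(events)
    steps = 0
    applied: list[DoseEvent] = []
    exp_draw = rng.exponential
    uni_draw = rng.random
    while True:
        next_event_t = pending[0].time if pending else np.inf
        boundary = min(next_event_t,
                       grid[next_rec] if next_rec < len(grid) else np.inf,
                       settings.t_end)

        np.multiply(base[:n1], xf[ridx], out=prop[:n1])
        np.cumsum(prop, out=cumprop)
        total = cumprop[-1] if len(cumprop) else 0.0
        t_jump = t + exp_draw(1.0 / total) if total > 0.0 else np.inf

        if t_jump >= boundary:
            t = boundary
            while next_rec < len(grid) and grid[next_rec] <= t + 1e-12:
                recorded[next_rec] = x
                next_rec += 1
            while pending and pending[0].time <= t + 1e-12:
                ev = pending.pop(0)
                evec[enzyme_idx[ev.enzyme]] = ev.new_copy_number
                base = _base_rates(k, enz, evec)
                prop = base.copy()
                applied.append(ev)
            if t >= settings.t_end - 1e-12:
                break
            continue

        t = t_jump
        j = int(np.searchsorted(cumprop, uni_draw() * total, side="right"))
        j = min(j, len(prop) - 1)
        x[col_idx[j]] += col_val[j]
        xf[col_idx[j]] = x[col_idx[j]]
        steps += 1
        if steps > settings.max_ssa_steps:
            raise SsaTruncationError(t, settings.max_ssa_steps)

    return Trajectory(times=grid, counts=recorded, network=network,
                      method="ssa", seed=settings.seed, events_applied=applied)


# ---------------------------------------------------------------------------
# ODE
# ---------------------------------------------------------------------------


def simulate_ode(network: ReactionNetwork, settings: SimulationSettings,
                 events: list[DoseEvent] | None = None) -> Trajectory:
    """Integrate the mass-action rate equations (counts as continuous variables).

    The network is affine-linear, so the constant sparse Jacobian A is
    passed to a stiff (BDF) integrator; integration restarts at each
    dosing event.  For this reaction class the solution equals the SSA
    ensemble mean exactly.
    """
    events = _check_events(events, settings.t_end)
    grid = np.arange(0.0, settings.t_end + 1e-12, settings.record_every)
    if grid[-1] < settings.t_end:
        grid = np.append(grid, settings.t_end)
    x = np.asarray(network.initial_counts, dtype=float).copy()
    recorded = np.empty((len(grid), len(x)))
    recorded[0] = x

    enzymes = dict(network.enzymes)
    applied: list[DoseEvent] = []
    pending = list(events)
    # apply any t<=0 doses before integrating
    while pending and pending[0].time <= 0.0:
        ev = pending.pop(0)
        enzymes[ev.enzyme] = ev.new_copy_number
        applied.append(ev)

    break_times = sorted({e.time for e in pending if e.time < settings.t_end})
    seg_bounds = [0.0] + break_times + [settings.t_end]
    for t0, t1 in zip(seg_bounds[:-1], seg_bounds[1:]):
        if t1 > t0:
            A, b = rate_matrices(network, enzymes)
            sol = solve_ivp(
                lambda t, y: A @ y + b, (t0, t1), x, method="BDF",
                dense_output=True, jac=lambda t, y: A,
                rtol=settings.rtol, atol=settings.atol)
            if not sol.success:
                raise RuntimeError(f"ODE integration failed: {sol.message}")
            seg_mask = (grid > t0 + 1e-12) & (grid <= t1 + 1e-12)
            if seg_mask.any():
                recorded[seg_mask] = sol.sol(grid[seg_mask]).T
            x = sol.y[:, -1]
        for ev in list(pending):
            if abs(ev.time - t1) <= 1e-12:
                enzymes[ev.enzyme] = ev.new_copy_number
                applied.append(ev)
                pending.remove(ev)

    return Trajectory(times=grid, counts=recorded, network=network,
                      method="ode", seed=None, events_applied=applied)


def simulate(network: ReactionNetwork, settings: SimulationSettings,
             events: list[DoseEvent] | None = None) -> Trajectory:
    """Dispatch to :func:`simulate_ssa` or :func:`simulate_ode` by method."""
    if settings.method == "ssa":
        return simulate_ssa(network, settings, events)
    if settings.method == "ode":
        return simulate_ode(network, settings, events)
    raise ValueError(f"unknown method {settings.method!r}")


def apply_pre_equilibration(network: ReactionNetwork,
                            config: ModelConfig | None = None,
                            settings: SimulationSettings | None = None,
                            duration: float | None = None,
                            integer: bool = False) -> np.ndarray:
    """Relax the model for a stated duration and return the final state.

    The relaxation runs under the network's current (pre-event) enzyme
    levels and returns the t=duration state for use as a t=0 initial
    condition.  Because the network is linear, the deterministic mean is
    exact, so the relaxation is integrated as an ODE; with ``integer``
    the result is rounded to whole molecules for SSA starts.
    """
    if duration is None:
        duration = config.pre_equilibration_minutes if config is not None else 0.0
    if duration < 0:
        raise ValueError("pre-equilibration duration must be >= 0")
    if duration == 0:
        state = np.asarray(network.initial_counts, dtype=float).copy()
    else:
        rtol = settings.rtol if settings is not None else 1e-8
        atol = settings.atol if settings is not None else 1e-8
        pre = SimulationSettings(t_end=duration, record_every=duration,
                                 method="ode", rtol=rtol, atol=atol)
        state = simulate_ode(network, pre).counts[-1].copy()
    if integer:
        state = np.asarray(np.rint(np.clip(state, 0, None)), dtype=np.int64)
    return state
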