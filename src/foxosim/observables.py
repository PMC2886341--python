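"""Derived quantities: localization and PTM fractions, half-lives,
steady states and scaled parameter sensitivities.

All fractions are of total protein; "total nuclear" counts the DNA-bound
pool together with the free nuclear pool, since both reside in the
nucleus.  Sensitivities are local elasticities (k/X) dX/dk computed by
central finite differences on a deterministic simulation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as spla

from .network import ReactionNetwork, Reaction
from .simulate import SimulationSettings, Trajectory, rate_matrices, simulate_ode

__all__ = [
    "localization_fractions",
    "ptm_fraction",
    "time_to_half_initial",
    "steady_state",
    "linear_steady_state",
    "SteadyStateError",
    "SensitivityRecord",
    "scaled_sensitivities",
]


class SteadyStateError(RuntimeError):
    """The model did not reach a (non-trivial) steady state in time."""


def localization_fractions(trajectory: Trajectory, time: float) -> dict:
    """Compartment fractions of total protein at a recorded time.

    Returns cytoplasm/nucleus/dna_bound fractions (summing to 1) plus
    total_nuclear = nucleus + dna_bound reported additionally.
    """
    state = trajectory.state_at(time)
    net = trajectory.network
    totals = {name: float(val) for name, val in
              net.counter_values(state).items()}
    total = totals["total_foxo"]
    if total <= 0:
        raise ValueError(f"zero total protein at t={time}: fractions undefined")
    out = {comp: totals[f"total_{comp}"] / total
           for comp in ("cytoplasm", "nucleus", "dna_bound")}
    out["total_nuclear"] = totals["total_nuclear"] / total
    return out


def ptm_fraction(trajectory: Trajectory, ptm_id: str, time: float) -> float:
    """Fraction of protein molecules carrying the given PTM flag, in [0, 1]."""
    net = trajectory.network
    counters = net.counter_by_name()
    if f"total_{ptm_id}" not in counters:
        raise KeyError(f"no counter for PTM {ptm_id!r}")
    state = trajectory.state_at(time)
    vals = net.counter_values(state)
    total = float(vals["total_foxo"])
    if total <= 0:
        raise ValueError(f"zero total protein at t={time}: fraction undefined")
    return float(vals[f"total_{ptm_id}"]) / total


def time_to_half_initial(trajectory: Trajectory, observable: str
                         ) -> float | None:
    """First time the observable falls to <= 50% of its t=0 value.

    Linearly interpolated between grid points; returns None if the level
    is never reached within the trajectory.
    """
    y = np.asarray(trajectory.observable(observable), dtype=float)
    t = trajectory.times
    y0 = y[0]
    if y0 <= 0:
        raise ValueError(f"non-positive initial value for {observable!r}")
    target = 0.5 * y0
    below = np.nonzero(y <= target)[0]
    below = below[below > 0]
    if len(below) == 0:
        return None
    i = below[0]
    if y[i - 1] == y[i]:
        return float(t[i])
    frac = (y[i - 1] - target) / (y[i - 1] - y[i])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def linear_steady_state(network: ReactionNetwork,
                        enzyme_counts: dict | None = None) -> np.ndarray:
    """Direct sparse solve of A x = -b for the stationary state.

    Species without any outflow (e.g. unreachable terminal forms) are held
    at zero; raises :class:`SteadyStateError` if such a species receives
    inflow, or if the active subsystem is singular (no steady state).
    """
    A, b = rate_matrices(network, enzyme_counts)
    A = A.tocsc()
    active = np.asarray(A.diagonal() < 0)
    if not active.all():
        inflow = np.abs(A[~active][:, active]).sum() + np.abs(b[~active]).sum()
        if inflow > 0:
            raise SteadyStateError(
                "species without outflow receive inflow: no steady state")
    x = np.zeros(A.shape[0])
    sub = A[active][:, active].tocsc()
    with np.errstate(all="raise"):
        try:
            x[active] = spla.spsolve(sub, -b[active])
        except Exception as exc:
            raise SteadyStateError(f"singular rate matrix: {exc}") from exc
    if not np.all(np.isfinite(x)):
        raise SteadyStateError("singular rate matrix: no finite steady state")
    return x


def steady_state(network: ReactionNetwork, t_start: float = 2000.0,
                 t_cap: float = 1e7, tol: float = 1e-7,
                 rtol: float = 1e-9, atol: float = 1e-9) -> np.ndarray:
    """Stationary state by long-time integration with stationarity detection.

    Integrates over doubling horizons starting at ``t_start`` minutes; the
    state is stationary when doubling the horizon changes no component by
    more than ``tol`` relative (max |dx| / (1 + |x|)) AND the rate of
    change is decaying.  Raises :class:`SteadyStateError` past ``t_cap``
    — some dosing regimes of this model have no non-trivial steady state
    (e.g. synthesis with degradation fully disabled grows without bound).
    """
    x = np.asarray(network.initial_counts, dtype=float)
    A, b = rate_matrices(network)
    horizon = t_start
    while horizon <= t_cap:
        net2 = copy.copy(network)
        net2.initial_counts = x
        settings = SimulationSettings(t_end=horizon, record_every=horizon,
                                      method="ode", rtol=rtol, atol=atol)
        x_new = simulate_ode(net2, settings).counts[-1]
        delta = np.abs(x_new - x) / (1.0 + np.abs(x_new))
        x = x_new
        if delta.max() < tol:
            deriv = np.abs(A @ x + b) / (1.0 + np.abs(x))
            if deriv.max() * horizon < 1.0:
                return x
        horizon *= 2
    raise SteadyStateError(
        f"no steady state within t={t_cap:g} min "
        f"(the model may not have a non-trivial steady state)")


@dataclass(frozen=True)
class SensitivityRecord:
    parameter: str
    target: str
    time: float
    scaled_sensitivity: float | None   # None where the target is ~0 (undefined)


def _perturbed_network(network: ReactionNetwork, parameter: str, factor: float
                       ) -> ReactionNetwork:
    """Copy of the network with one parameter scaled.

    ``parameter`` is either an enzyme name (scales its copy number) or a
    reaction-kind[:qualifier] selector scaling the rate constants of the
    matching reactions, e.g. "transport:cyt_to_nuc"-style selectors are
    expressed by reaction id prefix match or kind.
    """
    net = copy.copy(network)
    if parameter in net.enzymes:
        net.enzymes = dict(net.enzymes)
        net.enzymes[parameter] *= factor
        return net
    matched = False
    new_reactions: list[Reaction] = []
    for r in net.reactions:
        if r.kind == parameter or r.id == parameter:
            new_reactions.append(Reaction(
                id=r.id, kind=r.kind, reactants=r.reactants,
                products=r.products, rate_constant=r.rate_constant * factor,
                enzyme=r.enzyme))
            matched = True
        else:
            new_reactions.append(r)
    if not matched:
        raise KeyError(f"unknown parameter {parameter!r}: not an enzyme, "
                       f"reaction kind or reaction id")
    net.reactions = new_reactions
    return net


def scaled_sensitivities(network: ReactionNetwork, parameters, targets,
                         time: float, rel_step: float = 0.01,
                         floor: float = 1e-9,
                         settings: SimulationSettings | None = None
                         ) -> list[SensitivityRecord]:
    """Local scaled sensitivities (k/X) dX/dk at a fixed evaluation time.

    Central finite differences with a +/- ``rel_step`` relative
    perturbation of each parameter; ``targets`` are counter or species
    names.  Records with the target below ``floor`` at the evaluation time
    are flagged undefined (scaled_sensitivity None).
    """
    if settings is None:
        settings = SimulationSettings(t_end=time, record_every=time,
                                      method="ode")

    def target_values(net: ReactionNetwork) -> dict[str, float]:
        traj = simulate_ode(net, settings)
        return {name: float(traj.observable(name)[-1]) for name in targets}

    base_vals = target_values(network)
    records: list[SensitivityRecord] = []
    for param in parameters:
        up = target_values(_perturbed_network(network, param, 1 + rel_step))
        dn = target_values(_perturbed_network(network, param, 1 - rel_step))
        for name in targets:
            x = base_vals[name]
            if abs(x) < floor:
                records.append(SensitivityRecord(param, name, time, None))
                continue
            # (k/X) dX/dk with dk = 2*rel_step*k
            s = (up[name] - dn[name]) / (2 * rel_step * x)
            records.append(SensitivityRecord(param, name, time, float(s)))
    return records


def sensitivity_table(records) -> str:
    """Tab-separated dump: parameter, target, time, scaled_sensitivity."""
    lines = ["parameter\ttarget\ttime\tscaled_sensitivity"]
    for r in records:
        val = "NA" if r.scaled_sensitivity is None else f"{r.scaled_sensitivity:.6g}"
        lines.append(f"{r.parameter}\t{r.target}\t{r.time:g}\t{val}")
    return "\n".join(lines) + "\n"
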