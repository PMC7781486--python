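"""Gillespie direct-method simulation of the BLADE network.

Each run starts from 1000 copies of the unrecombined address Z00 (and
nothing else), draws exponential waiting times from the total reaction
propensity, fires one reaction per step chosen proportionally to its
propensity, and stops after a fixed number of reaction events (default
10000), when the total propensity reaches zero, or at an optional time
cap.  The inner loop is compiled with numba; a fixed seed gives a
bit-reproducible trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model import ADDRESS_IDX, SPECIES, ReactionNetwork

__all__ = [
    "SSAConfig",
    "Trajectory",
    "EmptyPopulationError",
    "gillespie_run",
    "gillespie_final",
    "final_occupancy",
    "default_initial_state",
]


class EmptyPopulationError(RuntimeError):
    """All address DNA has diluted away; occupancy fractions are undefined."""


def default_initial_state(n_dna: int = 1000) -> np.ndarray:
    """All species at 0 except Z00 at ``n_dna`` copies."""
    x0 = np.zeros(len(SPECIES), dtype=np.int64)
    x0[SPECIES.index("Z00")] = n_dna
    return x0


@dataclass(frozen=True)
class SSAConfig:
    """Run settings for one stochastic simulation."""

    initial_state: np.ndarray = field(default_factory=default_initial_state)
    max_reactions: int = 10000
    max_time: float = np.inf  # optional wall guard in simulated seconds
    seed: int = 0

    def __post_init__(self) -> None:
        x0 = np.asarray(self.initial_state, dtype=np.int64)
        if x0.shape != (len(SPECIES),) or (x0 < 0).any():
            raise ValueError("initial_state must be 10 non-negative counts")
        object.__setattr__(self, "initial_state", x0)
        if self.max_reactions < 1:
            raise ValueError("max_reactions must be >= 1")


@dataclass(frozen=True)
class Trajectory:
    """Event times and the species counts after each event.

    ``times[0] = 0`` holds the initial state; event k is described by
    ``times[k]``/``states[k]``.
    """

    times: np.ndarray  # float64[n_events + 1]
    states: np.ndarray  # int64[n_events + 1, 10]

    @property
    def n_events(self) -> int:
        return len(self.times) - 1

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


@njit(cache=True)
def _propensities(x, rates, r1, r2, comb2, guard_sp, guard_min, out):
    total = 0.0
    for j in range(rates.shape[0]):
        a = rates[j]
        if a > 0.0:
            i1 = r1[j]
            if i1 >= 0:
                c = x[i1]
                if comb2[j]:
                    a *= c * (c - 1) * 0.5
                else:
                    a *= c
            i2 = r2[j]
            if i2 >= 0:
                a *= x[i2]
            g = guard_sp[j]
            if g >= 0 and x[g] < guard_min[j]:
                a = 0.0
        out[j] = a
        total += a
    return total


@njit(cache=True)
def _gillespie(
    rates, r1, r2, comb2, guard_sp, guard_min, stoich,
    x0, max_reactions, max_time, seed, record,
):
    np.random.seed(seed)
    n_sp = x0.shape[0]
    n_rx = rates.shape[0]
    x = x0.copy()
    props = np.zeros(n_rx)
    if record:
        times = np.zeros(max_reactions + 1)
        states = np.zeros((max_reactions + 1, n_sp), dtype=np.int64)
        states[0] = x
    else:
        times = np.zeros(1)
        states = np.zeros((1, n_sp), dtype=np.int64)
    t = 0.0
    n_events = 0
    for _ in range(max_reactions):
        total = _propensities(x, rates, r1, r2, comb2, guard_sp, guard_min, props)
        if total <= 0.0:
            break
        tau = -np.log(np.random.random()) / total
        if t + tau > max_time:
            t = max_time
            break
        t += tau
        # select reaction proportionally to propensity
        thresh = np.random.random() * total
        acc = 0.0
        j = n_rx - 1
        for k in range(n_rx):
            acc += props[k]
            if acc >= thresh:
                j = k
                break
        for s in range(n_sp):
            x[s] += stoich[j, s]
        n_events += 1
        if record:
            times[n_events] = t
            states[n_events] = x
    if not record:
        states[0] = x
        times[0] = t
    return times, states, n_events, t


def gillespie_run(network: ReactionNetwork, config: SSAConfig) -> Trajectory:
    """Simulate one full trajectory, recording the state after every event."""
    times, states, n_events, _ = _gillespie(
        network.rates, network.r1, network.r2, network.comb2,
        network.guard_sp, network.guard_min, network.stoich,
        config.initial_state, config.max_reactions, config.max_time,
        np.uint32(config.seed), True,
    )
    return Trajectory(times=times[: n_events + 1].copy(), states=states[: n_events + 1].copy())


def gillespie_final(network: ReactionNetwork, config: SSAConfig) -> tuple[np.ndarray, float, int]:
    """Simulate without recording; return (final state, end time, event count).

    Used for ensembles where only the endpoint matters.
    """
    times, states, n_events, t_end = _gillespie(
        network.rates, network.r1, network.r2, network.comb2,
        network.guard_sp, network.guard_min, network.stoich,
        config.initial_state, config.max_reactions, config.max_time,
        np.uint32(config.seed), False,
    )
    return states[0].copy(), t_end, n_events


def final_occupancy(traj: Trajectory) -> tuple[float, float, float, float]:
    """Fractions of surviving address DNA in (Z00, Z10, Z01, Z11) at the end.

    Raises :class:`EmptyPopulationError` if no address DNA survives.
    """
    if traj.n_events < 0 or len(traj.states) == 0:
        raise ValueError("empty trajectory")
    counts = np.array([traj.final_state[i] for i in ADDRESS_IDX], dtype=float)
    total = counts.sum()
    if total == 0:
        raise EmptyPopulationError("all address DNA has diluted away")
    f = counts / total
    return (f[0], f[1], f[2], f[3])


def occupancy_from_state(state: np.ndarray) -> np.ndarray:
    """Address fractions from a raw state vector; (1,0,0,0) if DNA is extinct.

    Address DNA can only leave the system one copy at a time through
    dilution of Z00, so a run that loses all DNA necessarily lost its
    last copy from Z00; the population composition just before
    extinction is therefore pure Z00.  Returning that composition keeps
    the no-input condition (where dilution is the only active reaction)
    scoreable instead of undefined.
    """
    counts = np.array([state[i] for i in ADDRESS_IDX], dtype=float)
    total = counts.sum()
    if total == 0:
        return np.array([1.0, 0.0, 0.0, 0.0])
    return counts / total
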