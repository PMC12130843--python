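"""Permeation events, conductance, replica aggregation and state populations.

A complete permeation event is a full traversal of the pore: an ion last seen
in the intracellular bath (below SCav) that reaches the extracellular bath
(above S0) counts as one outward event, and symmetrically for inward events.
The two-gate construction (an ion must touch one bath and then the other)
makes the count immune to boundary flicker at the site edges.

Each permeating ion carries exactly one elementary charge regardless of its
scaled partial charge: charge scaling is a mean-field treatment of electronic
polarization, while the transported physical charge is the full +1 e.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .sfstate import BATH_ABOVE, BATH_BELOW, StateTrajectory
from .topology import E_CHARGE

__all__ = [
    "PermeationEvent",
    "ConductanceEstimate",
    "IVPoint",
    "detect_permeation_events",
    "current_from_events",
    "conductance_from_events",
    "aggregate_replicas",
    "state_populations",
    "salt_concentration",
    "WATER_MOLARITY",
]

WATER_MOLARITY = 55.5  # mol/L of pure water


@dataclass(frozen=True)
class PermeationEvent:
    ion_id: object
    completion_time: float  # ns (frame at which the far bath is first reached)
    direction: int  # +1 outward (toward +z), -1 inward

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")


@dataclass(frozen=True)
class ConductanceEstimate:
    mean: float  # pS
    sem: float  # pS
    n_replicas: int
    voltage: float  # mV

    def __post_init__(self) -> None:
        if self.n_replicas < 1:
            raise ValueError("need at least one replica")
        if self.sem < 0:
            raise ValueError("sem must be non-negative")


@dataclass(frozen=True)
class IVPoint:
    voltage: float  # mV
    current: float  # pA
    current_sem: float  # pA


def detect_permeation_events(traj: StateTrajectory) -> list[PermeationEvent]:
    """Complete traversals from the per-ion site history of a StateTrajectory.

    For each ion a last-touched-gate flag is tracked: seeing the ion in the
    far bath after it last touched the near bath records one event, at the
    time of the frame where the far bath is first reached.  Frames where the
    ion sits in the filter, or laterally outside the pore at mid height,
    leave the flag unchanged.  An ion that retreats to the bath it came from
    records nothing.
    """
    if traj.ion_site_index is None:
        raise ValueError(
            "trajectory carries no per-ion site history; discretize coordinates "
            "first (codes alone cannot attribute traversals to ions)"
        )
    last_gate: dict = {}
    events: list[PermeationEvent] = []
    for t, site_map in zip(traj.times, traj.ion_site_index):
        for ion_id, loc in site_map.items():
            if loc == BATH_BELOW:
                if last_gate.get(ion_id) == BATH_ABOVE:
                    events.append(PermeationEvent(ion_id, float(t), -1))
                last_gate[ion_id] = BATH_BELOW
            elif loc == BATH_ABOVE:
                if last_gate.get(ion_id) == BATH_BELOW:
                    events.append(PermeationEvent(ion_id, float(t), +1))
                last_gate[ion_id] = BATH_ABOVE
    return events


def current_from_events(n_events: float, duration: float) -> float:
    """Single-channel current in pA from a net signed event count over ``duration`` ns."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    # one elementary charge per permeating ion, regardless of the scaled partial charge
    return n_events * E_CHARGE / (duration * 1e-9) * 1e12


def conductance_from_events(n_events: float, duration: float, voltage: float) -> float:
    """Conductance in pS: ``g = I / V`` with ``I = n e / t``.

    ``n_events`` is the net signed count (outward minus inward); outward
    events at positive voltage give positive conductance.
    """
    if voltage == 0:
        raise ValueError("conductance undefined at zero voltage (current still is)")
    current_pA = current_from_events(n_events, duration)
    return current_pA / voltage * 1e3  # pA/mV -> pS


def aggregate_replicas(per_replica_conductances, voltage: float) -> ConductanceEstimate:
    """Mean and SEM (sd/sqrt(N)) of per-replica conductances at one voltage."""
    g = np.asarray(list(per_replica_conductances), dtype=float)
    if g.size == 0:
        raise ValueError("need at least one replica")
    mean = float(g.mean())
    sem = float(g.std(ddof=1) / math.sqrt(g.size)) if g.size > 1 else 0.0
    return ConductanceEstimate(mean=mean, sem=sem, n_replicas=int(g.size), voltage=voltage)


def state_populations(
    traj: StateTrajectory,
    n_boot: int = 1000,
    seed: int | None = None,
    block_length: int = 1,
    ci: float = 0.95,
) -> dict[str, tuple[float, tuple[float, float]]]:
    """SF state populations with percentile-bootstrap confidence intervals.

    Frames are resampled with replacement (``block_length > 1`` resamples
    blocks of consecutive frames, for correlated data); the CI is the
    percentile interval of the bootstrap population fractions.  Fractions sum
    to 1 over the observed codes.
    """
    if traj.n_frames < 1:
        raise ValueError("empty trajectory")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100 for a meaningful CI")
    if block_length < 1:
        raise ValueError("block_length must be >= 1")
    codes = np.asarray(traj.codes)
    states, labels = np.unique(codes, return_inverse=True)
    n = codes.size
    k = states.size
    rng = np.random.default_rng(seed)
    fractions = np.bincount(labels, minlength=k) / n

    if block_length == 1:
        # frame-level bootstrap of iid categories == multinomial resampling
        boot = rng.multinomial(n, fractions, size=n_boot) / n
    else:
        n_blocks = math.ceil(n / block_length)
        boot = np.empty((n_boot, k))
        for b in range(n_boot):
            starts = rng.integers(0, n, size=n_blocks)
            idx = (starts[:, None] + np.arange(block_length)[None, :]).ravel() % n
            idx = idx[:n]
            boot[b] = np.bincount(labels[idx], minlength=k) / n
    alpha = (1.0 - ci) / 2.0
    lo = np.quantile(boot, alpha, axis=0)
    hi = np.quantile(boot, 1.0 - alpha, axis=0)
    return {
        str(states[i]): (float(fractions[i]), (float(lo[i]), float(hi[i])))
        for i in range(k)
    }


def salt_concentration(n_cations: int, n_waters: int) -> float:
    """Salt concentration (mol/L) from cation and water counts in a box.

    Uses the molarity of pure water (55.5 mol/L):
    ``c = n_cations / n_waters * 55.5``.
    """
    if n_waters <= 0:
        raise ValueError("need a positive number of water molecules")
    if n_cations < 0:
        raise ValueError("cation count cannot be negative")
    return n_cations / n_waters * WATER_MOLARITY
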