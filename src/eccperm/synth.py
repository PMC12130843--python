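"""Synthetic trajectories with known ground truth.

Two generators make every analysis stage testable without MD output:

* :func:`simulate_ctmc` — an exact (Gillespie) continuous-time Markov chain
  over arbitrary state labels, observed at a uniform stride, with the full
  jump log retained.  Used to validate MFPT/rate estimation, lumping and
  bootstrap population recovery against analytic answers.
* :func:`simulate_channel` — a coordinate-level caricature of direct
  knock-on permeation: ions hop single-file between the S0-SCav site centers
  of a :class:`~eccperm.sfstate.SiteGeometry` with voltage-biased rates and a
  one-ion-per-site exclusion rule, waters fill ion-free sites, and emitted
  coordinates sit at site centers plus sub-boundary jitter.  The generator
  records its own per-frame occupancy codes and permeation events, so
  discretization and event detection can be checked for exact round-trip
  recovery.

Neither generator models energetics; they emulate the *kinematics* the
analysis layer consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .permeation import PermeationEvent
from .sfstate import (
    BATH_ABOVE,
    BATH_BELOW,
    FrameCoordinates,
    SiteGeometry,
    StateTrajectory,
)

__all__ = [
    "CTMCSpec",
    "ChannelSimSpec",
    "ChannelSimResult",
    "simulate_ctmc",
    "simulate_channel",
    "stationary_distribution",
    "demo_mechanism_ctmc_spec",
    "demo_channel_spec",
]


def stationary_distribution(rate_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution pi of a CTMC generator (pi Q = 0, sum pi = 1)."""
    Q = np.asarray(rate_matrix, dtype=float)
    n = Q.shape[0]
    if np.allclose(np.diag(Q), 0.0):
        off = Q - np.diag(np.diag(Q))
        Q = off - np.diag(off.sum(axis=1))
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return pi


@dataclass
class CTMCSpec:
    """Generative spec for a state-level chain.

    ``rate_matrix`` is the generator in 1/ns: off-diagonal entries are jump
    rates, each diagonal entry is minus its row's off-diagonal sum (a matrix
    with zero diagonal is completed automatically).
    """

    states: list[str]
    rate_matrix: np.ndarray  # 1/ns
    stride: float  # ns
    duration: float  # ns
    seed: int | None = None
    initial_state: str | None = None  # default: first state; "stationary" to sample

    def __post_init__(self) -> None:
        Q = np.array(self.rate_matrix, dtype=float)
        n = len(self.states)
        if Q.shape != (n, n):
            raise ValueError(f"rate matrix shape {Q.shape} does not match {n} states")
        off = Q - np.diag(np.diag(Q))
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be non-negative")
        if np.allclose(np.diag(Q), 0.0):
            Q = off - np.diag(off.sum(axis=1))
        if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-9):
            raise ValueError("generator rows must sum to zero")
        if self.duration <= self.stride or self.stride <= 0:
            raise ValueError("need duration > stride > 0")
        self.rate_matrix = Q


def simulate_ctmc(spec: CTMCSpec) -> tuple[StateTrajectory, list[tuple[float, str, str]]]:
    """Exact stochastic simulation of the chain, observed at a uniform stride.

    Returns the observed :class:`StateTrajectory` and the ground-truth jump
    log ``[(time_ns, from_state, to_state), ...]``.  An absorbing state simply
    holds for the rest of the requested duration.
    """
    rng = np.random.default_rng(spec.seed)
    Q = spec.rate_matrix
    n = len(spec.states)
    if spec.initial_state is None:
        s = 0
    elif spec.initial_state == "stationary":
        s = int(rng.choice(n, p=stationary_distribution(Q)))
    else:
        s = spec.states.index(spec.initial_state)

    jump_times: list[float] = []
    jump_to: list[int] = []
    jumps: list[tuple[float, str, str]] = []
    t = 0.0
    cur = s
    while True:
        out_rate = -Q[cur, cur]
        if out_rate <= 0.0:
            break  # absorbing state: trajectory stays put
        t += rng.exponential(1.0 / out_rate)
        if t >= spec.duration:
            break
        probs = Q[cur].clip(min=0.0)
        probs[cur] = 0.0
        nxt = int(rng.choice(n, p=probs / probs.sum()))
        jumps.append((t, spec.states[cur], spec.states[nxt]))
        jump_times.append(t)
        jump_to.append(nxt)
        cur = nxt

    frame_times = np.arange(0.0, spec.duration + spec.stride * 0.5, spec.stride)
    frame_times = frame_times[frame_times <= spec.duration + 1e-12]
    k = np.searchsorted(np.asarray(jump_times), frame_times, side="right")
    state_after = np.concatenate(([s], np.asarray(jump_to, dtype=int)))
    labels = state_after[k]
    codes = [spec.states[i] for i in labels]
    return StateTrajectory(times=frame_times, codes=codes), jumps


# --------------------------------------------------------------------------
# coordinate-level channel generator

@dataclass
class ChannelSimSpec:
    """Generative spec for a single-file ion-hopping channel trajectory.

    Rates are in 1/ns.  "Outward" is +z, i.e. from SCav (site index 5) toward
    S0 (index 0) and out into the extracellular bath; ``hop_rate_fwd`` biases
    hops outward relative to ``hop_rate_rev``, emulating a positive applied
    voltage.  At most one ion occupies a site.  When ``recycle`` is set, ions
    that left through one bath while entry happens only at the other are
    returned to the entry-side pool at the next frame boundary — after being
    recorded in their exit bath at least once — which keeps the flux in
    steady state and makes ground-truth events exactly recoverable from the
    observed frames.
    """

    geometry: SiteGeometry
    n_ions: int = 8
    hop_rate_fwd: float = 20.0
    hop_rate_rev: float = 2.0
    entry_rate_bottom: float = 10.0
    exit_rate_top: float = 20.0
    entry_rate_top: float = 0.0
    exit_rate_bottom: float = 0.0
    water_fill_prob: float = 0.7
    n_bulk_waters: int = 8
    duration: float = 100.0  # ns
    stride: float = 0.05  # ns
    seed: int | None = None
    jitter_frac: float = 0.25  # of each site's half-width; < 0.5 keeps sites unambiguous
    recycle: bool = True
    box: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        for name in ("hop_rate_fwd", "hop_rate_rev", "entry_rate_bottom",
                     "exit_rate_top", "entry_rate_top", "exit_rate_bottom"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_ions < 1:
            raise ValueError("need at least one ion")
        if not 0.0 < self.jitter_frac < 0.5:
            raise ValueError("jitter_frac must lie in (0, 0.5) to keep sites unambiguous")
        if self.duration <= self.stride or self.stride <= 0:
            raise ValueError("need duration > stride > 0")
        if not 0.0 <= self.water_fill_prob <= 1.0:
            raise ValueError("water_fill_prob must be a probability")
        if self.box is None:
            g = self.geometry
            lx = 2.0 * g.axis_xy[0] if g.axis_xy[0] > 0 else 4.0
            ly = 2.0 * g.axis_xy[1] if g.axis_xy[1] > 0 else 4.0
            self.box = (lx, ly, g.z_top + 1.5)


@dataclass
class ChannelSimResult:
    """Frames plus the generator's ground truth."""

    frames: list[FrameCoordinates]
    truth: StateTrajectory  # ground-truth codes and per-ion site labels
    events: list[PermeationEvent]  # ground-truth completed traversals
    spec: ChannelSimSpec = field(repr=False, default=None)

    @property
    def net_event_count(self) -> int:
        return sum(e.direction for e in self.events)


def _site_jitter(rng, lo: float, hi: float, frac: float) -> float:
    half = 0.5 * (hi - lo)
    return rng.uniform(-frac * half, frac * half)


def simulate_channel(spec: ChannelSimSpec) -> ChannelSimResult:
    """Simulate single-file biased hopping and emit coordinates + ground truth."""
    rng = np.random.default_rng(spec.seed)
    g = spec.geometry
    intervals = g.site_intervals()
    centers = g.site_centers()
    box = np.asarray(spec.box, dtype=float)
    ax, ay = g.axis_xy

    occ: list[object | None] = [None] * 6  # site index -> ion id
    below = [f"ion{i:04d}" for i in range(spec.n_ions)]
    above: list[object] = []
    # recycled ions wait here for one frame so they are observed in their new
    # bath before becoming eligible for entry
    below_staging: list[object] = []
    above_staging: list[object] = []
    entered_side: dict[object, str] = {}
    events: list[PermeationEvent] = []

    def possible_moves():
        moves = []
        for i in range(6):
            ion = occ[i]
            if ion is None:
                continue
            if i > 0 and occ[i - 1] is None and spec.hop_rate_fwd > 0:
                moves.append((spec.hop_rate_fwd, ("hop", i, i - 1)))
            if i == 0 and spec.exit_rate_top > 0:
                moves.append((spec.exit_rate_top, ("exit_top",)))
            if i < 5 and occ[i + 1] is None and spec.hop_rate_rev > 0:
                moves.append((spec.hop_rate_rev, ("hop", i, i + 1)))
            if i == 5 and spec.exit_rate_bottom > 0:
                moves.append((spec.exit_rate_bottom, ("exit_bottom",)))
        if below and occ[5] is None and spec.entry_rate_bottom > 0:
            moves.append((spec.entry_rate_bottom, ("enter_bottom",)))
        if above and occ[0] is None and spec.entry_rate_top > 0:
            moves.append((spec.entry_rate_top, ("enter_top",)))
        return moves

    def apply(move, t: float) -> None:
        kind = move[0]
        if kind == "hop":
            _, i, j = move
            occ[j], occ[i] = occ[i], None
        elif kind == "enter_bottom":
            ion = below.pop(0)
            occ[5] = ion
            entered_side[ion] = "below"
        elif kind == "enter_top":
            ion = above.pop(0)
            occ[0] = ion
            entered_side[ion] = "above"
        elif kind == "exit_top":
            ion = occ[0]
            occ[0] = None
            above.append(ion)
            if entered_side.pop(ion, None) == "below":
                events.append(PermeationEvent(ion, t, +1))
        elif kind == "exit_bottom":
            ion = occ[5]
            occ[5] = None
            below.append(ion)
            if entered_side.pop(ion, None) == "above":
                events.append(PermeationEvent(ion, t, -1))

    def bath_position(side: str, k: int) -> np.ndarray:
        # outside every site by construction: beyond the z caps
        if side == "below":
            z = g.z_bottom - 0.3 - rng.uniform(0.0, 0.2)
        else:
            z = g.z_top + 0.3 + rng.uniform(0.0, 0.2)
        return np.array([ax + 0.1 * (k % 3 - 1), ay + 0.1 * (k // 3 % 3 - 1), z])

    frame_times = np.arange(0.0, spec.duration + spec.stride * 0.5, spec.stride)
    frame_times = frame_times[frame_times <= spec.duration + 1e-12]

    frames: list[FrameCoordinates] = []
    codes: list[str] = []
    site_maps: list[dict] = []
    lateral_max = 0.5 * g.axis_radius
    generation = 0  # recycled-ion rename counter

    def record(t: float) -> None:
        ion_pos: dict[object, np.ndarray] = {}
        ion_site: dict[object, object] = {}
        for i in range(6):
            ion = occ[i]
            if ion is None:
                continue
            lo, hi = intervals[i]
            r = lateral_max * math.sqrt(rng.uniform())
            th = rng.uniform(0.0, 2.0 * math.pi)
            ion_pos[ion] = np.array(
                [ax + r * math.cos(th), ay + r * math.sin(th),
                 centers[i] + _site_jitter(rng, lo, hi, spec.jitter_frac)]
            )
            ion_site[ion] = i
        for k, ion in enumerate(below + below_staging):
            ion_pos[ion] = bath_position("below", k)
            ion_site[ion] = BATH_BELOW
        for k, ion in enumerate(above + above_staging):
            ion_pos[ion] = bath_position("above", k)
            ion_site[ion] = BATH_ABOVE

        waters = []
        letters = []
        for i in range(6):
            if occ[i] is not None:
                letters.append("K")
                continue
            if rng.uniform() < spec.water_fill_prob:
                lo, hi = intervals[i]
                r = lateral_max * math.sqrt(rng.uniform())
                th = rng.uniform(0.0, 2.0 * math.pi)
                waters.append(
                    [ax + r * math.cos(th), ay + r * math.sin(th),
                     centers[i] + _site_jitter(rng, lo, hi, spec.jitter_frac)]
                )
                letters.append("W")
            else:
                letters.append("0")
        for k in range(spec.n_bulk_waters):
            # bulk waters in the baths, laterally clear of the pore cylinder
            side = "below" if k % 2 == 0 else "above"
            p = bath_position(side, k)
            p[0] += 2.5 * g.axis_radius
            waters.append(p.tolist())

        frames.append(
            FrameCoordinates(
                time=t,
                ion_positions=ion_pos,
                water_o_positions=np.asarray(waters, dtype=float).reshape(-1, 3),
                sf_oxygen_z=np.asarray(g.plane_z),
                box=box,
            )
        )
        codes.append("".join(letters))
        site_maps.append(ion_site)

    t = 0.0
    for ft in frame_times:
        # advance the jump process to the frame time (exponential clocks are
        # memoryless, so re-drawing after each recorded frame is exact)
        while True:
            moves = possible_moves()
            total = sum(r for r, _ in moves)
            if total <= 0.0:
                break
            dt = rng.exponential(1.0 / total)
            if t + dt > ft:
                break
            t += dt
            u = rng.uniform(0.0, total)
            acc = 0.0
            for r, mv in moves:
                acc += r
                if u <= acc:
                    apply(mv, t)
                    break
        t = ft
        record(ft)
        # staged ions have now been observed in their bath once: activate them
        below.extend(below_staging)
        below_staging.clear()
        above.extend(above_staging)
        above_staging.clear()
        if spec.recycle:
            # Return exited ions to the entry-side pool under a fresh identity
            # (a grand-canonical bath swap): the exited ion's history ends in
            # its exit bath and a new ion appears in the entry bath, so no id
            # ever jumps between baths and the two-gate event detector
            # recovers the ground-truth events exactly.
            if spec.entry_rate_top == 0.0 and spec.entry_rate_bottom > 0.0 and above:
                for ion in above:
                    generation += 1
                    below_staging.append(f"{ion.split('r')[0]}r{generation}")
                above.clear()
            elif spec.entry_rate_bottom == 0.0 and spec.entry_rate_top > 0.0 and below:
                for ion in below:
                    generation += 1
                    above_staging.append(f"{ion.split('r')[0]}r{generation}")
                below.clear()

    truth = StateTrajectory(times=frame_times, codes=codes, ion_site_index=site_maps)
    return ChannelSimResult(frames=frames, truth=truth, events=events, spec=spec)


# --------------------------------------------------------------------------
# canonical demo scenarios

def demo_mechanism_ctmc_spec(
    seed: int | None = 0, duration: float = 2000.0, stride: float = 0.1
) -> CTMCSpec:
    """Driven 3-state cycle over realistic occupancy codes with one designed bottleneck.

    The cycle WKKKK0 -> WKKK0K -> WKK0KK -> WKKKK0 alternates 4-ion and 3-ion
    codes in the S1-S4 window (WKKKK0 holds 4 ions there, the other two hold
    3); the WKKK0K -> WKK0KK leg is the designed rate-limiting step (0.3/ns
    forward against 5/ns elsewhere, with 10:1 forward bias on every leg).
    """
    states = ["WKK0KK", "WKKK0K", "WKKKK0"]
    Q = np.zeros((3, 3))
    # forward cycle: WKKKK0 -> WKKK0K -> WKK0KK -> WKKKK0
    Q[2, 1] = 5.0
    Q[1, 0] = 0.3  # designed bottleneck
    Q[0, 2] = 5.0
    # 10:1 backward
    Q[1, 2] = 0.5
    Q[0, 1] = 0.03
    Q[2, 0] = 0.5
    return CTMCSpec(states=states, rate_matrix=Q, stride=stride,
                    duration=duration, seed=seed)


def demo_channel_spec(seed: int | None = 0, duration: float = 100.0) -> ChannelSimSpec:
    """Outward-biased knock-on channel on the canonical 5-plane SF geometry."""
    geometry = SiteGeometry(
        plane_z=(1.0, 1.3, 1.6, 1.9, 2.2),
        s0_cap=0.4,
        scav_depth=0.4,
        axis_radius=0.25,
        axis_xy=(2.0, 2.0),
    )
    return ChannelSimSpec(geometry=geometry, seed=seed, duration=duration)
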