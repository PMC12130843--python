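"""Permeation mechanism graphs from discretized SF trajectories.

Nodes are SF occupancy states (possibly lumped sets of states); a directed
edge A->B carries the transition rate defined as the inverse mean first
passage time (MFPT) from A to B, and the net flux, defined as the number of
direct A->B frame transitions minus the B->A ones.  States are progressively
lumped: as long as the fastest remaining inter-state rate exceeds a cutoff,
that pair is merged, the trajectory is relabeled, and all rates are
re-estimated from the relabeled trajectory.  The rate-limiting step is the
slowest transition among those carrying the dominant share of the net
permeation flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .sfstate import StateTrajectory

__all__ = [
    "TransitionStats",
    "MechanismGraph",
    "RateLimitingStep",
    "pairwise_transition_stats",
    "build_mechanism_graph",
    "lump_graph",
    "rate_limiting_step",
    "ion_count_class",
]


@dataclass
class TransitionStats:
    """Per-ordered-pair direct counts, MFPTs and MFPT-inverse rates.

    ``mfpt`` holds only pairs with at least one completed passage; a pair with
    no completed passage has an undefined (absent) rate, never a zero one.
    Passage times from replicas are pooled before averaging.
    """

    states: list[str]
    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    mfpt: dict[tuple[str, str], float] = field(default_factory=dict)  # ns
    n_passages: dict[tuple[str, str], int] = field(default_factory=dict)

    def rate(self, a: str, b: str) -> float | None:
        """MFPT-inverse rate in 1/ns, or None if no passage completed."""
        t = self.mfpt.get((a, b))
        return None if t is None else 1.0 / t

    def net_flux(self, a: str, b: str) -> int:
        return self.counts.get((a, b), 0) - self.counts.get((b, a), 0)


def _as_label_seqs(trajs) -> tuple[list[tuple[float, list[str]]], list[str]]:
    """Normalize input trajectories to (stride, code list) pairs plus state list."""
    if isinstance(trajs, StateTrajectory):
        trajs = [trajs]
    elif (
        isinstance(trajs, tuple)
        and len(trajs) == 2
        and isinstance(trajs[0], (int, float))
    ):
        trajs = [trajs]  # a bare (stride, codes) pair
    seqs: list[tuple[float, list[str]]] = []
    for t in trajs:
        if isinstance(t, StateTrajectory):
            seqs.append((t.stride, list(t.codes)))
        else:
            stride, codes = t
            seqs.append((float(stride), list(codes)))
    if not seqs:
        raise ValueError("need at least one trajectory")
    states = sorted({c for _, codes in seqs for c in codes})
    return seqs, states


def _accumulate_pair_stats(
    seqs: list[tuple[float, np.ndarray]], n_states: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Direct-transition counts, pooled passage-time sums and passage counts."""
    counts = np.zeros((n_states, n_states), dtype=np.int64)
    t_sum = np.zeros((n_states, n_states))
    t_n = np.zeros((n_states, n_states), dtype=np.int64)
    for stride, lab in seqs:
        a, b = lab[:-1], lab[1:]
        mask = a != b
        np.add.at(counts, (a[mask], b[mask]), 1)

        occ = [np.flatnonzero(lab == s) for s in range(n_states)]
        for s in range(n_states):
            if occ[s].size == 0:
                continue
            # entries into s: first frame of each run of s
            e = occ[s]
            entries = e[np.concatenate(([True], np.diff(e) > 1))]
            for s2 in range(n_states):
                if s2 == s or occ[s2].size == 0:
                    continue
                idx = occ[s2]
                pos = np.searchsorted(idx, entries)
                ok = pos < idx.size  # passages not completed are censored
                if not np.any(ok):
                    continue
                dt = (idx[pos[ok]] - entries[ok]) * stride
                t_sum[s, s2] += dt.sum()
                t_n[s, s2] += dt.size
    return counts, t_sum, t_n


def pairwise_transition_stats(trajs) -> TransitionStats:
    """MFPTs, MFPT-inverse rates and direct counts for every ordered state pair.

    ``MFPT(A->B)`` is the mean, over entries into A, of the time until the
    first subsequent visit to B; passages still pending at the end of a
    trajectory are censored.  Replicas are pooled at the passage-time level
    (never spliced end to end, and never averaged as rates).

    ``trajs`` may be a single :class:`StateTrajectory`, a sequence of them, or
    ``(stride, labels)`` pairs for pre-relabeled data.
    """
    seqs, states = _as_label_seqs(trajs)
    index = {s: i for i, s in enumerate(states)}
    int_seqs = [
        (stride, np.fromiter((index[c] for c in codes), dtype=np.int64, count=len(codes)))
        for stride, codes in seqs
    ]
    counts, t_sum, t_n = _accumulate_pair_stats(int_seqs, len(states))
    stats = TransitionStats(states=states)
    for i, a in enumerate(states):
        for j, b in enumerate(states):
            if i == j:
                continue
            if counts[i, j]:
                stats.counts[(a, b)] = int(counts[i, j])
            if t_n[i, j]:
                stats.mfpt[(a, b)] = float(t_sum[i, j] / t_n[i, j])
                stats.n_passages[(a, b)] = int(t_n[i, j])
    return stats


def ion_count_class(code: str, window: str = "s0_scav") -> int:
    """Number of K+ ions in a code, over all six sites or the S1-S4 window."""
    if window == "s0_scav":
        return code.count("K")
    if window == "s1_s4":
        return code[1:5].count("K")
    raise ValueError(f"unknown ion-count window {window!r}")


@dataclass
class MechanismGraph:
    """Directed graph of (lumped) SF states with MFPT rates and net fluxes."""

    graph: nx.DiGraph
    lump_cutoff: float | None = None  # 1/ns

    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def members(self, node: str) -> tuple[str, ...]:
        return self.graph.nodes[node]["members"]

    def population(self, node: str) -> float:
        return self.graph.nodes[node]["population"]

    def edge(self, a: str, b: str) -> dict | None:
        return self.graph.get_edge_data(a, b)

    def undirected_pairs(self) -> list[tuple[str, str]]:
        seen = set()
        out = []
        for a, b in self.graph.edges:
            key = (a, b) if a <= b else (b, a)
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def node_flux_imbalance(self, node: str) -> int:
        """Net flux in minus net flux out; 0 for a conserved steady cycle."""
        total = 0
        for _, b, d in self.graph.out_edges(node, data=True):
            total -= d["net_flux"]
        return total

    def to_json(self) -> dict:
        return {
            "lump_cutoff_per_ns": self.lump_cutoff,
            "nodes": [
                {
                    "label": n,
                    "members": list(d["members"]),
                    "population": d["population"],
                    "ion_class": d["ion_class"],
                }
                for n, d in self.graph.nodes(data=True)
            ],
            "edges": [
                {
                    "source": a,
                    "target": b,
                    "rate_per_ns": d.get("rate"),
                    "mfpt_ns": d.get("mfpt"),
                    "count": d.get("count", 0),
                    "net_flux": d["net_flux"],
                }
                for a, b, d in self.graph.edges(data=True)
            ],
        }

    def to_dot(self) -> str:
        """Graphviz rendering: node size ~ population, edge width ~ rate, label = net flux."""
        lines = ["digraph mechanism {", "  rankdir=TB;"]
        for n, d in self.graph.nodes(data=True):
            size = 0.5 + 2.0 * d["population"]
            color = {3: "lightblue", 4: "orange"}.get(d["ion_class"], "gray")
            lines.append(
                f'  "{n}" [width={size:.2f}, height={size:.2f}, fixedsize=true, '
                f'style=filled, fillcolor={color}, '
                f'label="{n}\\n{100 * d["population"]:.1f}%"];'
            )
        max_rate = max(
            (d.get("rate") or 0.0 for _, _, d in self.graph.edges(data=True)),
            default=1.0,
        ) or 1.0
        for a, b, d in self.graph.edges(data=True):
            if d["net_flux"] <= 0 and self.graph.has_edge(b, a):
                continue  # draw the positive-net-flux direction only
            rate = d.get("rate") or 0.0
            pw = 0.5 + 4.0 * rate / max_rate
            lines.append(
                f'  "{a}" -> "{b}" [penwidth={pw:.2f}, label="{d["net_flux"]}"];'
            )
        lines.append("}")
        return "\n".join(lines)


def build_mechanism_graph(
    stats: TransitionStats,
    populations: dict[str, float],
    ion_class_window: str = "s0_scav",
    lump_cutoff: float | None = None,
) -> MechanismGraph:
    """Graph with one node per state (population, ion-count class) and rate/flux edges.

    For lumped labels (member codes joined by "+") the ion-count class is the
    common class of the members, or None when members disagree.
    """
    if not stats.states:
        raise ValueError("empty transition statistics")
    g = nx.DiGraph()
    for s in stats.states:
        members = tuple(sorted(s.split("+")))
        classes = {ion_count_class(m, ion_class_window) for m in members}
        g.add_node(
            s,
            members=members,
            population=float(populations.get(s, 0.0)),
            ion_class=classes.pop() if len(classes) == 1 else None,
        )
    for (a, b), t in stats.mfpt.items():
        g.add_edge(
            a,
            b,
            rate=1.0 / t,
            mfpt=t,
            count=stats.counts.get((a, b), 0),
            net_flux=stats.net_flux(a, b),
        )
    return MechanismGraph(graph=g, lump_cutoff=lump_cutoff)


def _populations_from_seqs(seqs: list[tuple[float, list[str]]]) -> dict[str, float]:
    total = sum(len(codes) for _, codes in seqs)
    pops: dict[str, float] = {}
    for _, codes in seqs:
        for c in codes:
            pops[c] = pops.get(c, 0.0) + 1.0
    return {c: v / total for c, v in pops.items()}


def lump_graph(trajs, cutoff: float, ion_class_window: str = "s0_scav") -> MechanismGraph:
    """Progressively lump states whose exchange rate exceeds ``cutoff`` (1/ns).

    Starting from the raw codes, the fastest inter-state rate is found; if it
    exceeds the cutoff, that pair is merged (all member codes relabeled to one
    lumped state named by joining members with "+" in lexicographic order),
    rates are re-estimated on the relabeled trajectory, and the procedure
    repeats until the fastest remaining rate is at or below the cutoff.
    A cutoff above every rate returns the unlumped graph.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    seqs, _ = _as_label_seqs(trajs)
    label_of: dict[str, str] = {}  # original code -> current lumped label

    def relabel() -> list[tuple[float, list[str]]]:
        return [
            (stride, [label_of.get(c, c) for c in codes]) for stride, codes in seqs
        ]

    while True:
        cur = relabel()
        stats = pairwise_transition_stats(cur)
        best: tuple[str, str] | None = None
        best_rate = -np.inf
        for pair, t in stats.mfpt.items():
            r = 1.0 / t
            if r > best_rate:
                best_rate = r
                best = pair
        if best is None or best_rate <= cutoff:
            pops = _populations_from_seqs(cur)
            return build_mechanism_graph(
                stats, pops, ion_class_window=ion_class_window, lump_cutoff=cutoff
            )
        a, b = best
        members = sorted(set(a.split("+")) | set(b.split("+")))
        merged = "+".join(members)
        for code in members:
            label_of[code] = merged


@dataclass(frozen=True)
class RateLimitingStep:
    node_a: str
    node_b: str
    forward_rate: float  # 1/ns, in the direction of positive net flux
    net_flux: int
    flux_fraction: float
    warning: bool = False  # True when no pair met the flux threshold


def rate_limiting_step(
    graph: MechanismGraph,
    total_flux: float,
    flux_fraction_threshold: float = 0.5,
) -> RateLimitingStep:
    """Slowest transition among the pairs carrying the dominant net flux.

    ``total_flux`` is the net permeation event count measured on the same
    trajectories.  Among undirected pairs whose |net flux| is at least
    ``flux_fraction_threshold * total_flux``, the pair with the smallest
    forward rate (rate in the direction of positive net flux) is returned.
    If no pair qualifies (including zero total flux), the maximal-|flux| pair
    is returned with ``warning=True``.
    """
    pairs = graph.undirected_pairs()
    if not pairs:
        raise ValueError("graph has no edges")

    def pair_info(a: str, b: str):
        d_ab = graph.edge(a, b)
        flux = d_ab["net_flux"] if d_ab else -graph.edge(b, a)["net_flux"]
        fwd, rev = (a, b) if flux >= 0 else (b, a)
        d_fwd = graph.edge(fwd, rev)
        rate = d_fwd["rate"] if d_fwd else np.inf
        return abs(flux), rate, (fwd, rev)

    candidates = []
    for a, b in pairs:
        flux, rate, (fwd, rev) = pair_info(a, b)
        candidates.append((flux, rate, fwd, rev))

    qualified = [
        c for c in candidates
        if total_flux > 0 and c[0] >= flux_fraction_threshold * total_flux
    ]
    warning = not qualified
    pool = qualified or candidates
    if warning:
        flux, rate, fwd, rev = max(pool, key=lambda c: c[0])
    else:
        flux, rate, fwd, rev = min(pool, key=lambda c: c[1])
    frac = flux / total_flux if total_flux > 0 else float("nan")
    return RateLimitingStep(
        node_a=fwd, node_b=rev, forward_rate=float(rate),
        net_flux=int(flux), flux_fraction=float(frac), warning=warning,
    )
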