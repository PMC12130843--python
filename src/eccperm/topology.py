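"""Electronic continuum correction (ECC) charge scaling of force-field topologies.

The ECC treats electronic polarization in fixed-charge force fields as a mean
field: the partial charges of every ionized moiety (charged side chains,
termini, monatomic ions) are multiplied by a factor ``q < 1``, equivalent to
screening Coulomb interactions by an electronic dielectric constant
``eps_el = 1/q**2``.  Two conventions are supported:

* **group scaling** — the charge group carrying the net charge (e.g. the
  -CH2-CO2(-) group of aspartate) is multiplied by ``q``; all other atoms are
  untouched.  Appropriate for force fields whose ionized charge is localized
  in one charge group (CHARMM-style).
* **weighted-state scaling** — each atom's charge is the ``q``-weighted average
  of its charged-form and neutral-form charges.  Appropriate for force fields
  that spread the formal charge over the backbone (AMBER-style), where no
  single group sums to the formal charge.

The module also provides the Born-model utilities used to derive solvation
free-energy targets for scaled ions, the Eyring relation between rate ratios
and barrier differences, and linear interpolation of ion Lennard-Jones sigma
between optimized anchor values.  Epsilon is never modified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Topology",
    "ScalingScheme",
    "IonLJAnchorTable",
    "BornModelParams",
    "SolvationTarget",
    "scale_group_charges",
    "scale_weighted_charges",
    "apply_weighted_states",
    "interpolate_ion_sigma",
    "born_scaled_solvation_target",
    "born_electronic_term",
    "eyring_barrier_difference",
    "scaling_factor_from_dielectric",
    "E_CHARGE",
    "N_AVOGADRO",
    "EPSILON_0",
    "R_KCAL",
]

# CODATA 2018
E_CHARGE = 1.602176634e-19  # C
N_AVOGADRO = 6.02214076e23  # 1/mol
EPSILON_0 = 8.8541878128e-12  # F/m
R_KCAL = 1.98720425864083e-3  # kcal/(mol K)
_J_PER_KCAL = 4184.0

#: tolerance for deciding that a charge group carries an integer formal charge
GROUP_SUM_TOL = 1e-4


@dataclass(frozen=True)
class AtomRecord:
    """One atom line of a topology: identity, charge group and partial charge."""

    atom_name: str
    residue_name: str
    residue_id: int
    charge_group_id: int
    partial_charge: float  # e
    lj_type: str = ""
    mass: float | None = None
    line_no: int | None = None  # source line in the originating file, if any

    def __post_init__(self) -> None:
        if not math.isfinite(self.partial_charge):
            raise ValueError(
                f"non-finite partial charge on atom {self.atom_name!r} "
                f"(residue {self.residue_name} {self.residue_id})"
            )
        if self.charge_group_id < 0:
            raise ValueError("charge_group_id must be non-negative")


@dataclass
class Topology:
    """Ordered atom records plus bookkeeping for formal charges.

    ``applied_scale`` records the ECC factor already applied to the listed
    charged groups (1.0 for an unscaled force field); it lets a scaled
    topology be rescaled (e.g. inverted with 1/q) while still validating that
    charge groups carry integer formal charges underneath.
    """

    atoms: list[AtomRecord]
    formal_charge_by_residue: dict[int, int] = field(default_factory=dict)
    applied_scale: float = 1.0
    source: object | None = None  # io.TopologyDocument for layout-preserving writes

    @property
    def system_net_charge(self) -> float:
        return float(sum(a.partial_charge for a in self.atoms))

    def residues(self) -> list[tuple[int, str, list[int]]]:
        """(residue_id, residue_name, atom indices) in file order."""
        out: list[tuple[int, str, list[int]]] = []
        for i, a in enumerate(self.atoms):
            if out and out[-1][0] == a.residue_id and out[-1][1] == a.residue_name:
                out[-1][2].append(i)
            else:
                out.append((a.residue_id, a.residue_name, [i]))
        return out


@dataclass(frozen=True)
class ScalingScheme:
    mode: str  # "group" | "weighted"
    q: float

    def __post_init__(self) -> None:
        if self.mode not in ("group", "weighted"):
            raise ValueError(f"unknown scaling mode {self.mode!r}")
        if not 0.0 < self.q <= 1.0:
            raise ValueError(f"scaling factor q={self.q} outside (0, 1]")


def _check_q(q: float, *, allow_above_one: bool = True) -> None:
    if not (math.isfinite(q) and q > 0.0):
        raise ValueError(f"scaling factor q={q} must be a positive finite number")
    if not allow_above_one and q > 1.0:
        raise ValueError(f"scaling factor q={q} outside (0, 1]")


def scale_group_charges(
    topology: Topology,
    charged_groups: Mapping[str, Iterable[str]],
    q: float,
) -> Topology:
    """Multiply the net-charge-carrying group of each listed residue by ``q``.

    ``charged_groups`` maps residue names to the atom names forming the group
    that sums to the residue's integer formal charge (a single atom for
    monatomic ions).  Atoms outside listed groups are untouched, so a neutral
    system stays neutral and a system of net charge Q ends up at ``q*Q``.

    ``q`` is normally in (0, 1]; values above 1 are accepted so that a scaled
    topology can be rescaled back with 1/q.

    Raises
    ------
    ValueError
        if a listed group does not sum to an integer formal charge (within
        1e-4 e, after undoing any previously applied scale), if a residue
        named in ``charged_groups`` is absent from the topology, or if a
        matching residue lacks one of the listed atom names.
    """
    _check_q(q)
    groups = {name: frozenset(atoms) for name, atoms in charged_groups.items()}
    seen: set[str] = set()
    new_atoms = list(topology.atoms)
    formal_map = dict(topology.formal_charge_by_residue)

    for res_id, res_name, idxs in topology.residues():
        if res_name not in groups:
            continue
        seen.add(res_name)
        wanted = groups[res_name]
        members = [i for i in idxs if topology.atoms[i].atom_name in wanted]
        present = {topology.atoms[i].atom_name for i in members}
        missing = wanted - present
        if missing:
            raise ValueError(
                f"residue {res_name} {res_id}: charge-group atoms "
                f"{sorted(missing)} not found"
            )
        group_sum = sum(topology.atoms[i].partial_charge for i in members)
        unscaled = group_sum / topology.applied_scale
        formal = round(unscaled)
        if abs(unscaled - formal) > GROUP_SUM_TOL:
            raise ValueError(
                f"residue {res_name} {res_id}: charge group sums to "
                f"{group_sum:.6f} e (unscaled {unscaled:.6f} e), not an "
                f"integer formal charge within {GROUP_SUM_TOL} e"
            )
        for i in members:
            a = topology.atoms[i]
            new_atoms[i] = replace(a, partial_charge=a.partial_charge * q)
        formal_map[res_id] = formal

    unknown = set(groups) - seen
    if unknown:
        raise ValueError(
            f"charged_groups lists residues absent from topology: {sorted(unknown)}"
        )
    return Topology(
        atoms=new_atoms,
        formal_charge_by_residue=formal_map,
        applied_scale=topology.applied_scale * q,
        source=topology.source,
    )


def scale_weighted_charges(
    charged_state: Mapping[str, float] | Sequence[tuple[str, float]],
    neutral_state: Mapping[str, float] | Sequence[tuple[str, float]],
    q: float,
) -> dict[str, float]:
    """Weighted-average scaling: ``q*charged + (1-q)*neutral`` per atom.

    The charged state must carry a formal charge of +1 or -1 (within 1e-4 e)
    and the neutral state must be net zero; the result then carries
    ``q * formal`` by linearity.  Both states must list exactly the same atoms.
    """
    _check_q(q, allow_above_one=False)
    qc = dict(charged_state)
    qn = dict(neutral_state)
    if set(qc) != set(qn):
        only_c = sorted(set(qc) - set(qn))
        only_n = sorted(set(qn) - set(qc))
        raise ValueError(
            f"atom-name mismatch between states: only-charged {only_c}, "
            f"only-neutral {only_n}"
        )
    sum_c = sum(qc.values())
    formal = round(sum_c)
    if formal not in (-1, 1) or abs(sum_c - formal) > GROUP_SUM_TOL:
        raise ValueError(
            f"charged state sums to {sum_c:.6f} e; expected a formal charge of "
            f"+1 or -1 within {GROUP_SUM_TOL} e"
        )
    sum_n = sum(qn.values())
    if abs(sum_n) > GROUP_SUM_TOL:
        raise ValueError(f"neutral state is not net-zero (sum {sum_n:.6f} e)")
    return {name: q * qc[name] + (1.0 - q) * qn[name] for name in qc}


def apply_weighted_states(
    topology: Topology,
    state_charges: Mapping[str, Mapping[str, Mapping[str, float]]],
    q: float,
) -> Topology:
    """Apply weighted-state scaling to every matching residue of a topology.

    ``state_charges`` maps residue names to ``{"charged": {atom: e, ...},
    "neutral": {atom: e, ...}}``; each matching residue's atoms get
    ``q*charged + (1-q)*neutral``.  Convenience wrapper around
    :func:`scale_weighted_charges` for whole-topology CLI use.
    """
    new_atoms = list(topology.atoms)
    formal_map = dict(topology.formal_charge_by_residue)
    seen: set[str] = set()
    for res_id, res_name, idxs in topology.residues():
        if res_name not in state_charges:
            continue
        seen.add(res_name)
        spec = state_charges[res_name]
        mixed = scale_weighted_charges(spec["charged"], spec["neutral"], q)
        for i in idxs:
            a = topology.atoms[i]
            if a.atom_name in mixed:
                new_atoms[i] = replace(a, partial_charge=mixed[a.atom_name])
        formal_map[res_id] = round(sum(spec["charged"].values()))
    unknown = set(state_charges) - seen
    if unknown:
        raise ValueError(
            f"weighted-state charges list residues absent from topology: {sorted(unknown)}"
        )
    return Topology(
        atoms=new_atoms,
        formal_charge_by_residue=formal_map,
        applied_scale=topology.applied_scale * q,
        source=topology.source,
    )


@dataclass(frozen=True)
class IonLJAnchorTable:
    """Optimized LJ sigma anchors on a 0.05 grid of scaling factors.

    ``anchors`` maps scaling factor to sigma (nm); epsilon is a single value
    held fixed across the whole grid.  Intermediate factors (0.01 grid) are
    obtained by linear interpolation of sigma only.
    """

    ion: str
    anchors: Mapping[float, float]  # q -> sigma (nm)
    epsilon: float  # kJ/mol, constant

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise ValueError("anchor table needs at least two (q, sigma) points")
        qs = sorted(self.anchors)
        if any(self.anchors[qv] <= 0 for qv in qs):
            raise ValueError("anchor sigma values must be positive")
        if max(qs) > 1.0 + 1e-9:
            raise ValueError("anchor grid must not exceed q = 1.00")

    @property
    def q_grid(self) -> np.ndarray:
        return np.array(sorted(self.anchors), dtype=float)

    @property
    def sigma_grid(self) -> np.ndarray:
        return np.array([self.anchors[qv] for qv in sorted(self.anchors)], dtype=float)


def interpolate_ion_sigma(table: IonLJAnchorTable, q: float) -> float:
    """Piecewise-linear sigma(q) between the bracketing anchors; exact at anchors.

    No extrapolation: ``q`` outside the anchor range is rejected.
    """
    qs = table.q_grid
    if not (qs[0] - 1e-12 <= q <= qs[-1] + 1e-12):
        raise ValueError(
            f"q={q} outside anchor range [{qs[0]}, {qs[-1]}] for ion "
            f"{table.ion!r}; refusing to extrapolate"
        )
    return float(np.interp(q, qs, table.sigma_grid))


@dataclass(frozen=True)
class BornModelParams:
    """Inputs to the Born continuum expression for ion solvation energy."""

    z: int  # formal charge, e
    r0: float  # effective Born radius, nm
    eps_r: float = 1.0  # relative dielectric of the approximated medium

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError(f"Born radius r0={self.r0} nm must be positive")
        if self.eps_r < 1:
            raise ValueError("relative dielectric constant must be >= 1")


@dataclass(frozen=True)
class SolvationTarget:
    """Scaled-charge solvation target: dG_target = dG_exp * q**2."""

    dG_exp: float  # kcal/mol
    q: float

    @property
    def dG_target(self) -> float:
        return born_scaled_solvation_target(self.dG_exp, self.q)


def born_scaled_solvation_target(dG_exp: float, q: float) -> float:
    """Target solvation free energy for an ion with charges scaled by ``q``.

    Splitting the experimental hydration free energy into a nuclear part
    (simulated with scaled charges) and an electronic part (treated as a mean
    field), the Born model gives the electronic part proportional to
    ``1 - q**2``, so the simulation should target ``dG_exp * q**2``.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q={q} outside [0, 1]")
    return dG_exp * q * q


def born_electronic_term(params: BornModelParams, q: float) -> float:
    """Electronic part of the Born solvation energy, kcal/mol.

    ``dG_ele = -N_A z^2 e^2 / (8 pi eps0 r0) * (1 - q^2)``, the portion of the
    solvation free energy attributed to electronic screening when the scaling
    factor satisfies ``q**2 = 1/eps_el``.
    """
    r0_m = params.r0 * 1e-9
    pref = N_AVOGADRO * params.z**2 * E_CHARGE**2 / (8.0 * math.pi * EPSILON_0 * r0_m)
    return -pref * (1.0 - q * q) / _J_PER_KCAL


def eyring_barrier_difference(rate_ratio: float, T: float) -> float:
    """Barrier-height difference (kcal/mol) implied by a ratio of rates.

    ``dG = R T ln(rate_ratio)``: a 10:1 ratio at 310 K corresponds to about
    1.4 kcal/mol, a 2.5:1 ratio to about 0.6 kcal/mol.
    """
    if rate_ratio <= 0:
        raise ValueError("rate ratio must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive")
    return R_KCAL * T * math.log(rate_ratio)


def scaling_factor_from_dielectric(eps_el: float) -> float:
    """ECC scaling factor from the electronic (high-frequency) dielectric.

    ``q = sqrt(1/eps_el)``; for the typical organic-medium value of about 2
    this gives the widely quoted ~0.7.
    """
    if eps_el < 1:
        raise ValueError("electronic dielectric constant must be >= 1")
    return math.sqrt(1.0 / eps_el)
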