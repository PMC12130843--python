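"""File I/O: GROMACS-dialect topologies, trajectories and interchange CSVs.

The topology reader/writer handles the ``[ atoms ]`` block dialect
(columns nr, type, resnr, residue, atom, cgnr, charge, mass).  Reading keeps
every source line; writing re-emits untouched lines byte-identically and
rewrites only lines whose charge changed, with charges at 6 decimal places
and a residual-smearing step that distributes the sub-1e-4 e rounding
residual of each scaled residue over its edited atoms so that file-level
charge sums are exact.

Trajectory input is either the plain columnar fixture CSV
(frame, time_ns, particle_id, kind, x, y, z — all coordinates in nm) or any
coordinate+trajectory pair MDAnalysis can open (PDB/GRO + XTC/TRR/DCD),
converted to nm/ns at this boundary.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .permeation import PermeationEvent
from .sfstate import FrameCoordinates, StateTrajectory
from .topology import AtomRecord, Topology

__all__ = [
    "TopologyDocument",
    "read_topology",
    "write_topology",
    "write_fixture_csv",
    "read_fixture_csv",
    "write_codes_csv",
    "read_codes_csv",
    "write_events_csv",
    "read_events_csv",
    "read_rdf_table",
    "read_anchor_table",
    "read_trajectory",
]

CHARGE_DECIMALS = 6
_CHARGE_UNIT = 10 ** CHARGE_DECIMALS


@dataclass
class TopologyDocument:
    """Raw lines of a topology file plus the location of each atom record."""

    lines: list[str]  # without trailing newlines
    atom_line_idx: list[int] = field(default_factory=list)  # per AtomRecord


def _is_section(line: str) -> str | None:
    m = re.match(r"^\s*\[\s*(\S+)\s*\]", line)
    return m.group(1).lower() if m else None


def read_topology(path) -> Topology:
    """Parse the ``[ atoms ]`` blocks of a GROMACS-style topology include.

    Comments and non-atom sections are preserved verbatim for a
    layout-preserving write.  A malformed atom line (fewer than 7 whitespace
    fields, i.e. missing the charge column, or non-numeric fields) is
    rejected with its line number.
    """
    text = Path(path).read_text()
    lines = text.split("\n")
    doc = TopologyDocument(lines=lines)
    atoms: list[AtomRecord] = []
    section = None
    for i, raw in enumerate(lines):
        sec = _is_section(raw)
        if sec is not None:
            section = sec
            continue
        if section != "atoms":
            continue
        body = raw.split(";", 1)[0]
        if not body.strip():
            continue
        fields = body.split()
        if len(fields) < 7:
            raise ValueError(
                f"{path}:{i + 1}: malformed atom line (expected at least "
                f"7 columns nr/type/resnr/residue/atom/cgnr/charge, got "
                f"{len(fields)}): {raw.strip()!r}"
            )
        try:
            resnr = int(fields[2])
            cgnr = int(fields[5])
            charge = float(fields[6])
            mass = float(fields[7]) if len(fields) >= 8 else None
        except ValueError as exc:
            raise ValueError(f"{path}:{i + 1}: {exc}: {raw.strip()!r}") from exc
        atoms.append(
            AtomRecord(
                atom_name=fields[4],
                residue_name=fields[3],
                residue_id=resnr,
                charge_group_id=cgnr,
                partial_charge=charge,
                lj_type=fields[1],
                mass=mass,
                line_no=i,
            )
        )
        doc.atom_line_idx.append(i)
    if not atoms:
        raise ValueError(f"{path}: no [ atoms ] records found")
    return Topology(atoms=atoms, source=doc)


def _smear_residue(mu: np.ndarray, target_mu: int) -> np.ndarray:
    """Distribute an integer micro-charge residual over a group of atoms."""
    diff = int(target_mu - mu.sum())
    if diff == 0:
        return mu
    n = mu.size
    step = 1 if diff > 0 else -1
    for k in range(abs(diff)):
        mu[k % n] += step
    return mu


def write_topology(topology: Topology, path) -> None:
    """Write a topology, preserving the layout of untouched lines.

    Lines whose charge is unchanged (to write precision) are emitted
    byte-identically; edited lines are re-emitted with normalized whitespace
    and the charge at 6 decimals.  For each residue with a recorded formal
    charge, rounding residuals over the edited atoms are smeared in 1e-6 e
    steps so the written residue sum equals ``applied_scale * formal`` exactly.
    """
    doc = topology.source
    if doc is None or len(doc.atom_line_idx) != len(topology.atoms):
        _write_minimal(topology, path)
        return

    mu = np.array(
        [round(a.partial_charge * _CHARGE_UNIT) for a in topology.atoms], dtype=np.int64
    )
    orig_charges = []
    for li in doc.atom_line_idx:
        orig_charges.append(float(doc.lines[li].split(";", 1)[0].split()[6]))
    changed = np.array(
        [abs(a.partial_charge - c) > 0.5 / _CHARGE_UNIT
         for a, c in zip(topology.atoms, orig_charges)]
    )

    for res_id, res_name, idxs in topology.residues():
        formal = topology.formal_charge_by_residue.get(res_id)
        if formal is None:
            continue
        edited = [i for i in idxs if changed[i]]
        if not edited:
            continue
        target_res = round(topology.applied_scale * formal * _CHARGE_UNIT)
        untouched = int(sum(mu[i] for i in idxs if not changed[i]))
        sub = np.array([mu[i] for i in edited], dtype=np.int64)
        sub = _smear_residue(sub, target_res - untouched)
        for i, v in zip(edited, sub):
            mu[i] = v

    out_lines = list(doc.lines)
    for rec_i, li in enumerate(doc.atom_line_idx):
        if not changed[rec_i]:
            continue
        a = topology.atoms[rec_i]
        body = doc.lines[li].split(";", 1)
        comment = f" ;{body[1]}" if len(body) > 1 else ""
        fields = body[0].split()
        fields[6] = f"{mu[rec_i] / _CHARGE_UNIT:.{CHARGE_DECIMALS}f}"
        out_lines[li] = (
            f"{fields[0]:>6} {fields[1]:>10} {fields[2]:>6} {fields[3]:>6} "
            f"{fields[4]:>6} {fields[5]:>6} {fields[6]:>12}"
            + ("".join(f" {f:>10}" for f in fields[7:]))
            + comment
        )
    Path(path).write_text("\n".join(out_lines))


def _write_minimal(topology: Topology, path) -> None:
    lines = ["[ atoms ]", "; nr type resnr residue atom cgnr charge mass"]
    for i, a in enumerate(topology.atoms, start=1):
        mass = f" {a.mass:10.4f}" if a.mass is not None else ""
        lines.append(
            f"{i:>6} {a.lj_type or 'X':>10} {a.residue_id:>6} {a.residue_name:>6} "
            f"{a.atom_name:>6} {a.charge_group_id:>6} "
            f"{a.partial_charge:>12.{CHARGE_DECIMALS}f}{mass}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# columnar fixture trajectories

KIND_ION = "ion"
KIND_WATER = "water"
KIND_SFO = "sfo"  # selectivity-filter oxygen layer mean; particle_id = layer 0..4


def write_fixture_csv(frames: Sequence[FrameCoordinates], path,
                      header_lines: Iterable[str] = ()) -> None:
    """Write frames in the plain columnar format (coordinates in nm)."""
    rows = []
    for fi, f in enumerate(frames):
        for ion_id, p in f.ion_positions.items():
            rows.append((fi, f.time, str(ion_id), KIND_ION, p[0], p[1], p[2]))
        for wi, p in enumerate(f.water_o_positions):
            rows.append((fi, f.time, f"w{wi}", KIND_WATER, p[0], p[1], p[2]))
        if f.sf_oxygen_z is not None:
            for li, z in enumerate(f.sf_oxygen_z):
                rows.append((fi, f.time, str(li), KIND_SFO, 0.0, 0.0, z))
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        if frames and frames[0].box is not None:
            b = frames[0].box
            fh.write(f"# box_nm = {b[0]:.6f} {b[1]:.6f} {b[2]:.6f}\n")
        fh.write("frame,time_ns,particle_id,kind,x,y,z\n")
        for r in rows:
            fh.write(f"{r[0]},{r[1]:.6f},{r[2]},{r[3]},{r[4]:.6f},{r[5]:.6f},{r[6]:.6f}\n")


def read_fixture_csv(path) -> list[FrameCoordinates]:
    """Read a columnar fixture trajectory back into FrameCoordinates."""
    box = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            m = re.match(r"#\s*box_nm\s*=\s*(\S+)\s+(\S+)\s+(\S+)", line)
            if m:
                box = np.array([float(g) for g in m.groups()])
    df = pd.read_csv(path, comment="#")
    required = {"frame", "time_ns", "particle_id", "kind", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: fixture CSV missing columns {required - set(df.columns)}")
    frames = []
    for _, grp in df.groupby("frame", sort=True):
        t = float(grp["time_ns"].iloc[0])
        ions = {}
        waters = []
        sfo = {}
        for row in grp.itertuples(index=False):
            p = np.array([row.x, row.y, row.z], dtype=float)
            if row.kind == KIND_ION:
                ions[str(row.particle_id)] = p
            elif row.kind == KIND_WATER:
                waters.append(p)
            elif row.kind == KIND_SFO:
                sfo[int(row.particle_id)] = float(row.z)
            else:
                raise ValueError(f"{path}: unknown particle kind {row.kind!r}")
        sf_z = None
        if sfo:
            if sorted(sfo) != [0, 1, 2, 3, 4]:
                raise ValueError(f"{path}: need exactly 5 SF oxygen layers, got {sorted(sfo)}")
            sf_z = np.array([sfo[i] for i in range(5)])
        frames.append(
            FrameCoordinates(
                time=t,
                ion_positions=ions,
                water_o_positions=np.asarray(waters, dtype=float).reshape(-1, 3),
                sf_oxygen_z=sf_z,
                box=box,
            )
        )
    return frames


# --------------------------------------------------------------------------
# interchange CSVs

def write_codes_csv(traj: StateTrajectory, path, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("time_ns,code\n")
        for t, c in zip(traj.times, traj.codes):
            fh.write(f"{t:.6f},{c}\n")


def read_codes_csv(path) -> StateTrajectory:
    df = pd.read_csv(path, comment="#")
    if not {"time_ns", "code"}.issubset(df.columns):
        raise ValueError(f"{path}: code table needs columns time_ns, code")
    return StateTrajectory(
        times=df["time_ns"].to_numpy(dtype=float), codes=[str(c) for c in df["code"]]
    )


def write_events_csv(events: Sequence[PermeationEvent], path,
                     header_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("ion_id,time_ns,direction\n")
        for e in events:
            fh.write(f"{e.ion_id},{e.completion_time:.6f},{e.direction:+d}\n")


def read_events_csv(path) -> list[PermeationEvent]:
    df = pd.read_csv(path, comment="#")
    if not {"ion_id", "time_ns", "direction"}.issubset(df.columns):
        raise ValueError(f"{path}: events CSV needs columns ion_id, time_ns, direction")
    return [
        PermeationEvent(str(r.ion_id), float(r.time_ns), int(r.direction))
        for r in df.itertuples(index=False)
    ]


def read_rdf_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Two-column text RDF: r (nm) and g(r)."""
    data = np.loadtxt(path, comments=("#", "@", ";"))
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (r_nm, g)")
    return data[:, 0], data[:, 1]


def read_anchor_table(path) -> pd.DataFrame:
    """CSV of LJ anchors: columns ion, q, sigma_nm, epsilon_kj_mol."""
    df = pd.read_csv(path, comment="#")
    need = {"ion", "q", "sigma_nm", "epsilon_kj_mol"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: anchor table needs columns {sorted(need)}")
    return df


# --------------------------------------------------------------------------
# MD trajectory input (MDAnalysis boundary; internal units are nm and ns)

def read_trajectory(
    coords_path,
    traj_path=None,
    ion_selection: str = "name K POT",
    water_selection: str = "name OW OH2",
    sf_oxygen_selection: str | None = None,
    length_scale: float = 0.1,  # MDAnalysis works in Angstrom; 0.1 converts to nm
    stride: int = 1,
) -> list[FrameCoordinates]:
    """Read a standard coordinate(+trajectory) pair into FrameCoordinates.

    SF oxygen layer means are computed per frame by sorting the selected SF
    oxygens by z and averaging five contiguous, equally sized layers (the
    atom count must therefore be a multiple of 5, e.g. 4 oxygens per layer
    in a tetrameric channel).
    """
    import MDAnalysis as mda

    u = mda.Universe(str(coords_path)) if traj_path is None else mda.Universe(
        str(coords_path), str(traj_path)
    )
    ions = u.select_atoms(ion_selection)
    if len(ions) == 0:
        raise ValueError(f"ion selection matched nothing: {ion_selection!r}")
    waters = u.select_atoms(water_selection)
    if len(waters) == 0:
        raise ValueError(f"water selection matched nothing: {water_selection!r}")
    sfo = None
    if sf_oxygen_selection is not None:
        sfo = u.select_atoms(sf_oxygen_selection)
        if len(sfo) == 0:
            raise ValueError(f"SF oxygen selection matched nothing: {sf_oxygen_selection!r}")
        if len(sfo) % 5 != 0:
            raise ValueError(
                f"SF oxygen selection has {len(sfo)} atoms; need a multiple of 5 "
                "(five layers)"
            )

    frames: list[FrameCoordinates] = []
    for ts in u.trajectory[::stride]:
        ion_pos = {
            f"{a.name}{a.resid}_{a.ix}": a.position * length_scale for a in ions
        }
        sf_z = None
        if sfo is not None:
            z = np.sort(sfo.positions[:, 2] * length_scale)
            sf_z = z.reshape(5, -1).mean(axis=1)
        box = ts.dimensions[:3] * length_scale if ts.dimensions is not None else None
        frames.append(
            FrameCoordinates(
                time=float(ts.time) / 1000.0,  # ps -> ns
                ion_positions=ion_pos,
                water_o_positions=waters.positions * length_scale,
                sf_oxygen_z=sf_z,
                box=box,
            )
        )
    return frames
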