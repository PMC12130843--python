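"""Selectivity-filter occupancy coding.

A K+ channel selectivity filter (SF) stacks four ion binding sites S1-S4
between five oxygen-layer planes (backbone carbonyls for S1-S3, threonine
hydroxyls closing S4), with S0 just above the top plane and the cavity site
SCav just below the bottom one.  Each trajectory frame is discretized into a
6-letter code over (S0, S1, S2, S3, S4, SCav): ``K`` if the site holds a K+
ion, ``W`` if it holds a water oxygen (and no ion), ``0`` if empty.

Geometry convention: z increases toward the extracellular side, so "outward"
permeation is +z.  Sites are cylinders of radius ``axis_radius`` around the
pore axis, sliced by the oxygen-layer planes; z intervals are half-open
(lower-inclusive) so a particle sitting exactly on a plane belongs to the
site above it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SITE_NAMES",
    "BATH_ABOVE",
    "BATH_BELOW",
    "BATH_SIDE",
    "SiteGeometry",
    "FrameCoordinates",
    "StateTrajectory",
    "validate_occupancy_code",
    "build_site_geometry",
    "assign_frame_occupancy",
    "discretize_trajectory",
]

logger = logging.getLogger(__name__)

SITE_NAMES = ("S0", "S1", "S2", "S3", "S4", "SCav")
BATH_ABOVE = "bath_above"  # extracellular side, z above the S0 cap
BATH_BELOW = "bath_below"  # intracellular side, z below the SCav floor
BATH_SIDE = "bath"  # inside the SF z-range but laterally outside the pore cylinder

DEFAULT_S0_CAP = 0.4  # nm
DEFAULT_SCAV_DEPTH = 0.4  # nm
DEFAULT_AXIS_RADIUS = 0.25  # nm


@dataclass(frozen=True)
class SiteGeometry:
    """Binding-site boundary model: 5 oxygen-layer planes plus caps and a pore cylinder."""

    plane_z: tuple[float, ...]  # 5 ascending z values (nm)
    s0_cap: float = DEFAULT_S0_CAP
    scav_depth: float = DEFAULT_SCAV_DEPTH
    axis_radius: float = DEFAULT_AXIS_RADIUS
    axis_xy: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        z = np.asarray(self.plane_z, dtype=float)
        if z.size != 5 or not np.all(np.isfinite(z)):
            raise ValueError("plane_z must be 5 finite oxygen-layer z values")
        if np.any(np.diff(z) <= 0):
            raise ValueError(
                f"oxygen-layer planes must be strictly ordered; got {z.tolist()} "
                "(degenerate or swapped layers suggest a broken SF or misselection)"
            )
        if min(self.s0_cap, self.scav_depth, self.axis_radius) <= 0:
            raise ValueError("s0_cap, scav_depth and axis_radius must be positive")
        object.__setattr__(self, "plane_z", tuple(float(v) for v in z))

    def site_intervals(self) -> list[tuple[float, float]]:
        """[lo, hi) z intervals for S0..SCav, top to bottom."""
        p = self.plane_z
        return [
            (p[4], p[4] + self.s0_cap),  # S0
            (p[3], p[4]),  # S1
            (p[2], p[3]),  # S2
            (p[1], p[2]),  # S3
            (p[0], p[1]),  # S4
            (p[0] - self.scav_depth, p[0]),  # SCav
        ]

    @property
    def z_top(self) -> float:
        return self.plane_z[4] + self.s0_cap

    @property
    def z_bottom(self) -> float:
        return self.plane_z[0] - self.scav_depth

    def site_centers(self) -> list[float]:
        return [0.5 * (lo + hi) for lo, hi in self.site_intervals()]

    def min_half_width(self) -> float:
        return min(0.5 * (hi - lo) for lo, hi in self.site_intervals())


@dataclass
class FrameCoordinates:
    """Per-frame particle positions (nm) relevant to SF occupancy."""

    time: float  # ns
    ion_positions: dict[object, np.ndarray]
    water_o_positions: np.ndarray  # (n, 3)
    sf_oxygen_z: np.ndarray | None = None  # 5 per-layer mean z values
    box: np.ndarray | None = None  # (3,) orthorhombic edges

    def __post_init__(self) -> None:
        self.ion_positions = {
            k: np.asarray(v, dtype=float) for k, v in self.ion_positions.items()
        }
        self.water_o_positions = np.asarray(self.water_o_positions, dtype=float)
        if self.water_o_positions.size == 0:
            self.water_o_positions = np.empty((0, 3))
        for k, v in self.ion_positions.items():
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"ion {k!r} has invalid coordinates {v}")
        if self.water_o_positions.ndim != 2 or self.water_o_positions.shape[1] != 3:
            raise ValueError("water_o_positions must be an (n, 3) array")
        if not np.all(np.isfinite(self.water_o_positions)):
            raise ValueError("non-finite water coordinates")
        if self.sf_oxygen_z is not None:
            z = np.asarray(self.sf_oxygen_z, dtype=float)
            if z.size != 5 or not np.all(np.isfinite(z)):
                raise ValueError("sf_oxygen_z must hold 5 finite layer means")
            self.sf_oxygen_z = z
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(-1)


@dataclass
class StateTrajectory:
    """Discretized trajectory: per-frame state labels and per-ion site labels.

    Labels are normally 6-letter occupancy codes, but any hashable string is
    accepted so that lumped states and synthetic state chains can share the
    container; :func:`discretize_trajectory` always emits valid codes.
    """

    times: np.ndarray  # ns, uniform stride
    codes: list[str]
    ion_site_index: list[dict] | None = None  # per frame: ion_id -> site index | bath label

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size != len(self.codes):
            raise ValueError("times and codes must have equal length")
        if self.ion_site_index is not None and len(self.ion_site_index) != len(self.codes):
            raise ValueError("ion_site_index length must match codes")
        if self.times.size >= 2:
            strides = np.diff(self.times)
            if np.any(strides <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(strides, strides[0], rtol=1e-6, atol=1e-12):
                raise ValueError(
                    f"non-uniform frame stride; measured strides range "
                    f"[{strides.min():.6g}, {strides.max():.6g}] ns"
                )

    @property
    def stride(self) -> float:
        if self.times.size < 2:
            raise ValueError("stride undefined for fewer than 2 frames")
        return float(self.times[1] - self.times[0])

    @property
    def n_frames(self) -> int:
        return int(self.times.size)


def validate_occupancy_code(code: str) -> str:
    """Check the 6-letter K/W/0 format of an occupancy code; returns it unchanged."""
    if len(code) != 6 or any(ch not in "KW0" for ch in code):
        raise ValueError(
            f"occupancy code {code!r} must be 6 characters over {{K, W, 0}}"
        )
    return code


def build_site_geometry(
    sf_oxygen_z_layers: Sequence[float],
    s0_cap: float = DEFAULT_S0_CAP,
    scav_depth: float = DEFAULT_SCAV_DEPTH,
    axis_radius: float = DEFAULT_AXIS_RADIUS,
    axis_xy: tuple[float, float] = (0.0, 0.0),
) -> SiteGeometry:
    """Site geometry from the 5 oxygen-layer mean z values (any input order)."""
    z = np.sort(np.asarray(sf_oxygen_z_layers, dtype=float))
    return SiteGeometry(
        plane_z=tuple(z),
        s0_cap=s0_cap,
        scav_depth=scav_depth,
        axis_radius=axis_radius,
        axis_xy=tuple(axis_xy),
    )


def _lateral_r(xy: np.ndarray, geometry: SiteGeometry, box: np.ndarray | None) -> float:
    d = xy - np.asarray(geometry.axis_xy)
    if box is not None:
        # unwrap laterally relative to the pore axis (minimum image)
        d -= box[:2] * np.round(d / box[:2])
    return float(np.hypot(d[0], d[1]))


def _locate(pos: np.ndarray, geometry: SiteGeometry,
            intervals: list[tuple[float, float]], box: np.ndarray | None):
    """Site index 0..5, or a bath label."""
    z = pos[2]
    if _lateral_r(pos[:2], geometry, box) <= geometry.axis_radius:
        for i, (lo, hi) in enumerate(intervals):
            if lo <= z < hi:
                return i
    if z >= geometry.z_top:
        return BATH_ABOVE
    if z < geometry.z_bottom:
        return BATH_BELOW
    return BATH_SIDE


def assign_frame_occupancy(
    frame: FrameCoordinates, geometry: SiteGeometry
) -> tuple[str, dict]:
    """Occupancy code and per-ion site labels for one frame.

    Per site the letter is ``K`` if at least one ion is present (ions take
    priority over water), ``W`` if at least one water oxygen is present, else
    ``0``.  Multiple ions in one site still yield a single ``K`` (logged);
    the per-ion labels preserve the counts.  Particles outside every site are
    labelled bath (above / below / lateral).
    """
    intervals = geometry.site_intervals()
    ion_site: dict = {}
    ions_per_site = [0] * 6
    for ion_id, pos in frame.ion_positions.items():
        loc = _locate(pos, geometry, intervals, frame.box)
        ion_site[ion_id] = loc
        if isinstance(loc, int):
            ions_per_site[loc] += 1
    for i, n in enumerate(ions_per_site):
        if n > 1:
            logger.warning(
                "frame t=%.6g ns: %d ions share site %s", frame.time, n, SITE_NAMES[i]
            )
    water_in_site = [False] * 6
    for pos in frame.water_o_positions:
        loc = _locate(pos, geometry, intervals, frame.box)
        if isinstance(loc, int):
            water_in_site[loc] = True
    letters = [
        "K" if ions_per_site[i] else ("W" if water_in_site[i] else "0")
        for i in range(6)
    ]
    return "".join(letters), ion_site


def discretize_trajectory(
    frames: Sequence[FrameCoordinates],
    geometry: SiteGeometry | None = None,
    geometry_mode: str = "static",
    **geometry_kwargs,
) -> StateTrajectory:
    """Discretize a coordinate trajectory into an SF StateTrajectory.

    ``geometry_mode="static"`` uses ``geometry`` (or one built from the first
    frame's SF-oxygen layers) for every frame; ``"per-frame"`` rebuilds the
    plane positions from each frame's ``sf_oxygen_z`` while keeping the cap,
    depth and radius parameters.  Extra keyword arguments are forwarded to
    :func:`build_site_geometry` when geometry is derived from the frames.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames with a uniform stride")
    if geometry_mode not in ("static", "per-frame"):
        raise ValueError(f"unknown geometry_mode {geometry_mode!r}")

    if geometry is None:
        if frames[0].sf_oxygen_z is None:
            raise ValueError("no geometry given and frames carry no SF oxygen layers")
        geometry = build_site_geometry(frames[0].sf_oxygen_z, **geometry_kwargs)

    times = np.array([f.time for f in frames], dtype=float)
    codes: list[str] = []
    site_maps: list[dict] = []
    for f in frames:
        geo = geometry
        if geometry_mode == "per-frame":
            if f.sf_oxygen_z is None:
                raise ValueError("per-frame geometry requested but frame lacks sf_oxygen_z")
            geo = build_site_geometry(
                f.sf_oxygen_z,
                s0_cap=geometry.s0_cap,
                scav_depth=geometry.scav_depth,
                axis_radius=geometry.axis_radius,
                axis_xy=geometry.axis_xy,
            )
        code, ion_site = assign_frame_occupancy(f, geo)
        codes.append(code)
        site_maps.append(ion_site)
    return StateTrajectory(times=times, codes=codes, ion_site_index=site_maps)
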