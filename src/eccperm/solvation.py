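"""Ion-water radial distribution functions and first-solvation-shell radius.

The radius-corrected LJ parameters for scaled-charge ions are chosen so that
the first solvation shell of the scaled ion matches the unscaled force field.
The measurement behind that criterion is implemented here: an ion-water-oxygen
RDF on a fine grid (0.002 nm bins by default) and a Gaussian fit of the
highest points of the first peak, whose center is taken as the shell radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["RDFProfile", "ShellFit", "compute_rdf", "first_shell_radius"]

DEFAULT_BIN_WIDTH = 0.002  # nm
DEFAULT_FIT_POINTS = 7


@dataclass(frozen=True)
class RDFProfile:
    """g(r) on a uniform grid of bin centers (nm)."""

    bin_centers: np.ndarray
    g: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        c = np.asarray(self.bin_centers, dtype=float)
        g = np.asarray(self.g, dtype=float)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if c.shape != g.shape or c.ndim != 1:
            raise ValueError("bin_centers and g must be 1-D arrays of equal length")
        if c.size >= 2:
            steps = np.diff(c)
            if not np.allclose(steps, self.bin_width, rtol=1e-6, atol=1e-12):
                raise ValueError("bin grid is not uniform at the stated bin width")
        if not np.all(np.isfinite(g)) or np.any(g < 0):
            raise ValueError("g(r) must be finite and non-negative")
        object.__setattr__(self, "bin_centers", c)
        object.__setattr__(self, "g", g)


@dataclass(frozen=True)
class ShellFit:
    """Gaussian fit of the first RDF peak; ``center`` is the shell radius (nm)."""

    center: float
    width: float
    amplitude: float
    points_used: int


def _min_image_distances(ref: np.ndarray, tgt: np.ndarray, box: np.ndarray) -> np.ndarray:
    """All ref-target pair distances under the orthorhombic minimum-image convention."""
    d = tgt[None, :, :] - ref[:, None, :]
    d -= box * np.round(d / box)
    return np.sqrt((d * d).sum(axis=-1)).ravel()


def compute_rdf(
    reference_positions,
    target_positions,
    box,
    bin_width: float = DEFAULT_BIN_WIDTH,
    r_max: float | None = None,
) -> RDFProfile:
    """Radial distribution function between two selections over frames.

    Parameters
    ----------
    reference_positions, target_positions
        Per-frame coordinate arrays in nm: sequences of ``(n, 3)`` arrays (a
        single ``(n, 3)`` array is treated as one frame).  The two selections
        may share particles; zero-distance self pairs are excluded.
    box
        Orthorhombic box lengths ``(lx, ly, lz)`` in nm, applied with the
        minimum-image convention.
    bin_width, r_max
        Histogram resolution and range; ``r_max`` defaults to half the
        smallest box edge.

    Returns
    -------
    RDFProfile
        g(r) normalized by the ideal-gas shell density (uniform targets tend
        to 1 at large r).
    """
    ref_frames = _as_frames(reference_positions, "reference")
    tgt_frames = _as_frames(target_positions, "target")
    if len(ref_frames) != len(tgt_frames):
        raise ValueError("reference and target must cover the same frames")
    box = np.asarray(box, dtype=float).reshape(-1)
    if box.size != 3 or np.any(box <= 0):
        raise ValueError("box must be three positive orthorhombic edge lengths (nm)")
    if r_max is None:
        r_max = float(box.min()) / 2.0
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if r_max <= bin_width:
        raise ValueError(f"r_max={r_max} must exceed bin_width={bin_width}")

    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    counts = np.zeros(edges.size - 1, dtype=float)
    n_ref_total = 0
    n_tgt_total = 0
    for ref, tgt in zip(ref_frames, tgt_frames):
        dists = _min_image_distances(ref, tgt, box)
        dists = dists[dists > 1e-12]  # drop self pairs when selections overlap
        counts += np.histogram(dists, bins=edges)[0]
        n_ref_total += len(ref)
        n_tgt_total += len(tgt)

    n_frames = len(ref_frames)
    mean_ref = n_ref_total / n_frames
    mean_tgt = n_tgt_total / n_frames
    volume = float(np.prod(box))
    rho = mean_tgt / volume  # ideal-gas number density of targets
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = n_frames * mean_ref * rho * shell_vol
    g = counts / norm
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFProfile(bin_centers=centers, g=g, bin_width=bin_width)


def _as_frames(positions, label: str) -> list[np.ndarray]:
    if isinstance(positions, np.ndarray) and positions.ndim == 2:
        positions = [positions]
    frames = [np.atleast_2d(np.asarray(p, dtype=float)) for p in positions]
    if not frames or any(f.size == 0 for f in frames):
        raise ValueError(f"empty {label} selection")
    for f in frames:
        if f.shape[1] != 3:
            raise ValueError(f"{label} positions must be (n, 3) arrays")
    return frames


def _first_peak_index(g: np.ndarray) -> int:
    """Index of the first strict local maximum with g > 1 past the excluded-volume region."""
    n = g.size
    # skip the initial region where g == 0 (hard-core exclusion)
    start = 0
    while start < n and g[start] == 0.0:
        start += 1
    i = max(start, 1)
    while i < n - 1:
        if g[i] > 1.0 and g[i] > g[i - 1] and g[i] >= g[i + 1]:
            return i  # ties broken toward smaller r
        i += 1
    raise ValueError("no first peak found (g(r) is monotone or never exceeds 1)")


def _peak_window(g: np.ndarray, i_peak: int, n_points: int) -> np.ndarray:
    """Indices of the ``n_points`` highest bins contiguous with the peak."""
    lo = hi = i_peak
    while hi - lo + 1 < n_points:
        left = g[lo - 1] if lo > 0 else -np.inf
        right = g[hi + 1] if hi < g.size - 1 else -np.inf
        if left == right == -np.inf:
            break
        if left >= right:
            lo -= 1
        else:
            hi += 1
    return np.arange(lo, hi + 1)


def first_shell_radius(rdf: RDFProfile, n_points: int = DEFAULT_FIT_POINTS) -> ShellFit:
    """First-solvation-shell radius from a Gaussian fit of the first RDF peak.

    The ``n_points`` highest bins contiguous with the first local maximum are
    fitted with ``A * exp(-(r - mu)**2 / (2 sigma**2))``; the fitted ``mu`` is
    the shell radius.  The fit is amplitude-free: uniformly rescaling g(r)
    leaves the center unchanged.
    """
    g = rdf.g
    r = rdf.bin_centers
    if g.size < n_points:
        raise ValueError(f"RDF has {g.size} bins; need at least n_points={n_points}")
    i_peak = _first_peak_index(g)
    window = _peak_window(g, i_peak, n_points)
    rw, gw = r[window], g[window]

    def gauss(x, A, mu, sigma):
        return A * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))

    p0 = (float(g[i_peak]), float(r[i_peak]), 2.0 * rdf.bin_width)
    try:
        popt, _ = curve_fit(gauss, rw, gw, p0=p0, maxfev=10000, xtol=1e-12, ftol=1e-12)
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise ValueError(f"Gaussian fit of the first peak failed: {exc}") from exc
    A, mu, sigma = popt
    if not np.isfinite(mu) or sigma == 0:
        raise ValueError("singular Gaussian fit (zero width or non-finite center)")
    return ShellFit(center=float(mu), width=float(abs(sigma)), amplitude=float(A),
                    points_used=len(window))
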