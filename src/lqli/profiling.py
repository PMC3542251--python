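"""Density-vs-distance curves across the invasive front.

Detections inside a rectangle are counted in 5 um segments along the
perpendicular axis and standardized to cells per 5000 um^2 (the area of
one 1 mm x 5 um segment), so that with the default 1 mm width the density
equals the raw count.  Curves from several rectangles on the same tumor
are merged into a mean curve; a centered moving average smooths per-bin
Poisson noise before peak or ratio statistics are taken.

The axis convention places the host (peritumoral) tissue on [0, 2 mm] and
the tumor on [2, 4] mm; reported peak offsets are relative to the front
(v - L/2), negative meaning outside the tumor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .detection import CellDetection
from .geometry import RectangleROI, point_to_uv

__all__ = [
    "DensityProfile",
    "HeterogeneityStats",
    "PeakStats",
    "bin_counts",
    "to_density",
    "merge_profiles",
    "smooth_profile",
    "minmax_ratio",
    "peak_stats",
]

#: standard width the counts are normalized to, um (1 mm)
STANDARD_WIDTH_UM = 1000.0
#: default smoothing window in bins (21 bins = 105 um): below the
#: 200-400 um structure scale of margin peaks, above per-bin shot noise
DEFAULT_SMOOTH_BINS = 21
#: default window for the margin peak search, um along the axis
#: (600 um outside to 400 um inside the front)
DEFAULT_MARGIN_WINDOW = (1400.0, 2400.0)
#: pseudo-density floor protecting max/min ratios from empty bins
DEFAULT_RATIO_FLOOR = 0.2


@dataclass(frozen=True)
class DensityProfile:
    """Lymphocyte density per 5 um segment along the rectangle axis.

    ``density[i]`` is the cell density of segment ``[edges[i], edges[i+1])``
    in cells per 5000 um^2 (i.e. standardized to a 1 mm-wide strip).
    """

    bin_edges: np.ndarray
    density: np.ndarray
    n_rectangles: int = 1
    width_used: float = STANDARD_WIDTH_UM

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        dens = np.asarray(self.density, dtype=float)
        if edges.ndim != 1 or dens.ndim != 1 or len(edges) != len(dens) + 1:
            raise ValueError("bin_edges must be 1-D with len(density)+1 entries")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(dens < 0):
            raise ValueError("densities must be non-negative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "density", dens)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def length(self) -> float:
        return float(self.bin_edges[-1] - self.bin_edges[0])

    @property
    def front_v(self) -> float:
        """Axis position of the invasive front (middle of the axis)."""
        return float(self.bin_edges[0]) + self.length / 2.0

    @property
    def offsets(self) -> np.ndarray:
        """Bin centers relative to the front, um (negative = outside)."""
        return self.bin_centers - self.front_v


@dataclass(frozen=True)
class HeterogeneityStats:
    """Max/min density ratio over a stated axis window."""

    ratio: float
    window: tuple[float, float]
    floor_used: float


@dataclass(frozen=True)
class PeakStats:
    """Location and height of the density maximum near the margin."""

    peak_offset_um: float
    peak_height: float
    degenerate: bool = False


def bin_counts(dets: list[CellDetection], roi: RectangleROI) -> np.ndarray:
    """Integer cell counts per 5 um segment.

    Bins are half-open ``[v, v + bin)`` except the last, which is closed,
    so every detection inside the rectangle is counted exactly once.
    """
    edges = roi.bin_edges
    if not dets:
        return np.zeros(roi.n_bins, dtype=np.int64)
    pts = np.array([[d.x_um, d.y_um] for d in dets])
    _, v = point_to_uv(pts, roi)
    counts, _ = np.histogram(v, bins=edges)
    return counts.astype(np.int64)


def to_density(counts: np.ndarray, roi: RectangleROI) -> DensityProfile:
    """Standardize per-bin counts to cells per 5000 um^2 (1 mm-wide strip).

    With the default 1 mm rectangle width the density equals the raw
    count; narrower rectangles are scaled by 1000/W.
    """
    if roi.width <= 0:
        raise ValueError("rectangle width must be positive")
    scale = STANDARD_WIDTH_UM / roi.width
    return DensityProfile(
        bin_edges=roi.bin_edges,
        density=np.asarray(counts, dtype=float) * scale,
        n_rectangles=1,
        width_used=roi.width,
    )


def merge_profiles(profiles: list[DensityProfile]) -> DensityProfile:
    """Per-bin arithmetic mean of curves from several rectangles."""
    if not profiles:
        raise ValueError("merge_profiles needs at least one profile")
    edges = profiles[0].bin_edges
    for p in profiles[1:]:
        if len(p.bin_edges) != len(edges) or not np.allclose(p.bin_edges, edges):
            raise ValueError("profiles to merge must share the same bin grid")
    mean = np.mean([p.density for p in profiles], axis=0)
    return DensityProfile(
        bin_edges=edges,
        density=mean,
        n_rectangles=len(profiles),
        width_used=profiles[0].width_used,
    )


def smooth_profile(p: DensityProfile, window_bins: int = DEFAULT_SMOOTH_BINS) -> DensityProfile:
    """Centered moving average with edge truncation.

    At the boundaries the window shrinks to the available bins, so a
    constant profile is exactly preserved; ``window_bins=1`` is the
    identity.
    """
    if window_bins < 1 or window_bins % 2 == 0:
        raise ValueError("window_bins must be an odd integer >= 1")
    if window_bins == 1:
        return p
    kernel = np.ones(window_bins)
    num = np.convolve(p.density, kernel, mode="same")
    den = np.convolve(np.ones_like(p.density), kernel, mode="same")
    return replace(p, density=num / den)


def _window_slice(p: DensityProfile, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must satisfy v_lo < v_hi")
    centers = p.bin_centers
    sel = (centers >= lo) & (centers <= hi)
    if not sel.any():
        raise ValueError("window contains no bins")
    return sel


def minmax_ratio(
    p: DensityProfile,
    window: tuple[float, float] = (2000.0, 4000.0),
    floor: float = DEFAULT_RATIO_FLOOR,
    window_bins: int = DEFAULT_SMOOTH_BINS,
) -> HeterogeneityStats:
    """Max/min density ratio on the smoothed curve over an axis window.

    The denominator is floored at a small pseudo-density so empty bins do
    not produce infinite ratios.
    """
    s = smooth_profile(p, window_bins)
    sel = _window_slice(s, window)
    vals = s.density[sel]
    ratio = float(vals.max() / max(vals.min(), floor))
    return HeterogeneityStats(ratio=max(ratio, 1.0), window=(float(window[0]), float(window[1])), floor_used=floor)


def peak_stats(
    p: DensityProfile, margin_window: tuple[float, float] = DEFAULT_MARGIN_WINDOW
) -> PeakStats:
    """Argmax of an (already smoothed) curve over the margin window.

    The offset is reported relative to the front (negative = host side).
    When the maximum is a plateau of bins, the middle bin of the plateau
    is reported (for an even plateau, the member nearer the front); a
    completely flat window sets the ``degenerate`` flag.
    """
    sel = np.flatnonzero(_window_slice(p, margin_window))
    vals = p.density[sel]
    vmax = float(vals.max())
    cand = sel[vals >= vmax - 1e-12]
    if len(cand) % 2 == 1:
        idx = cand[len(cand) // 2]
    else:
        centers = p.bin_centers
        a, b = cand[len(cand) // 2 - 1], cand[len(cand) // 2]
        idx = a if abs(centers[a] - p.front_v) <= abs(centers[b] - p.front_v) else b
    degenerate = bool(vals.max() - vals.min() <= 1e-12)
    return PeakStats(
        peak_offset_um=float(p.bin_centers[idx] - p.front_v),
        peak_height=vmax,
        degenerate=degenerate,
    )
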