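"""Transition plots: smoothed occupancy maps of a fly's moving time.

A transition plot is a 2-D histogram of the platform positions a fly
visited *while moving* (immobile time contributes nothing), weighted by
time, then Gaussian-smoothed.  For display the map is normalised to its
maximum and every cell at or above ``cap_fraction`` (default 95 %) of the
maximum is pinned to the top colour level; below the cap the scale is
proportional.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .arena import ArenaConfig
from .errors import UsageError
from .io import Trajectory
from .kinematics import StepSeries, compute_steps

__all__ = ["OccupancyMap", "occupancy", "render_levels", "pool_maps", "save_heatmap"]


@dataclass
class OccupancyMap:
    """Time-weighted positional histogram over the platform bounding box.

    ``grid[i, j]`` is seconds of moving time in the cell with y-index i and
    x-index j (row 0 at the smallest y).  The grid extends a few smoothing
    lengths beyond the platform so that the Gaussian filter conserves mass.
    """

    grid: np.ndarray
    x_edges_mm: np.ndarray
    y_edges_mm: np.ndarray
    bin_size_mm: float
    sigma_bins: float
    cap_fraction: float = 0.95

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(left, right, bottom, top) in mm, for matplotlib ``imshow``."""
        return (
            float(self.x_edges_mm[0]),
            float(self.x_edges_mm[-1]),
            float(self.y_edges_mm[0]),
            float(self.y_edges_mm[-1]),
        )

    @property
    def total_mass_s(self) -> float:
        return float(self.grid.sum())


def occupancy(
    traj: Trajectory,
    steps: StepSeries | None = None,
    arena: ArenaConfig | None = None,
    bin_size_mm: float = 2.0,
    sigma_bins: float = 1.0,
    cap_fraction: float = 0.95,
    immobility_speed_mm_s: float = 1.0,
) -> OccupancyMap:
    """Build the smoothed moving-time occupancy map for one fly.

    Step midpoints of moving steps are binned with their step duration as
    weight; a Gaussian filter of scale ``sigma_bins`` is then applied.  A
    fly that never moves yields an all-zero (still valid) map.
    """
    if bin_size_mm <= 0:
        raise UsageError("bin_size_mm must be positive")
    arena = arena or ArenaConfig()
    if steps is None:
        steps = compute_steps(traj, immobility_speed_mm_s)
    # pad the platform bounding box so smoothing cannot push mass off-grid
    pad_bins = int(math.ceil(4.0 * sigma_bins)) + 1
    half = (
        math.ceil(arena.platform_radius_mm / bin_size_mm) + pad_bins
    ) * bin_size_mm
    n_bins = int(round(2 * half / bin_size_mm))
    edges = np.linspace(-half, half, n_bins + 1)
    m = steps.moving
    hist, _, _ = np.histogram2d(
        steps.y_mid_mm[m], steps.x_mid_mm[m], bins=[edges, edges], weights=steps.dt_s[m]
    )
    if sigma_bins > 0:
        hist = gaussian_filter(hist, sigma=sigma_bins, mode="constant")
    return OccupancyMap(
        grid=hist,
        x_edges_mm=edges,
        y_edges_mm=edges.copy(),
        bin_size_mm=bin_size_mm,
        sigma_bins=sigma_bins,
        cap_fraction=cap_fraction,
    )


def render_levels(occ: OccupancyMap, cap_fraction: float | None = None) -> np.ndarray:
    """Normalise a map to colour levels in [0, 1] with the top-level cap.

    Cells at or above ``cap_fraction`` of the maximum map to 1.0 (the top
    colour); below the cap the scale is proportional to occupancy.
    An all-zero map is returned unchanged with a warning.
    """
    cap = occ.cap_fraction if cap_fraction is None else cap_fraction
    peak = occ.grid.max()
    if peak <= 0:
        warnings.warn("occupancy map is identically zero; nothing to render", stacklevel=2)
        return np.zeros_like(occ.grid)
    levels = occ.grid / peak
    levels[levels >= cap] = 1.0
    return levels


def pool_maps(maps: list[OccupancyMap]) -> OccupancyMap:
    """Sum per-fly maps (e.g. all flies of one strain x replicate panel).

    Normalisation to colour levels happens after pooling, so frequently
    visited positions of the group dominate the panel.
    """
    if not maps:
        raise UsageError("cannot pool zero maps")
    first = maps[0]
    for m in maps[1:]:
        if m.grid.shape != first.grid.shape or m.bin_size_mm != first.bin_size_mm:
            raise UsageError("cannot pool maps with different grids")
    return OccupancyMap(
        grid=np.sum([m.grid for m in maps], axis=0),
        x_edges_mm=first.x_edges_mm,
        y_edges_mm=first.y_edges_mm,
        bin_size_mm=first.bin_size_mm,
        sigma_bins=first.sigma_bins,
        cap_fraction=first.cap_fraction,
    )


def save_heatmap(
    occ: OccupancyMap,
    path,
    arena: ArenaConfig | None = None,
    title: str = "",
) -> None:
    """Render a transition plot to PNG/SVG (format chosen by file suffix)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    arena = arena or ArenaConfig()
    levels = render_levels(occ)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(
        levels,
        origin="lower",
        extent=occ.extent,
        cmap="jet",
        vmin=0.0,
        vmax=1.0,
        interpolation="nearest",
    )
    rim = plt.Circle((0, 0), arena.platform_radius_mm, fill=False, color="white", lw=1.0)
    ax.add_patch(rim)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    if title:
        ax.set_title(title)
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
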