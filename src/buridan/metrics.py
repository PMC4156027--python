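"""The twelve locomotor parameters computed per fly.

The parameters fall into three broad families:

* temporal — number of pauses, median pause length, median activity-bout
  duration, total time active;
* spatial — thigmotaxis while moving and while sitting (time share in the
  outer equal-area annulus), stripe deviation (median angle between the
  walking direction and the direction to the nearer stripe), turning angle
  and meander (path tortuosity);
* mixed — median walking speed, distance travelled per minute, and the
  number of walks between the two stripe end zones.

All angle outputs are in degrees.  Metrics that need movement (speed and
angle statistics) are NaN, with a warning, for a fly that never moved.
"""

from __future__ import annotations

import warnings

import numpy as np

from .arena import ArenaConfig
from .errors import UsageError
from .io import FlyMetadata, MetricsRow, Trajectory
from .kinematics import BoutSegmentation, StepSeries, compute_steps, segment_bouts

__all__ = [
    "median_speed",
    "distance_per_min",
    "turning_angle",
    "meander",
    "thigmotaxis",
    "stripe_deviation",
    "count_walks",
    "pause_stats",
    "compute_all_metrics",
    "metrics_from_steps",
]


def _warn_nan(reason: str) -> float:
    warnings.warn(reason, stacklevel=3)
    return float("nan")


def median_speed(steps: StepSeries) -> float:
    """Median speed (mm/s) over moving steps only."""
    sel = steps.speed_mm_s[steps.moving]
    if sel.size == 0:
        return _warn_nan("median_speed undefined: no moving steps")
    return float(np.median(sel))


def distance_per_min(steps: StepSeries | Trajectory) -> float:
    """Total path length divided by record duration, in mm/min.

    Uses every step, moving or not, so the measure reflects the raw
    trajectory; immobility flags only enter the speed and angle metrics.
    """
    if isinstance(steps, Trajectory):
        steps = compute_steps(steps)
    if steps.duration_s <= 0:
        raise UsageError("record duration must be positive")
    return float(steps.step_mm.sum() * 60.0 / steps.duration_s)


def turning_angle(steps: StepSeries) -> float:
    """Median absolute heading change (deg in [0, 180]) between consecutive moving steps."""
    turns = steps.turn_deg[~np.isnan(steps.turn_deg)]
    if turns.size == 0:
        return _warn_nan("turning_angle undefined: no consecutive moving steps")
    return float(np.median(turns))


def meander(steps: StepSeries) -> float:
    """Median of per-step turning angle divided by that step's speed (deg*s/mm)."""
    ok = ~np.isnan(steps.turn_deg)
    if not ok.any():
        return _warn_nan("meander undefined: no consecutive moving steps")
    return float(np.median(steps.turn_deg[ok] / steps.speed_mm_s[ok]))


def _pause_membership(steps: StepSeries, segmentation: BoutSegmentation) -> np.ndarray:
    """Boolean mask of steps whose midpoint falls inside a pause."""
    if not segmentation.pauses:
        return np.zeros(steps.n_steps, dtype=bool)
    edges = np.array(segmentation.pauses).ravel()
    return np.searchsorted(edges, steps.t_mid_s) % 2 == 1


def thigmotaxis(
    steps: StepSeries,
    segmentation: BoutSegmentation,
    arena: ArenaConfig,
    state: str = "moving",
) -> float:
    """Share of time spent in the outer annulus of area equal to the inner disc.

    ``state="moving"`` selects moving steps; ``state="sitting"`` selects
    steps inside pauses.  Returns NaN when the selected time is zero.
    """
    if state == "moving":
        sel = steps.moving
    elif state == "sitting":
        sel = _pause_membership(steps, segmentation)
    else:
        raise UsageError(f"state must be 'moving' or 'sitting', not {state!r}")
    total = steps.dt_s[sel].sum()
    if total <= 0:
        return float("nan")
    outer = steps.r_mm > arena.thigmotaxis_boundary_radius_mm
    return float(steps.dt_s[sel & outer].sum() / total)


def _nearest_stripe_deviation_deg(
    heading_deg: np.ndarray,
    x_mm: np.ndarray,
    y_mm: np.ndarray,
    arena: ArenaConfig,
) -> np.ndarray:
    """Per-sample angle (deg, clipped to [0, 90]) to the nearer stripe direction."""
    centers = arena.stripe_centers_mm
    dev = np.full(len(heading_deg), np.inf)
    for cx, cy in centers:
        bearing = np.degrees(np.arctan2(cy - y_mm, cx - x_mm))
        d = np.abs(heading_deg - bearing) % 360.0
        d = np.where(d > 180.0, 360.0 - d, d)
        dev = np.minimum(dev, d)
    # with opposed stripes the nearer deviation can only exceed 90 deg by
    # the small parallax of off-centre positions; clip to the nominal range
    return np.minimum(dev, 90.0)


def stripe_deviation(steps: StepSeries, arena: ArenaConfig) -> float:
    """Median deviation (deg in [0, 90]) between walking direction and the nearer stripe.

    For each moving step the bearings from the step midpoint to both stripe
    centres are computed and the smaller absolute angular difference to the
    heading is taken.  0 means the fly always walks straight at a stripe;
    an uncorrelated random walk scores ~45.
    """
    m = steps.moving
    if not m.any():
        return _warn_nan("stripe_deviation undefined: no moving steps")
    dev = _nearest_stripe_deviation_deg(
        steps.heading_deg[m], steps.x_mid_mm[m], steps.y_mid_mm[m], arena
    )
    return float(np.median(dev))


def _zone_labels(steps: StepSeries, arena: ArenaConfig) -> np.ndarray:
    """End-zone membership per step midpoint: 0 outside, 1/2 for the two stripe zones."""
    r_min = arena.walk_zone_fraction * arena.platform_radius_mm
    pos_angle = np.degrees(np.arctan2(steps.y_mid_mm, steps.x_mid_mm))
    labels = np.zeros(steps.n_steps, dtype=np.int8)
    for k, bearing in enumerate(arena.stripe_bearings_deg, start=1):
        d = np.abs(pos_angle - bearing) % 360.0
        d = np.where(d > 180.0, 360.0 - d, d)
        in_zone = (steps.r_mm > r_min) & (d <= arena.walk_zone_half_angle_deg)
        labels[in_zone] = k
    return labels


def count_walks(steps: StepSeries, arena: ArenaConfig) -> int:
    """Number of walks between the two stripes.

    A walk is counted each time the fly enters one stripe end zone having
    last occupied the other.  End zones are the sectors within
    ``walk_zone_half_angle_deg`` of a stripe bearing beyond
    ``walk_zone_fraction`` of the platform radius.
    """
    labels = _zone_labels(steps, arena)
    visits = labels[labels > 0]
    if visits.size == 0:
        return 0
    changes = visits[np.concatenate([[True], visits[1:] != visits[:-1]])]
    return int(len(changes) - 1)


def pause_stats(segmentation: BoutSegmentation) -> dict:
    """Temporal summary: pause count, median pause/bout duration, total time active."""
    pause_lengths = np.array([e - s for s, e in segmentation.pauses])
    bout_lengths = np.array([e - s for s, e in segmentation.bouts])
    return {
        "n_pauses": int(len(pause_lengths)),
        "pause_length": float(np.median(pause_lengths)) if pause_lengths.size else float("nan"),
        "bout_duration": float(np.median(bout_lengths)) if bout_lengths.size else float("nan"),
        "time_active": float(bout_lengths.sum()) if bout_lengths.size else 0.0,
    }


def metrics_from_steps(
    meta: FlyMetadata,
    steps: StepSeries,
    segmentation: BoutSegmentation,
    arena: ArenaConfig,
) -> MetricsRow:
    """Assemble the twelve parameters from precomputed kinematics."""
    temporal = pause_stats(segmentation)
    return MetricsRow(
        fly_id=meta.fly_id,
        strain=meta.strain,
        replicate=meta.replicate,
        median_speed=median_speed(steps),
        distance_per_min=distance_per_min(steps),
        turning_angle=turning_angle(steps),
        meander=meander(steps),
        thigmo_moving=thigmotaxis(steps, segmentation, arena, "moving"),
        thigmo_sitting=thigmotaxis(steps, segmentation, arena, "sitting"),
        stripe_deviation=stripe_deviation(steps, arena),
        n_walks=count_walks(steps, arena),
        **temporal,
    )


def compute_all_metrics(
    traj: Trajectory,
    arena: ArenaConfig | None = None,
    immobility_speed_mm_s: float = 1.0,
    min_pause_s: float = 1.0,
    smooth_window: int = 0,
) -> MetricsRow:
    """Compute all twelve locomotor parameters for one fly.

    Degenerate but parseable flies (e.g. completely stationary) yield NaN
    for the undefined metrics with a warning, never an exception.
    """
    arena = arena or ArenaConfig()
    steps = compute_steps(traj, immobility_speed_mm_s, smooth_window)
    segmentation = segment_bouts(steps, min_pause_s)
    return metrics_from_steps(traj.meta, steps, segmentation, arena)
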