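"""Per-step kinematics and activity/pause segmentation.

A trajectory of n samples yields n-1 *steps*.  Step i covers the interval
[t_i, t_{i+1}]; its displacement, speed and heading are computed from the
two bounding samples and attributed to the interval midpoint.  A step is
*moving* when its speed reaches the immobility threshold; maximal runs of
non-moving steps longer than the pause threshold are *pauses*, and the rest
of the record forms *activity bouts* (brief sub-threshold stops are
absorbed into the surrounding bout).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, UsageError
from .io import Trajectory

__all__ = ["StepSeries", "BoutSegmentation", "compute_steps", "segment_bouts"]


@dataclass
class StepSeries:
    """Per-step kinematic series derived from one trajectory.

    All arrays have length ``n_samples - 1``.  ``heading_deg`` is NaN for
    zero-length steps; ``turn_deg[i]`` is the absolute heading change from
    step i-1 to step i, defined (non-NaN) only when both are moving steps.
    """

    t_mid_s: np.ndarray
    dt_s: np.ndarray
    step_mm: np.ndarray
    speed_mm_s: np.ndarray
    heading_deg: np.ndarray
    turn_deg: np.ndarray
    x_mid_mm: np.ndarray
    y_mid_mm: np.ndarray
    r_mm: np.ndarray
    moving: np.ndarray
    t_start_s: float
    t_end_s: float

    @property
    def n_steps(self) -> int:
        return len(self.t_mid_s)

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s


@dataclass
class BoutSegmentation:
    """Alternating activity bouts and pauses tiling one record.

    ``bouts`` and ``pauses`` are lists of ``(start_s, end_s)`` intervals;
    together they tile ``[t_start_s, t_end_s]`` exactly.
    """

    bouts: list[tuple[float, float]]
    pauses: list[tuple[float, float]]
    t_start_s: float
    t_end_s: float
    min_pause_s: float = 1.0


def _boxcar(values: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    padded = np.pad(values, window // 2, mode="edge")
    out = np.convolve(padded, kernel, mode="valid")
    return out[: len(values)]


def compute_steps(
    traj: Trajectory,
    immobility_speed_mm_s: float = 1.0,
    smooth_window: int = 0,
) -> StepSeries:
    """Differentiate a trajectory into a :class:`StepSeries`.

    Parameters
    ----------
    immobility_speed_mm_s : float
        Steps slower than this are flagged as not moving.  Must be positive.
    smooth_window : int
        Optional boxcar window (in samples) applied to x and y before
        differencing; 0 or 1 disables smoothing (the default).
    """
    if immobility_speed_mm_s <= 0:
        raise UsageError("immobility_speed_mm_s must be positive")
    if len(traj) < 2:
        raise UsageError("trajectory needs at least two samples")
    t = traj.times_s
    x, y = traj.x_mm, traj.y_mm
    if smooth_window and smooth_window > 1:
        x = _boxcar(x, int(smooth_window))
        y = _boxcar(y, int(smooth_window))
    dt = np.diff(t)
    zero_dt = np.nonzero(dt == 0)[0]
    if zero_dt.size:
        raise DataError(f"duplicate timestamp at sample {int(zero_dt[0]) + 1}")
    dx = np.diff(x)
    dy = np.diff(y)
    step = np.hypot(dx, dy)
    speed = step / dt
    heading = np.degrees(np.arctan2(dy, dx)) % 360.0
    heading[step == 0] = np.nan
    moving = (speed >= immobility_speed_mm_s) & (step > 0)

    turn = np.full(len(step), np.nan)
    if len(step) > 1:
        pair = moving[:-1] & moving[1:]
        dh = np.abs(heading[1:] - heading[:-1])
        dh = np.where(dh > 180.0, 360.0 - dh, dh)
        turn[1:][pair] = dh[pair]

    x_mid = 0.5 * (x[:-1] + x[1:])
    y_mid = 0.5 * (y[:-1] + y[1:])
    return StepSeries(
        t_mid_s=0.5 * (t[:-1] + t[1:]),
        dt_s=dt,
        step_mm=step,
        speed_mm_s=speed,
        heading_deg=heading,
        turn_deg=turn,
        x_mid_mm=x_mid,
        y_mid_mm=y_mid,
        r_mm=np.hypot(x_mid, y_mid),
        moving=moving,
        t_start_s=float(t[0]),
        t_end_s=float(t[-1]),
    )


def segment_bouts(steps: StepSeries, min_pause_s: float = 1.0) -> BoutSegmentation:
    """Split a record into activity bouts and pauses.

    A pause is a maximal run of non-moving steps whose total duration
    strictly exceeds ``min_pause_s`` (the canonical threshold is "stopped
    for more than 1 s", so exactly 1.0 s is *not* a pause).  Everything
    else — including shorter stops — belongs to activity bouts.  An
    entirely immobile record longer than the threshold is one pause.
    """
    if steps.n_steps == 0:
        raise UsageError("empty step series")
    m = steps.moving
    starts = steps.t_mid_s - steps.dt_s / 2.0
    ends = steps.t_mid_s + steps.dt_s / 2.0

    # maximal runs of immobile steps
    pauses: list[tuple[float, float]] = []
    boundaries = np.nonzero(np.diff(m.astype(np.int8)))[0] + 1
    run_edges = np.concatenate([[0], boundaries, [len(m)]])
    for a, b in zip(run_edges[:-1], run_edges[1:]):
        if not m[a]:
            s, e = float(starts[a]), float(ends[b - 1])
            if e - s > min_pause_s:
                pauses.append((s, e))

    # bouts are the complement of the pauses within the record span;
    # the tolerance swallows float slivers from midpoint arithmetic
    eps = 1e-9 * max(1.0, abs(steps.t_end_s))
    bouts: list[tuple[float, float]] = []
    cursor = steps.t_start_s
    for s, e in pauses:
        if s > cursor + eps:
            bouts.append((cursor, s))
        cursor = e
    if steps.t_end_s > cursor + eps:
        bouts.append((cursor, steps.t_end_s))
    return BoutSegmentation(
        bouts=bouts,
        pauses=pauses,
        t_start_s=steps.t_start_s,
        t_end_s=steps.t_end_s,
        min_pause_s=min_pause_s,
    )
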