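"""Reading and writing per-fly trajectory files and the metrics table.

Each fly is stored as a pair of plain-text files:

* ``<fly_id>.csv`` — the trajectory, comma-separated with header
  ``time_s,x_mm,y_mm`` (common short aliases ``t``/``time``, ``x``, ``y``
  are accepted on read);
* ``<fly_id>.yaml`` — flat YAML metadata with at least ``fly_id``,
  ``strain`` and ``replicate``.

The metrics table is a CSV with one row per fly: three identifier columns
followed by the twelve locomotor parameters in a fixed order.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arena import ArenaConfig
from .errors import DataError, FormatError, UsageError

__all__ = [
    "FlyMetadata",
    "Trajectory",
    "MetricsRow",
    "METRIC_COLUMNS",
    "ID_COLUMNS",
    "read_trajectory",
    "write_trajectory",
    "read_metadata",
    "write_metadata",
    "metrics_table",
    "write_metrics_table",
    "read_metrics_table",
]

logger = logging.getLogger(__name__)

#: Identifier columns of the metrics table, in order.
ID_COLUMNS = ["fly_id", "strain", "replicate"]

#: The twelve locomotor parameters, in the column order of the metrics table.
METRIC_COLUMNS = [
    "median_speed",
    "distance_per_min",
    "turning_angle",
    "meander",
    "thigmo_moving",
    "thigmo_sitting",
    "stripe_deviation",
    "n_walks",
    "n_pauses",
    "bout_duration",
    "pause_length",
    "time_active",
]

NOMINAL_DURATION_S = 300.0

_TIME_ALIASES = {"time_s", "t", "time", "t_s"}
_X_ALIASES = {"x_mm", "x"}
_Y_ALIASES = {"y_mm", "y"}


@dataclass
class FlyMetadata:
    """Identity and grouping labels for one fly."""

    fly_id: str
    strain: str = ""
    replicate: str = ""
    setup_id: str = ""
    extra: dict = field(default_factory=dict)


@dataclass
class Trajectory:
    """Timestamped centroid positions of one fly in the arena frame (mm)."""

    times_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    meta: FlyMetadata = field(default_factory=lambda: FlyMetadata(fly_id="unknown"))

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        if not (len(self.times_s) == len(self.x_mm) == len(self.y_mm)):
            raise DataError("times, x and y must have equal lengths")

    def __len__(self) -> int:
        return len(self.times_s)

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0]) if len(self) else 0.0


@dataclass
class MetricsRow:
    """The twelve locomotor parameters of one fly, plus its identifiers.

    Angle metrics are NaN when undefined (e.g. a fly that never moved);
    proportions lie in [0, 1]; ``stripe_deviation`` lies in [0, 90] degrees
    (0 = always walking straight at a stripe, 45 = random-walk baseline).
    """

    fly_id: str
    strain: str
    replicate: str
    median_speed: float  # mm/s, over moving steps
    distance_per_min: float  # mm/min, total path length per minute
    turning_angle: float  # deg, median absolute heading change while moving
    meander: float  # deg*s/mm, median of per-step turn/speed
    thigmo_moving: float  # proportion of moving time in the outer annulus
    thigmo_sitting: float  # proportion of pause time in the outer annulus
    stripe_deviation: float  # deg, median deviation from nearest stripe
    n_walks: int  # walks between the two stripe end zones
    n_pauses: int  # immobile intervals longer than the pause threshold
    bout_duration: float  # s, median activity-bout duration
    pause_length: float  # s, median pause duration
    time_active: float  # s, summed activity-bout duration

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _resolve_columns(columns) -> dict:
    """Map actual header names to the canonical time/x/y names."""
    mapping = {}
    lowered = {c.strip().lower(): c for c in columns}
    for canon, aliases in (
        ("time_s", _TIME_ALIASES),
        ("x_mm", _X_ALIASES),
        ("y_mm", _Y_ALIASES),
    ):
        hit = [orig for low, orig in lowered.items() if low in aliases]
        if not hit:
            raise FormatError(f"trajectory file is missing a {canon!r} column")
        mapping[canon] = hit[0]
    return mapping


def read_metadata(meta_path) -> FlyMetadata:
    """Read a flat YAML metadata file into a :class:`FlyMetadata`."""
    with open(meta_path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise FormatError(f"metadata file {meta_path!s} must contain a mapping")
    if "fly_id" not in raw:
        raise FormatError(f"metadata file {meta_path!s} is missing 'fly_id'")
    known = {k: str(raw.pop(k)) for k in ("fly_id", "strain", "replicate", "setup_id") if k in raw}
    return FlyMetadata(extra=raw, **known)


def write_metadata(meta: FlyMetadata, meta_path) -> None:
    out = {
        "fly_id": meta.fly_id,
        "strain": meta.strain,
        "replicate": meta.replicate,
    }
    if meta.setup_id:
        out["setup_id"] = meta.setup_id
    out.update(meta.extra)
    with open(meta_path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


def read_trajectory(
    data_path,
    meta_path=None,
    arena: ArenaConfig | None = None,
    *,
    duration_tolerance: float = 0.05,
    position_noise_mm: float = 2.0,
) -> Trajectory:
    """Read one fly's trajectory (and optionally its metadata file).

    The time column must be non-decreasing.  Points that lie outside the
    platform by more than ``position_noise_mm`` (tracker noise allowance)
    are clipped back to the rim and logged.  Records whose duration is more
    than ``duration_tolerance`` (fractional) away from the nominal 300 s
    recording length trigger a warning but are returned; downstream metrics
    use the actual duration.
    """
    arena = arena or ArenaConfig()
    try:
        frame = pd.read_csv(data_path)
    except pd.errors.EmptyDataError:
        raise DataError(f"trajectory file {data_path!s} is empty") from None
    if frame.empty:
        raise DataError(f"trajectory file {data_path!s} has a header but no rows")
    cols = _resolve_columns(frame.columns)
    t = frame[cols["time_s"]].to_numpy(dtype=float)
    x = frame[cols["x_mm"]].to_numpy(dtype=float)
    y = frame[cols["y_mm"]].to_numpy(dtype=float)
    if np.isnan(t).any() or np.isnan(x).any() or np.isnan(y).any():
        raise DataError(f"trajectory file {data_path!s} contains missing values")
    dec = np.nonzero(np.diff(t) < 0)[0]
    if dec.size:
        raise DataError(
            f"time column decreases at row {int(dec[0]) + 1} in {data_path!s}"
        )

    r = np.hypot(x, y)
    outside = r > arena.platform_radius_mm + position_noise_mm
    if outside.any():
        logger.info(
            "%s: clipping %d point(s) outside the platform to the rim",
            data_path,
            int(outside.sum()),
        )
    clip = r > arena.platform_radius_mm
    if clip.any():
        scale = arena.platform_radius_mm / r[clip]
        x = x.copy()
        y = y.copy()
        x[clip] *= scale
        y[clip] *= scale

    meta = read_metadata(meta_path) if meta_path is not None else FlyMetadata(
        fly_id=Path(str(data_path)).stem
    )
    traj = Trajectory(times_s=t, x_mm=x, y_mm=y, meta=meta)
    if not math.isclose(
        traj.duration_s, NOMINAL_DURATION_S, rel_tol=duration_tolerance
    ):
        warnings.warn(
            f"fly {meta.fly_id}: record duration {traj.duration_s:.1f} s differs "
            f"from the nominal {NOMINAL_DURATION_S:.0f} s by more than "
            f"{duration_tolerance:.0%}; metrics will use the actual duration",
            stacklevel=2,
        )
    return traj


def write_trajectory(traj: Trajectory, data_path, meta_path=None) -> None:
    """Write a trajectory (and optionally its metadata) in the package dialect."""
    frame = pd.DataFrame(
        {"time_s": traj.times_s, "x_mm": traj.x_mm, "y_mm": traj.y_mm}
    )
    frame.to_csv(data_path, index=False, float_format="%.10g")
    if meta_path is not None:
        write_metadata(traj.meta, meta_path)


def metrics_table(rows) -> pd.DataFrame:
    """Assemble :class:`MetricsRow` objects (or dicts) into an ordered DataFrame."""
    if isinstance(rows, pd.DataFrame):
        missing = [c for c in ID_COLUMNS + METRIC_COLUMNS if c not in rows.columns]
        if missing:
            raise UsageError(f"metrics table is missing column(s) {missing}")
        return rows.loc[:, ID_COLUMNS + METRIC_COLUMNS].reset_index(drop=True)
    dicts = []
    for row in rows:
        d = row.as_dict() if isinstance(row, MetricsRow) else dict(row)
        missing = [c for c in ID_COLUMNS + METRIC_COLUMNS if c not in d]
        if missing:
            raise UsageError(f"metrics row for {d.get('fly_id', '?')!r} is missing {missing}")
        dicts.append({c: d[c] for c in ID_COLUMNS + METRIC_COLUMNS})
    if not dicts:
        raise UsageError("cannot build a metrics table from zero rows")
    return pd.DataFrame(dicts, columns=ID_COLUMNS + METRIC_COLUMNS)


def write_metrics_table(rows, path) -> None:
    """Write the per-fly metrics table as CSV with a stable column order."""
    table = metrics_table(rows)
    table.to_csv(path, index=False, float_format="%.10g")


def read_metrics_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={c: str for c in ID_COLUMNS})
    missing = [c for c in ID_COLUMNS + METRIC_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"metrics table {path!s} is missing column(s) {missing}")
    return table
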