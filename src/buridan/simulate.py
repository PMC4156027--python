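"""Synthetic fly trajectories with the statistical structure the analysis assumes.

The walker is a two-state (move/pause) correlated random walk on the
platform disc.  While moving, each step's heading is drawn from a von
Mises mixture: with probability ``fixation_strength`` the fly orients
toward the nearer of the two stripes (concentration ``fixation_kappa``),
otherwise it continues near its previous heading (concentration
``persistence_kappa``).  Step speeds are gamma distributed; move/pause
switching follows exponential holding times; positions that would leave
the platform are folded back at the rim (the real fly turns at the water
moat).  ``fixation_strength = 0`` with ``persistence_kappa = 0`` is the
uncorrelated random walk used as the stripe-fixation baseline.

Every fly draws all of its randomness from its own seed stream, so a fly
simulated alone is bit-identical to the same fly simulated inside a batch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from numpy.random import Generator, SeedSequence, default_rng

from .arena import ArenaConfig
from .errors import UsageError
from .io import FlyMetadata, Trajectory

__all__ = [
    "FlyModelParams",
    "StrainSpec",
    "DEFAULT_REPLICATE_SHIFT",
    "simulate_fly",
    "simulate_flies",
    "simulate_random_walk",
    "random_walk_params",
    "plan_study",
    "simulate_study",
]


@dataclass(frozen=True)
class FlyModelParams:
    """Generative parameters for one fly.

    Attributes
    ----------
    mean_speed_mm_s, speed_cv : float
        Mean and coefficient of variation of the gamma-distributed step
        speeds (``speed_cv = 0`` gives constant speed).
    persistence_kappa : float
        von Mises concentration of heading continuation (0 = uncorrelated).
    fixation_strength : float
        Probability in [0, 1] that a step orients toward the nearer stripe
        instead of continuing the previous heading.
    fixation_kappa : float
        von Mises concentration of the stripe-directed component.
    p_stop_per_s, p_go_per_s : float
        Move->pause and pause->move switching rates (per second).
    dt_s, duration_s : float
        Sampling interval and record length.
    """

    mean_speed_mm_s: float = 15.0
    speed_cv: float = 0.25
    persistence_kappa: float = 4.0
    fixation_strength: float = 0.3
    fixation_kappa: float = 4.0
    p_stop_per_s: float = 0.05
    p_go_per_s: float = 0.5
    dt_s: float = 0.05
    duration_s: float = 300.0
    seed: int | None = None

    def validate(self) -> None:
        if self.mean_speed_mm_s <= 0:
            raise UsageError("mean_speed_mm_s must be positive")
        if self.speed_cv < 0:
            raise UsageError("speed_cv must be non-negative")
        if not 0.0 <= self.fixation_strength <= 1.0:
            raise UsageError("fixation_strength must lie in [0, 1]")
        if self.persistence_kappa < 0 or self.fixation_kappa < 0:
            raise UsageError("kappa parameters must be non-negative")
        if self.p_stop_per_s < 0 or self.p_go_per_s < 0:
            raise UsageError("switching rates must be non-negative")
        if self.dt_s <= 0 or self.duration_s <= 0:
            raise UsageError("dt_s and duration_s must be positive")

    def with_shift(self, shift: dict) -> "FlyModelParams":
        """Return a copy with additive perturbations applied to named fields."""
        known = set(self.__dataclass_fields__)
        unknown = set(shift) - known
        if unknown:
            raise UsageError(f"unknown parameter field(s) in shift: {sorted(unknown)}")
        return replace(self, **{k: getattr(self, k) + v for k, v in shift.items()})


#: Small activity shift applied to the second replicate by default; it
#: emulates the between-years hardware difference (a real but numerically
#: small replicate effect) without touching the spatial parameters.
DEFAULT_REPLICATE_SHIFT: dict = {"mean_speed_mm_s": 0.75, "p_stop_per_s": 0.005}


@dataclass(frozen=True)
class StrainSpec:
    """One (sub-)strain of the simulated study design."""

    name: str
    params: FlyModelParams = field(default_factory=FlyModelParams)
    n_flies: int = 12
    replicate_shifts: tuple[dict, ...] = field(
        default_factory=lambda: ({}, dict(DEFAULT_REPLICATE_SHIFT))
    )

    def __post_init__(self) -> None:
        if self.n_flies < 1:
            raise UsageError("n_flies must be at least 1")
        if not self.name:
            raise UsageError("strain name must be non-empty")


def random_walk_params(
    duration_s: float = 300.0, dt_s: float = 0.05, speed_mm_s: float = 15.0
) -> FlyModelParams:
    """Parameters of the uncorrelated random-walk baseline (no fixation, no pauses)."""
    return FlyModelParams(
        mean_speed_mm_s=speed_mm_s,
        speed_cv=0.0,
        persistence_kappa=0.0,
        fixation_strength=0.0,
        fixation_kappa=0.0,
        p_stop_per_s=0.0,
        p_go_per_s=1.0,
        dt_s=dt_s,
        duration_s=duration_s,
    )


def _resolve_seed(params: FlyModelParams, seed) -> SeedSequence:
    if isinstance(seed, SeedSequence):
        return seed
    if seed is not None:
        return SeedSequence(seed)
    if params.seed is not None:
        return SeedSequence(params.seed)
    return SeedSequence()


def _draw_fly(params: FlyModelParams, n_steps: int, arena: ArenaConfig, rng: Generator):
    """Pre-draw all randomness for one fly from its own generator.

    Draw order is fixed and is part of the reproducibility contract.
    """
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    r0 = arena.platform_radius_mm * np.sqrt(rng.uniform())
    h0 = rng.uniform(-np.pi, np.pi)
    u_switch = rng.random(n_steps)
    u_mix = rng.random(n_steps)
    # one von Mises draw per step, with the concentration of the branch
    # (persistence vs stripe attraction) that u_mix selects for that step
    if params.fixation_strength <= 0.0:
        vm = rng.vonmises(0.0, params.persistence_kappa, n_steps)
    elif params.fixation_strength >= 1.0:
        vm = rng.vonmises(0.0, params.fixation_kappa, n_steps)
    else:
        kappa = np.where(
            u_mix < params.fixation_strength,
            params.fixation_kappa,
            params.persistence_kappa,
        )
        vm = rng.vonmises(0.0, kappa)
    if params.speed_cv > 0:
        shape = 1.0 / params.speed_cv**2
        speeds = rng.gamma(shape, params.mean_speed_mm_s / shape, n_steps)
    else:
        speeds = np.full(n_steps, params.mean_speed_mm_s)
    start = np.array([r0 * np.cos(theta0), r0 * np.sin(theta0)])
    return start, h0, u_switch, u_mix, vm, speeds


@njit(cache=True)
def _step_kernel(
    x0, y0, h0, u_switch, u_mix, vm, step_len,
    p_stay_moving, p_resume, fix_w, R, s1x, s1y, s2x, s2y, pos
):  # pragma: no cover - exercised via _step_batch
    n, T = u_switch.shape
    two_pi = 2.0 * math.pi
    for k in range(n):
        x = x0[k]
        y = y0[k]
        h = h0[k]
        moving = True
        pos[k, 0, 0] = x
        pos[k, 0, 1] = y
        for i in range(T):
            u = u_switch[k, i]
            moving = u < p_stay_moving[k] if moving else u < p_resume[k]
            # bearing to the stripe closer to the current heading
            b1 = math.atan2(s1y - y, s1x - x)
            b2 = math.atan2(s2y - y, s2x - x)
            d1 = abs(b1 - h) % two_pi
            if d1 > math.pi:
                d1 = two_pi - d1
            d2 = abs(b2 - h) % two_pi
            if d2 > math.pi:
                d2 = two_pi - d2
            target = b1 if d1 <= d2 else b2
            fixate = u_mix[k, i] < fix_w[k]
            mu = target if fixate else h
            h_new = mu + vm[k, i]
            st = step_len[k, i] if moving else 0.0
            xn = x + st * math.cos(h_new)
            yn = y + st * math.sin(h_new)
            if xn * xn + yn * yn > R * R:
                # radial fold at the rim (moat): bring the overshoot back inside
                r = math.sqrt(xn * xn + yn * yn)
                f = max(2.0 * R - r, 0.0) / r
                xn *= f
                yn *= f
                if moving:
                    h_new = math.atan2(yn - y, xn - x)
            if moving:
                h = h_new
            x = xn
            y = yn
            pos[k, i + 1, 0] = x
            pos[k, i + 1, 1] = y


def _reference_step_batch(inputs, R, s1x, s1y, s2x, s2y, pos):
    """Pure-numpy twin of :func:`_step_kernel`, kept as a cross-check oracle.

    Implements the identical update formulas step by step across the batch;
    used in tests to pin down the compiled kernel's semantics.
    """
    x0, y0, h0, u_switch, u_mix, vm, step_len, p_stay, p_res, fix_w = inputs
    n, T = u_switch.shape
    two_pi = 2.0 * np.pi
    x = x0.copy()
    y = y0.copy()
    h = h0.copy()
    moving = np.ones(n, dtype=bool)
    pos[:, 0, 0] = x
    pos[:, 0, 1] = y
    for i in range(T):
        u = u_switch[:, i]
        moving = np.where(moving, u < p_stay, u < p_res)
        b1 = np.arctan2(s1y - y, s1x - x)
        b2 = np.arctan2(s2y - y, s2x - x)
        d1 = np.abs(b1 - h) % two_pi
        d1 = np.where(d1 > np.pi, two_pi - d1, d1)
        d2 = np.abs(b2 - h) % two_pi
        d2 = np.where(d2 > np.pi, two_pi - d2, d2)
        target = np.where(d1 <= d2, b1, b2)
        fixate = u_mix[:, i] < fix_w
        mu = np.where(fixate, target, h)
        h_new = mu + vm[:, i]
        st = np.where(moving, step_len[:, i], 0.0)
        xn = x + st * np.cos(h_new)
        yn = y + st * np.sin(h_new)
        r2 = xn * xn + yn * yn
        out = r2 > R * R
        if out.any():
            r = np.sqrt(r2[out])
            f = np.maximum(2.0 * R - r, 0.0) / r
            xn = xn.copy()
            yn = yn.copy()
            xn[out] *= f
            yn[out] *= f
            folded = out & moving
            h_new = np.where(folded, np.arctan2(yn - y, xn - x), h_new)
        h = np.where(moving, h_new, h)
        x, y = xn, yn
        pos[:, i + 1, 0] = x
        pos[:, i + 1, 1] = y


def _step_batch(
    params_list: list[FlyModelParams],
    arena: ArenaConfig,
    draws: list,
    use_kernel: bool = True,
) -> np.ndarray:
    """Advance a batch of flies with identical dt/duration; returns (n, T+1, 2) positions."""
    n = len(params_list)
    dt = params_list[0].dt_s
    n_steps = int(round(params_list[0].duration_s / dt))
    R = arena.platform_radius_mm
    (s1x, s1y), (s2x, s2y) = arena.stripe_centers_mm

    starts = np.stack([d[0] for d in draws])
    inputs = (
        starts[:, 0].copy(),
        starts[:, 1].copy(),
        np.array([d[1] for d in draws]),
        np.stack([d[2] for d in draws]),
        np.stack([d[3] for d in draws]),
        np.stack([d[4] for d in draws]),
        np.stack([d[5] for d in draws]) * dt,
        np.exp(-dt * np.array([p.p_stop_per_s for p in params_list])),
        -np.expm1(-dt * np.array([p.p_go_per_s for p in params_list])),
        np.array([p.fixation_strength for p in params_list]),
    )
    pos = np.empty((n, n_steps + 1, 2))
    if use_kernel:
        x0, y0, h0, usw, umx, vm, stl, pstay, pres, fw = inputs
        _step_kernel(
            x0, y0, h0, usw, umx, vm, stl, pstay, pres, fw,
            R, s1x, s1y, s2x, s2y, pos,
        )
    else:
        _reference_step_batch(inputs, R, s1x, s1y, s2x, s2y, pos)
    return pos


def simulate_flies(
    params_list: list[FlyModelParams],
    seeds=None,
    arena: ArenaConfig | None = None,
    metas: list[FlyMetadata] | None = None,
) -> list[Trajectory]:
    """Simulate a batch of flies sharing ``dt_s`` and ``duration_s``.

    ``seeds`` may be a list of ints/SeedSequences (one per fly) or None to
    use each fly's own ``params.seed``.  Each fly's randomness comes from
    its own stream, so batch composition does not affect the result.
    """
    if not params_list:
        raise UsageError("params_list must be non-empty")
    arena = arena or ArenaConfig()
    for p in params_list:
        p.validate()
        if p.dt_s != params_list[0].dt_s or p.duration_s != params_list[0].duration_s:
            raise UsageError("all flies in a batch must share dt_s and duration_s")
    if seeds is None:
        seeds = [None] * len(params_list)
    n_steps = int(round(params_list[0].duration_s / params_list[0].dt_s))
    draws = [
        _draw_fly(p, n_steps, arena, default_rng(_resolve_seed(p, s)))
        for p, s in zip(params_list, seeds)
    ]
    pos = _step_batch(params_list, arena, draws)
    times = params_list[0].dt_s * np.arange(n_steps + 1)
    out = []
    for k, p in enumerate(params_list):
        meta = metas[k] if metas is not None else FlyMetadata(fly_id=f"sim{k:04d}")
        out.append(
            Trajectory(times_s=times.copy(), x_mm=pos[k, :, 0], y_mm=pos[k, :, 1], meta=meta)
        )
    return out


def simulate_fly(
    params: FlyModelParams,
    seed=None,
    arena: ArenaConfig | None = None,
    meta: FlyMetadata | None = None,
) -> Trajectory:
    """Simulate a single fly; fully reproducible from its seed."""
    return simulate_flies(
        [params], seeds=[seed], arena=arena, metas=[meta] if meta is not None else None
    )[0]


def simulate_random_walk(
    duration_s: float = 300.0,
    dt_s: float = 0.05,
    speed_mm_s: float = 15.0,
    seed=None,
    arena: ArenaConfig | None = None,
) -> Trajectory:
    """Uncorrelated random walk: i.i.d. uniform headings, constant speed, no pauses."""
    if duration_s <= 0 or dt_s <= 0 or speed_mm_s <= 0:
        raise UsageError("duration_s, dt_s and speed_mm_s must be positive")
    return simulate_fly(random_walk_params(duration_s, dt_s, speed_mm_s), seed=seed, arena=arena)


def plan_study(
    strains: list[StrainSpec],
    replicate_labels: tuple[str, ...] | None = None,
) -> list[tuple[FlyModelParams, FlyMetadata]]:
    """Expand a study design into one (params, metadata) pair per fly.

    Each strain is run once per replicate with that replicate's additive
    parameter shift applied; fly ids are ``<strain>_<replicate>_<k>``.
    """
    if not strains:
        raise UsageError("study needs at least one strain")
    plan: list[tuple[FlyModelParams, FlyMetadata]] = []
    for spec in strains:
        shifts = spec.replicate_shifts
        labels = replicate_labels or tuple(f"r{i + 1}" for i in range(len(shifts)))
        if len(labels) != len(shifts):
            raise UsageError("replicate_labels must match replicate_shifts in length")
        for rep_label, shift in zip(labels, shifts):
            params = spec.params.with_shift(shift)
            for k in range(spec.n_flies):
                meta = FlyMetadata(
                    fly_id=f"{spec.name}_{rep_label}_{k:02d}",
                    strain=spec.name,
                    replicate=rep_label,
                )
                plan.append((params, meta))
    return plan


def simulate_study(
    strains: list[StrainSpec],
    seed,
    arena: ArenaConfig | None = None,
    replicate_labels: tuple[str, ...] | None = None,
) -> list[Trajectory]:
    """Simulate a full multi-strain, multi-replicate study, deterministic per seed.

    Per-fly seed streams are spawned from ``seed`` in plan order, so fly k
    can be regenerated alone with ``SeedSequence(seed, spawn_key=(k,))``.
    """
    plan = plan_study(strains, replicate_labels)
    children = SeedSequence(seed).spawn(len(plan))
    return simulate_flies(
        [p for p, _ in plan],
        seeds=children,
        arena=arena,
        metas=[m for _, m in plan],
    )
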