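import warnings

import numpy as np
import pytest

from buridan import (
    ArenaConfig,
    FlyModelParams,
    UsageError,
    compute_all_metrics,
    compute_steps,
    count_walks,
    distance_per_min,
    meander,
    median_speed,
    pause_stats,
    segment_bouts,
    simulate_fly,
    stripe_deviation,
    thigmotaxis,
    turning_angle,
)
from buridan.kinematics import StepSeries
from buridan.metrics import _nearest_stripe_deviation_deg

from .conftest import make_traj, scripted_traj


def make_steps(
    *,
    speeds=None,
    headings=None,
    x_mid=None,
    y_mid=None,
    moving=None,
    dt=1.0,
):
    """Hand-built StepSeries for metric unit tests."""
    n = len(next(a for a in (speeds, headings, x_mid) if a is not None))
    speeds = np.ones(n) * 10.0 if speeds is None else np.asarray(speeds, float)
    headings = np.zeros(n) if headings is None else np.asarray(headings, float)
    x_mid = np.zeros(n) if x_mid is None else np.asarray(x_mid, float)
    y_mid = np.zeros(n) if y_mid is None else np.asarray(y_mid, float)
    moving = np.ones(n, bool) if moving is None else np.asarray(moving, bool)
    dt_arr = np.full(n, dt)
    turn = np.full(n, np.nan)
    both = moving[1:] & moving[:-1]
    dh = np.abs(np.diff(headings))
    dh = np.where(dh > 180.0, 360.0 - dh, dh)
    turn[1:][both] = dh[both]
    return StepSeries(
        t_mid_s=dt * (np.arange(n) + 0.5),
        dt_s=dt_arr,
        step_mm=speeds * dt,
        speed_mm_s=speeds,
        heading_deg=headings % 360.0,
        turn_deg=turn,
        x_mid_mm=x_mid,
        y_mid_mm=y_mid,
        r_mm=np.hypot(x_mid, y_mid),
        moving=moving,
        t_start_s=0.0,
        t_end_s=dt * n,
    )


class TestSpeedAndDistance:
    def test_median_over_moving_steps_only(self):
        steps = make_steps(speeds=[2, 4, 6, 8, 100, 0.1], moving=[1, 1, 1, 1, 1, 0])
        assert median_speed(steps) == pytest.approx(6.0)

    def test_constant_speed_walker(self):
        steps = make_steps(speeds=np.full(30, 10.0))
        assert median_speed(steps) == pytest.approx(10.0)

    def test_no_moving_steps_warns_nan(self):
        steps = make_steps(speeds=[0.1, 0.1], moving=[0, 0])
        with pytest.warns(UserWarning, match="no moving steps"):
            assert np.isnan(median_speed(steps))

    def test_straight_300mm_over_300s_is_60_per_min(self):
        # zig-zag of total path length 300 mm walked over 300 s
        n = 300
        x = np.cumsum(np.concatenate([[0.0], np.tile([1.0, -1.0], n // 2)]))
        traj = make_traj(np.arange(n + 1.0), x, np.zeros(n + 1))
        steps = compute_steps(traj, immobility_speed_mm_s=0.01)
        assert distance_per_min(steps) == pytest.approx(60.0)

    def test_stationary_fly_distance_zero(self):
        steps = compute_steps(make_traj([0, 1, 2], [0, 0, 0], [0, 0, 0]))
        assert distance_per_min(steps) == 0.0

    def test_zero_duration_is_usage_error(self):
        steps = make_steps(speeds=[1.0], dt=1.0)
        steps.t_end_s = steps.t_start_s
        with pytest.raises(UsageError):
            distance_per_min(steps)


class TestAngles:
    def test_straight_path_turns_zero(self):
        steps = make_steps(headings=np.zeros(10))
        assert turning_angle(steps) == pytest.approx(0.0)
        assert meander(steps) == pytest.approx(0.0)

    def test_square_wave_ninety_degrees(self):
        steps = make_steps(headings=[0, 90, 0, 90, 0, 90])
        assert turning_angle(steps) == pytest.approx(90.0)

    def test_meander_is_turn_over_speed(self):
        steps = make_steps(headings=[0, 90, 0, 90], speeds=np.full(4, 10.0))
        assert meander(steps) == pytest.approx(9.0)

    def test_wrapped_difference_matches_brute_force(self):
        rng = np.random.default_rng(11)
        headings = rng.uniform(0, 360, 500)
        steps = make_steps(headings=headings)
        dh = np.abs(np.diff(headings))
        expected = np.median(np.where(dh > 180, 360 - dh, dh))
        assert turning_angle(steps) == pytest.approx(expected, abs=1e-12)

    def test_no_turns_warns_nan(self):
        steps = make_steps(headings=[0.0, 10.0], moving=[1, 0])
        with pytest.warns(UserWarning):
            assert np.isnan(turning_angle(steps))


class TestThigmotaxis:
    def test_circling_at_rim_scores_one(self, arena):
        ang = np.linspace(0, 2 * np.pi, 100)
        steps = make_steps(x_mid=55 * np.cos(ang), y_mid=55 * np.sin(ang))
        seg = segment_bouts(steps)
        assert thigmotaxis(steps, seg, arena, "moving") == pytest.approx(1.0)

    def test_equal_area_boundary_value(self, arena):
        assert arena.thigmotaxis_boundary_radius_mm == pytest.approx(41.37, abs=0.005)

    def test_uniform_positions_give_half(self, arena):
        rng = np.random.default_rng(4)
        n = 100_000
        r = arena.platform_radius_mm * np.sqrt(rng.uniform(size=n))
        ang = rng.uniform(0, 2 * np.pi, n)
        steps = make_steps(x_mid=r * np.cos(ang), y_mid=r * np.sin(ang))
        seg = segment_bouts(steps)
        assert thigmotaxis(steps, seg, arena, "moving") == pytest.approx(0.5, abs=0.02)

    def test_sitting_uses_pause_time(self, arena):
        # 30 immobile steps at the rim (one long pause), 3 moving at centre
        moving = np.array([1, 1, 1] + [0] * 30, bool)
        x = np.concatenate([np.zeros(3), np.full(30, 55.0)])
        steps = make_steps(x_mid=x, moving=moving, speeds=np.where(moving, 10.0, 0.0))
        seg = segment_bouts(steps)
        assert thigmotaxis(steps, seg, arena, "sitting") == pytest.approx(1.0)
        assert thigmotaxis(steps, seg, arena, "moving") == pytest.approx(0.0)

    def test_unknown_state_rejected(self, arena):
        steps = make_steps(speeds=[1.0, 1.0])
        with pytest.raises(UsageError):
            thigmotaxis(steps, segment_bouts(steps), arena, "hovering")


class TestStripeDeviation:
    def test_heading_at_stripe_is_zero(self, arena):
        steps = make_steps(headings=[90.0] * 3)  # stripe bearing 90 deg
        assert stripe_deviation(steps, arena) == pytest.approx(0.0, abs=1e-12)

    def test_perpendicular_heading_is_ninety(self, arena):
        steps = make_steps(headings=[0.0] * 3)
        assert stripe_deviation(steps, arena) == pytest.approx(90.0)

    def test_uniform_headings_at_centre_median_is_45(self, arena):
        headings = np.arange(0.0, 360.0, 0.1)
        dev = _nearest_stripe_deviation_deg(
            headings, np.zeros(headings.size), np.zeros(headings.size), arena
        )
        assert np.median(dev) == pytest.approx(45.0, abs=1e-9)

    def test_values_stay_in_range_off_centre(self, arena):
        rng = np.random.default_rng(5)
        n = 2000
        r = arena.platform_radius_mm * np.sqrt(rng.uniform(size=n))
        ang = rng.uniform(0, 2 * np.pi, n)
        dev = _nearest_stripe_deviation_deg(
            rng.uniform(0, 360, n), r * np.cos(ang), r * np.sin(ang), arena
        )
        assert dev.min() >= 0.0 and dev.max() <= 90.0


class TestCountWalks:
    def test_rim_to_rim_oscillation(self, arena):
        # 7 transits along the stripe axis; each transit is one walk
        targets = [55.0 if i % 2 == 0 else -55.0 for i in range(8)]
        y = np.concatenate(
            [np.linspace(a, b, 40, endpoint=False) for a, b in zip(targets[:-1], targets[1:])]
        )
        steps = make_steps(y_mid=y, x_mid=np.zeros(y.size), speeds=np.full(y.size, 20.0))
        assert count_walks(steps, arena) == 7

    def test_circling_mid_platform_scores_zero(self, arena):
        ang = np.linspace(0, 6 * np.pi, 200)
        r = 0.4 * arena.platform_radius_mm  # inside the zone radius
        steps = make_steps(x_mid=r * np.cos(ang), y_mid=r * np.sin(ang))
        assert count_walks(steps, arena) == 0

    def test_reentering_same_zone_not_counted(self, arena):
        y = np.concatenate([np.linspace(55, 10, 20), np.linspace(10, 55, 20)])
        steps = make_steps(y_mid=y, x_mid=np.zeros(y.size))
        assert count_walks(steps, arena) == 0


class TestPauseStats:
    def test_scripted_pattern(self):
        traj = scripted_traj(
            [("move", 10.0), ("stop", 2.0), ("move", 10.0), ("stop", 3.0), ("move", 10.0)]
        )
        seg = segment_bouts(compute_steps(traj))
        stats = pause_stats(seg)
        assert stats["n_pauses"] == 2
        assert stats["pause_length"] == pytest.approx(2.5)
        assert stats["time_active"] == pytest.approx(30.0)
        assert stats["bout_duration"] == pytest.approx(10.0)

    def test_continuous_walker(self):
        traj = scripted_traj([("move", 25.0)])
        stats = pause_stats(segment_bouts(compute_steps(traj)))
        assert stats["n_pauses"] == 0
        assert stats["time_active"] == pytest.approx(25.0)


class TestComputeAllMetrics:
    def test_stationary_fly_is_degenerate_not_fatal(self, arena):
        traj = make_traj(np.arange(0, 300.5, 0.5), np.full(601, 30.0), np.zeros(601))
        with pytest.warns(UserWarning):
            row = compute_all_metrics(traj, arena)
        assert row.distance_per_min == 0.0
        assert row.time_active == 0.0
        assert np.isnan(row.median_speed)
        assert np.isnan(row.stripe_deviation)
        assert row.n_pauses == 1
        assert row.thigmo_sitting == pytest.approx(0.0)  # r=30 is inside the boundary

    def test_strong_fixator_has_low_stripe_deviation(self, arena):
        fly = simulate_fly(
            FlyModelParams(fixation_strength=0.9, fixation_kappa=10.0), seed=99
        )
        row = compute_all_metrics(fly, arena)
        assert row.stripe_deviation < 20.0
        assert row.n_walks > 5

    @pytest.mark.parametrize("angle", [30.0, 123.4])
    def test_rotation_equivariance(self, arena, default_fly, angle):
        base = compute_all_metrics(default_fly, arena).as_dict()
        th = np.radians(angle)
        xr = default_fly.x_mm * np.cos(th) - default_fly.y_mm * np.sin(th)
        yr = default_fly.x_mm * np.sin(th) + default_fly.y_mm * np.cos(th)
        rotated = make_traj(default_fly.times_s, xr, yr)
        other = compute_all_metrics(rotated, arena.rotated(angle)).as_dict()
        from buridan import METRIC_COLUMNS

        for key in METRIC_COLUMNS:
            if isinstance(base[key], float):
                np.testing.assert_allclose(
                    other[key], base[key], rtol=1e-9, atol=1e-9, err_msg=key
                )
            else:
                assert other[key] == base[key], key

    def test_mirror_invariance(self, arena, default_fly):
        base = compute_all_metrics(default_fly, arena).as_dict()
        mirrored = make_traj(default_fly.times_s, -default_fly.x_mm, default_fly.y_mm)
        other = compute_all_metrics(mirrored, arena).as_dict()
        from buridan import METRIC_COLUMNS

        for key in METRIC_COLUMNS:
            if isinstance(base[key], float):
                np.testing.assert_allclose(
                    other[key], base[key], rtol=1e-9, atol=1e-9, err_msg=key
                )
            else:
                assert other[key] == base[key], key

    def test_metric_invariants_on_simulated_flies(self, arena):
        from numpy.random import SeedSequence

        from buridan import simulate_flies

        params = [FlyModelParams() for _ in range(20)]
        flies = simulate_flies(params, seeds=SeedSequence(2718).spawn(20))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows = [compute_all_metrics(f, arena) for f in flies]
        for row in rows:
            assert 0.0 <= row.thigmo_moving <= 1.0
            assert np.isnan(row.thigmo_sitting) or 0.0 <= row.thigmo_sitting <= 1.0
            assert 0.0 <= row.stripe_deviation <= 90.0
            assert 0.0 <= row.turning_angle <= 180.0
            assert row.n_walks >= 0 and row.n_pauses >= 0
            assert row.time_active <= 300.0 + 0.05
            total_paused = 300.0 - row.time_active
            assert row.n_pauses == 0 or row.pause_length * row.n_pauses <= total_paused * 3
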