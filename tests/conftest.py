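import numpy as np
import pytest

from buridan import ArenaConfig, FlyMetadata, Trajectory


@pytest.fixture(scope="session")
def arena():
    return ArenaConfig()


def make_traj(times, x, y, fly_id="f1", strain="CS_X", replicate="r1"):
    return Trajectory(
        times_s=np.asarray(times, dtype=float),
        x_mm=np.asarray(x, dtype=float),
        y_mm=np.asarray(y, dtype=float),
        meta=FlyMetadata(fly_id=fly_id, strain=strain, replicate=replicate),
    )


def scripted_traj(segments, dt=0.1, speed=10.0, fly_id="scripted"):
    """Trajectory from (state, duration) segments, state in {"move", "stop"}.

    Movement runs back and forth along the x axis at ``speed`` so the path
    stays inside the platform.
    """
    xs = [0.0]
    direction = 1.0
    for state, duration in segments:
        n = int(round(duration / dt))
        for _ in range(n):
            if state == "move":
                nxt = xs[-1] + direction * speed * dt
                if abs(nxt) > 50.0:
                    direction = -direction
                    nxt = xs[-1] + direction * speed * dt
                xs.append(nxt)
            else:
                xs.append(xs[-1])
    t = dt * np.arange(len(xs))
    return make_traj(t, xs, np.zeros(len(xs)), fly_id=fly_id)


@pytest.fixture(scope="session")
def default_fly():
    """One simulated fly with default parameters, shared across tests."""
    from buridan import FlyModelParams, simulate_fly

    return simulate_fly(FlyModelParams(), seed=1234)
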