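import numpy as np
import pytest

from aspursuit import EyeTrace, GenerativeParams, KinematicCondition, generative_velocity


@pytest.fixture
def clean_params():
    """Generative parameters without saccades or measurement noise."""
    return GenerativeParams(saccade_rate=0.0, position_noise_sd=0.0)


@pytest.fixture
def v11c_oblique():
    return KinematicCondition("v11c", v0=11.0, accel=0.0, duration=0.5, direction=45.0)


def velocity_trace(cond, aspv_true, params, noise_sd=0.0, seed=0, t_start=-0.5):
    """Build an EyeTrace with velocity set directly from the generative model.

    Bypasses the position round trip so tests control the velocity noise
    exactly (white Gaussian of the given sd, deg/s along the motion).
    """
    fs = 1000.0
    n = int(round((cond.duration - t_start) * fs)) + 1
    t = t_start + np.arange(n) / fs
    v = generative_velocity(t, cond, aspv_true, params)
    if noise_sd > 0:
        v = v + np.random.default_rng(seed).normal(0.0, noise_sd, n)
    th = np.radians(cond.direction)
    return EyeTrace(
        time=t,
        x=np.zeros(n),
        y=np.zeros(n),
        vx=v * np.cos(th),
        vy=v * np.sin(th),
        meta={"direction": cond.direction, "aspv_true": aspv_true},
    )
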