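import numpy as np
import pytest

from radarhrv.synthesis import (
    NoiseConfig,
    RadarConfig,
    Scene,
    VitalSignParams,
    compose_displacement,
    generate_ibi_sequence,
    synthesize_cube,
)

FRAME_RATE = 20.0


@pytest.fixture
def params():
    return VitalSignParams()


@pytest.fixture
def time_grid():
    return np.arange(int(60.0 * FRAME_RATE)) / FRAME_RATE


def make_trace(seed, duration_s=60.0, snr_db=None, jitter_sd=0.03, params=None):
    """Standard synthetic chest-wall scenario used across the suite."""
    p = params or VitalSignParams(ibi_jitter_sd_s=jitter_sd)
    rng = np.random.default_rng(seed)
    t = np.arange(int(duration_s * FRAME_RATE)) / FRAME_RATE
    n_beats = int(np.ceil(duration_s / p.mean_ibi_s)) + 2
    ibis = generate_ibi_sequence(p.mean_ibi_s, jitter_sd, n_beats, rng)
    noise = NoiseConfig(snr_db=snr_db) if snr_db is not None else NoiseConfig()
    return compose_displacement(p, ibis, noise, t, rng)


@pytest.fixture
def small_cube_scene():
    """Small radar cube with one vibrating target and two static clutter points."""
    config = RadarConfig(
        n_samples=64,
        n_chirps=4,
        frame_rate=FRAME_RATE,
        n_beam=64,
        rx_positions=tuple((float(i), 0.0) for i in range(4))
        + tuple((0.0, float(j)) for j in range(1, 4)),
    )
    target = (0.3, 1.5, -0.2)
    scene = Scene(
        target_position=target,
        clutter=(((-0.5, 2.2, 0.1), 2.0), ((0.2, 0.8, 0.0), 1.5)),
        snr_db=20.0,
    )
    trace = make_trace(3, duration_s=10.0)
    cube = synthesize_cube(config, scene, trace, seed=3)
    return cube, target
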