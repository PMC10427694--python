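import numpy as np
import pytest

from reachkin.kinematics import Trial
from reachkin.mjt import MJTParams, sample_mjt
from reachkin.simulate import NoiseModel, SessionConfig, generate_cohort

#: all noise switched off: trials are exact sampled minimum-jerk movements
SILENT_NOISE = NoiseModel(
    duration_intercept=0.5,
    duration_slope=0.01,
    duration_jitter_sd=0.0,
    trajectory_noise_sd=0.0,
    endpoint_sd=0.0,
    onset_delay_mean=0.3,
    onset_delay_sd=0.0,
)


def mjt_trial(distance=50.0, d=1.0, fs=60.0, window=3.0, delay=0.0, **meta) -> Trial:
    """A noise-free trial: optional flat lead-in, exact MJT, hold at target."""
    n = int(round(window * fs))
    t = np.arange(n) / fs
    params = MJTParams(x0=0.0, xf=distance, d=d, t_s=delay)
    x = np.where(
        t < delay, 0.0, np.where(t > delay + d, distance, 0.0)
    )
    inside = (t >= delay) & (t <= delay + d)
    from reachkin.mjt import mjt_position

    x[inside] = np.asarray(mjt_position(params, t[inside]))
    defaults = dict(
        subject_id="S01", modality="manipulandum", block=1, trial_id="T01", target_distance=distance
    )
    defaults.update(meta)
    return Trial(times=t, positions=x, **defaults)


@pytest.fixture(scope="session")
def two_modality_cohort():
    """Default-noise 4-subject cohort, both modalities, fixed seed."""
    config = SessionConfig(
        n_subjects=4, modalities=("manipulandum", "sonomyography"), seed=20231
    )
    trials, truth = generate_cohort(config)
    return config, trials, truth
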