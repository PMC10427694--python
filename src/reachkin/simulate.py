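"""Synthetic cursor-trajectory cohorts with known ground truth.

The generator emulates the structure of a two-modality target-acquisition
study: each trial is a minimum-jerk movement from the start edge to a
scattered endpoint near the target center, preceded by a reaction-delay
hold and followed by a hold at the endpoint until the trial window closes.
Movement duration grows linearly with distance (with per-trial jitter),
endpoint scatter is truncated at the target half-width so subjects always
settle inside the target band, and smoothed zero-mean noise — larger for
the sonomyography-like modality than for the manipulandum-like one — is
added to the moving segment only, tapered to zero at its ends so the hold
phases stay clean.

Every stochastic choice is recorded in a ground-truth table so parameter-
recovery tests can compare pipeline estimates against what was simulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .kinematics import Trial
from .mjt import MJTParams, mjt_position_clamped

__all__ = [
    "SessionConfig",
    "NoiseModel",
    "MANIPULANDUM_NOISE",
    "SONOMYOGRAPHY_NOISE",
    "DEFAULT_NOISE_MODELS",
    "generate_trial",
    "generate_cohort",
    "trials_to_frame",
]

#: The study's seven target distances, % of workspace width.
DEFAULT_DISTANCES = (12.5, 25.0, 37.5, 50.0, 62.5, 75.0, 87.5)

#: 5 cm target diameter on a 27-inch (68.58 cm) wide workspace -> 3.6 % half-width.
DEFAULT_TARGET_HALFWIDTH = 3.6

MIN_DURATION = 0.2  # s, floor on simulated movement durations


@dataclass(frozen=True)
class SessionConfig:
    """Experimental design of one simulated session."""

    n_subjects: int = 1
    modalities: tuple[str, ...] = ("manipulandum",)
    target_distances: tuple[float, ...] = DEFAULT_DISTANCES
    n_blocks: int = 5
    fs: float = 60.0
    trial_window: float = 10.0
    target_halfwidth: float = DEFAULT_TARGET_HALFWIDTH
    seed: int | None = None

    def __post_init__(self) -> None:
        if not all(0 < d <= 100 for d in self.target_distances):
            raise ValueError("target distances must lie in (0, 100]")
        if self.n_blocks < 1 or self.fs <= 0 or self.trial_window <= 0:
            raise ValueError("invalid session design")

    @property
    def trials_per_subject_per_modality(self) -> int:
        return len(self.target_distances) * self.n_blocks


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic structure of one control modality.

    Durations follow ``intercept + slope * distance + N(0, jitter)``
    (seconds); endpoints scatter around the target center with a normal
    truncated at the target half-width; trajectory noise is moving-average
    smoothed white noise of the given standard deviation (% workspace
    width), applied to the moving segment.
    """

    duration_intercept: float = 0.5
    duration_slope: float = 0.01  # s per % distance
    duration_jitter_sd: float = 0.05
    trajectory_noise_sd: float = 1.5
    noise_smoothing_window: int = 9
    endpoint_sd: float = 0.4
    onset_delay_mean: float = 0.3
    onset_delay_sd: float = 0.05

    def __post_init__(self) -> None:
        sds = (self.duration_jitter_sd, self.trajectory_noise_sd, self.endpoint_sd, self.onset_delay_sd)
        if any(s < 0 for s in sds) or self.duration_slope < 0:
            raise ValueError("noise scales must be nonnegative")
        if self.noise_smoothing_window < 1:
            raise ValueError("smoothing window must be >= 1 sample")


# Defaults anchored to the study's reported regularities: trajectory SDs of
# roughly 0.5-2.4 % for the manipulandum and 4.3-5.8 % for sonomyography,
# time to target growing ~0.01 s per % distance in both, longer times but a
# tighter spread for the manipulandum.  The manipulandum's noise is smoothed
# over ~0.5 s (arm movements wander slowly and stay nearly monotone) while
# sonomyography noise is smoothed over ~0.15 s (signal-derived control
# jitters on a faster timescale).
MANIPULANDUM_NOISE = NoiseModel(
    duration_intercept=0.55,
    duration_slope=0.01,
    duration_jitter_sd=0.06,
    trajectory_noise_sd=1.5,
    noise_smoothing_window=31,
    endpoint_sd=0.4,
    onset_delay_mean=0.3,
    onset_delay_sd=0.05,
)
SONOMYOGRAPHY_NOISE = NoiseModel(
    duration_intercept=0.40,
    duration_slope=0.01,
    duration_jitter_sd=0.18,
    trajectory_noise_sd=5.0,
    noise_smoothing_window=9,
    endpoint_sd=1.2,
    onset_delay_mean=0.3,
    onset_delay_sd=0.10,
)
DEFAULT_NOISE_MODELS = {
    "manipulandum": MANIPULANDUM_NOISE,
    "sonomyography": SONOMYOGRAPHY_NOISE,
}


def _truncated_normal(rng: np.random.Generator, sd: float, bound: float) -> float:
    if sd == 0.0:
        return 0.0
    a, b = -bound / sd, bound / sd
    return float(sps.truncnorm.rvs(a, b, scale=sd, random_state=rng))


def _smoothed_noise(rng: np.random.Generator, n: int, sd: float, window: int) -> np.ndarray:
    """Moving-average-filtered white noise with post-filter SD ~ sd, tapered to 0 at the ends."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    window = min(window, n)  # convolve("same") returns max(len, window) otherwise
    white = rng.normal(0.0, sd * np.sqrt(window), size=n)
    if window > 1:
        kernel = np.ones(window)
        noise = np.convolve(white, kernel, mode="same") / np.convolve(
            np.ones(n), kernel, mode="same"
        )
    else:
        noise = white
    ramp = min(max(window, 3), max(n // 4, 1))
    taper = np.ones(n)
    edge = np.sin(0.5 * np.pi * np.arange(1, ramp + 1) / ramp) ** 2
    taper[:ramp] = edge
    taper[-ramp:] = np.minimum(taper[-ramp:], edge[::-1])
    return noise * taper


def generate_trial(
    distance: float,
    noise: NoiseModel,
    config: SessionConfig,
    rng: np.random.Generator,
    subject_id: str = "S01",
    modality: str = "manipulandum",
    block: int = 1,
    trial_id: str = "T01",
) -> tuple[Trial, dict]:
    """Simulate one trial; returns the Trial and its ground-truth record."""
    d = noise.duration_intercept + noise.duration_slope * distance
    if noise.duration_jitter_sd > 0:
        d += rng.normal(0.0, noise.duration_jitter_sd)
    if d < MIN_DURATION:
        d = MIN_DURATION
    xf = distance + _truncated_normal(rng, noise.endpoint_sd, config.target_halfwidth)
    delay = noise.onset_delay_mean
    if noise.onset_delay_sd > 0:
        delay += rng.normal(0.0, noise.onset_delay_sd)
    delay = max(delay, 0.0)

    n = int(round(config.trial_window * config.fs))
    t = np.arange(n) / config.fs
    x = np.asarray(mjt_position_clamped(MJTParams(x0=0.0, xf=xf, d=d, t_s=delay), t))

    moving = (t >= delay) & (t <= delay + d)
    x[moving] += _smoothed_noise(
        rng, int(moving.sum()), noise.trajectory_noise_sd, noise.noise_smoothing_window
    )

    trial = Trial(
        subject_id=subject_id,
        modality=modality,
        block=block,
        trial_id=trial_id,
        target_distance=distance,
        times=t,
        positions=x,
    )
    truth = dict(
        subject_id=subject_id,
        modality=modality,
        block=block,
        trial_id=trial_id,
        target_distance=distance,
        true_duration=float(d),
        true_endpoint=float(xf),
        true_onset_delay=float(delay),
        true_peak_velocity=1.875 * abs(xf) / d,
    )
    return trial, truth


def generate_cohort(
    config: SessionConfig,
    noise_models: dict[str, NoiseModel] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[Trial], pd.DataFrame]:
    """Simulate a full cohort: subjects x modalities x blocks x distances.

    Within each block the target order is randomized.  All randomness
    derives from one generator (``config.seed`` if ``rng`` not given), so
    identical seeds give identical cohorts.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if noise_models is None:
        noise_models = {
            m: DEFAULT_NOISE_MODELS.get(m, MANIPULANDUM_NOISE) for m in config.modalities
        }
    trials: list[Trial] = []
    truths: list[dict] = []
    for s in range(config.n_subjects):
        subject_id = f"S{s + 1:02d}"
        for modality in config.modalities:
            noise = noise_models[modality]
            for block in range(1, config.n_blocks + 1):
                order = rng.permutation(len(config.target_distances))
                for j, k in enumerate(order):
                    trial, truth = generate_trial(
                        config.target_distances[k],
                        noise,
                        config,
                        rng,
                        subject_id=subject_id,
                        modality=modality,
                        block=block,
                        trial_id=f"{subject_id}-{modality[:4]}-b{block}-t{j + 1}",
                    )
                    trials.append(trial)
                    truths.append(truth)
    return trials, pd.DataFrame(truths)


def trials_to_frame(trials: list[Trial]) -> pd.DataFrame:
    """Tidy long table, one row per sample (the on-disk trial schema)."""
    frames = []
    for tr in trials:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": tr.subject_id,
                    "modality": tr.modality,
                    "block": tr.block,
                    "trial_id": tr.trial_id,
                    "target_distance_pct": tr.target_distance,
                    "t_s": tr.times,
                    "position_pct": tr.positions,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
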