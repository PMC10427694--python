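"""Per-trial kinematic metrics for point-to-point cursor trajectories.

A trial is a sampled 1-D cursor trace, normalized so the start edge is 0 %
of workspace width and the movement is positive-going.  The pipeline
segments each trial (movement onset = first sustained positive velocity;
movement end = first crossing of 95 % of the target distance) and derives
the study's metrics: time to target, peak velocity and its latency, RMS
position error against a minimum-jerk reference, and path efficiency.

Position error needs a per-condition reference trajectory: for each
(modality, target distance) cell the minimum-jerk reference is built with
duration equal to that cell's mean time to target, so the two-pass driver
:func:`compute_metrics` first segments every trial and then scores each
against its condition's reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .mjt import MJTParams, ReferenceTrace, sample_mjt

__all__ = [
    "Trial",
    "TrialMetrics",
    "ConditionSummary",
    "OnsetNotFoundError",
    "UndefinedMetricError",
    "estimate_velocity",
    "detect_onset",
    "detect_end",
    "time_to_target",
    "peak_velocity_and_time",
    "position_error",
    "path_efficiency",
    "completion_curve",
    "normalize_to_smallest_distance",
    "analyze_trial",
    "compute_metrics",
    "condition_reference",
    "mean_position_trace",
    "summarize_conditions",
    "METRIC_COLUMNS",
]


class OnsetNotFoundError(ValueError):
    """The velocity never exceeded the onset threshold."""


class UndefinedMetricError(ValueError):
    """A metric was requested for a trial on which it is undefined."""


@dataclass(frozen=True)
class Trial:
    """One recorded trajectory with its design metadata.

    positions are in % workspace width, direction-normalized (0 = start
    edge, movement positive-going); times in seconds, nominally uniform.
    """

    subject_id: str
    modality: str
    block: int
    trial_id: str
    target_distance: float
    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.positions, dtype=float)
        if t.ndim != 1 or t.shape != x.shape or t.size < 2:
            raise ValueError("a trial needs matching 1-D times/positions with >= 2 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError(f"trial {self.trial_id}: times must be strictly increasing")
        if not np.all(np.isfinite(x)):
            raise ValueError(f"trial {self.trial_id}: non-finite positions")
        if not 0 < self.target_distance <= 100:
            raise ValueError(f"target distance must be in (0, 100], got {self.target_distance}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", x)

    @property
    def fs(self) -> float:
        """Nominal sampling rate (Hz), from the median sample interval."""
        return 1.0 / float(np.median(np.diff(self.times)))


@dataclass(frozen=True)
class TrialMetrics:
    subject_id: str
    modality: str
    block: int
    trial_id: str
    target_distance: float
    completed: bool
    onset_time: float | None = None
    end_time: float | None = None
    time_to_target: float | None = None
    peak_velocity: float | None = None
    time_to_peak: float | None = None
    path_efficiency: float | None = None
    position_error: float | None = None


METRIC_COLUMNS = [
    "subject_id",
    "modality",
    "block",
    "trial_id",
    "target_distance",
    "completed",
    "onset_time",
    "end_time",
    "time_to_target",
    "peak_velocity",
    "time_to_peak",
    "path_efficiency",
    "position_error",
]


@dataclass(frozen=True)
class ConditionSummary:
    """Per-(modality, distance) aggregates over completed trials."""

    modality: str
    target_distance: float
    n_trials: int
    n_completed: int
    mean_time_to_target: float
    means: dict
    sds: dict
    mean_trace: ReferenceTrace | None = None


# --------------------------------------------------------------------------
# segmentation


def estimate_velocity(trial: Trial, smooth_window: int = 1) -> np.ndarray:
    """Backward-difference velocity (%/s), optionally smoothed.

    ``v[0] = 0`` and ``v[i] = (x[i] - x[i-1]) / dt[i]`` with per-interval
    dt, followed by a centered moving average of odd width
    ``smooth_window`` (1 disables smoothing; edges use partial windows).
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be an odd positive sample count")
    dt = np.diff(trial.times)
    v = np.empty_like(trial.positions)
    v[0] = 0.0
    v[1:] = np.diff(trial.positions) / dt
    if smooth_window > 1:
        kernel = np.ones(smooth_window)
        v = np.convolve(v, kernel, mode="same") / np.convolve(
            np.ones_like(v), kernel, mode="same"
        )
    return v


def detect_onset(
    trial: Trial,
    velocity: np.ndarray,
    eps: float = 0.0,
    debounce: int = 1,
) -> int:
    """Index of movement onset: first run of ``debounce`` samples with v > eps.

    With the defaults (eps=0, debounce=1) this is literally the first
    sample at which movement velocity is positive.  Raises
    :class:`OnsetNotFoundError` if no such run exists.
    """
    if eps < 0 or debounce < 1:
        raise ValueError("eps must be >= 0 and debounce >= 1")
    above = velocity > eps
    run = 0
    for i, ok in enumerate(above):
        run = run + 1 if ok else 0
        if run >= debounce:
            return i - debounce + 1
    raise OnsetNotFoundError(f"trial {trial.trial_id}: velocity never exceeded {eps} %/s")


def detect_end(trial: Trial, onset: int) -> int | None:
    """First index at/after onset with position strictly above 95 % of target.

    Returns ``None`` if the threshold is never crossed (incomplete trial).
    """
    threshold = 0.95 * trial.target_distance
    idx = np.nonzero(trial.positions[onset:] > threshold)[0]
    return int(onset + idx[0]) if idx.size else None


def time_to_target(onset_time: float, end_time: float) -> float:
    if end_time < onset_time:
        raise UndefinedMetricError("end time precedes onset time")
    return end_time - onset_time


def peak_velocity_and_time(
    velocity: np.ndarray, times: np.ndarray, onset: int, end: int
) -> tuple[float, float]:
    """Max velocity over [onset, end] and its latency from onset; earliest tie wins."""
    if end < onset:
        raise UndefinedMetricError("empty movement segment")
    seg = velocity[onset : end + 1]
    k = int(np.argmax(seg))  # argmax takes the first maximum, the required tie-break
    return float(seg[k]), float(times[onset + k] - times[onset])


# --------------------------------------------------------------------------
# trajectory-shape metrics


def position_error(
    times: np.ndarray,
    positions: np.ndarray,
    reference: ReferenceTrace,
) -> float:
    """RMS error (%) between an onset-based trace and a minimum-jerk reference.

    ``times`` must be re-based so onset is 0, matching the reference grid.
    The observed trace is linearly interpolated onto the reference's sample
    times; beyond its last sample it is held at its final value, so a trial
    that finished early is scored as if it stayed at its endpoint.
    """
    obs = np.interp(reference.times, times, positions)
    return float(np.sqrt(np.mean((obs - reference.positions) ** 2)))


def path_efficiency(
    trial: Trial, onset: int, end: int | None = None, mode: str = "ideal-over-actual"
) -> float:
    """Path efficiency (%) of the movement.

    ``ideal`` is the straight-line distance from the segment's start
    position to the target center; ``actual`` is the total distance the
    cursor traversed to settle, ``sum |x[i+1] - x[i]|`` from onset to
    ``end`` (default: the last sample, i.e. through settlement — the
    threshold-crossing index would stop mid-deceleration and overstate
    efficiency).  The default ``ideal-over-actual`` orientation makes a
    trial that settles at the target's near edge (actual < ideal) exceed
    100 %; the ``actual-over-ideal`` reciprocal is also available.
    """
    if end is None:
        end = len(trial.positions) - 1
    seg = trial.positions[onset : end + 1]
    actual = float(np.sum(np.abs(np.diff(seg))))
    ideal = abs(trial.target_distance - float(seg[0]))
    if actual == 0.0:
        raise UndefinedMetricError("zero traversed path length")
    if mode == "ideal-over-actual":
        return 100.0 * ideal / actual
    if mode == "actual-over-ideal":
        return 100.0 * actual / ideal
    raise ValueError(f"unknown path-efficiency mode {mode!r}")


def completion_curve(metrics: pd.DataFrame, time_grid: Sequence[float]) -> np.ndarray:
    """Fraction of trials completed by each time on the grid.

    Counts trials with ``completed`` true and ``time_to_target <= t``,
    over ALL trials (incomplete ones stay in the denominator), so the
    curve is nondecreasing and bounded by the overall completion rate.
    """
    if len(metrics) == 0:
        raise ValueError("no trials")
    done = metrics.loc[metrics["completed"].astype(bool), "time_to_target"].to_numpy(float)
    grid = np.asarray(time_grid, dtype=float)
    return (done[None, :] <= grid[:, None]).sum(axis=1) / len(metrics)


def normalize_to_smallest_distance(
    metrics: pd.DataFrame, columns: Sequence[str] = ("peak_velocity", "time_to_target")
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize metrics within each modality by the smallest-distance means.

    Each completed trial's value in ``columns`` is divided by the mean of
    that column over the modality's smallest-distance completed trials
    (so smallest-distance trials average 1.0 by construction).  Returns
    the normalized per-trial table and a per-(modality, distance) ellipse
    summary: center = mean normalized pair, axes = SDs.
    """
    done = metrics.loc[metrics["completed"].astype(bool)].copy()
    if done.empty:
        raise UndefinedMetricError("no completed trials to normalize")
    out = []
    for modality, grp in done.groupby("modality", sort=True):
        d_min = grp["target_distance"].min()
        base = grp.loc[grp["target_distance"] == d_min, list(columns)].mean()
        if base.isna().any() or (base == 0).any():
            raise UndefinedMetricError(
                f"modality {modality!r}: smallest-distance means unavailable"
            )
        g = grp.copy()
        for c in columns:
            g[f"norm_{c}"] = g[c] / base[c]
        out.append(g)
    normalized = pd.concat(out, ignore_index=True)
    ncols = [f"norm_{c}" for c in columns]
    ellipses = (
        normalized.groupby(["modality", "target_distance"], sort=True)[ncols]
        .agg(["mean", "std"])
        .reset_index()
    )
    ellipses.columns = [
        "_".join(c).rstrip("_") if isinstance(c, tuple) else c for c in ellipses.columns
    ]
    return normalized, ellipses


# --------------------------------------------------------------------------
# drivers


def analyze_trial(
    trial: Trial,
    smooth_window: int = 1,
    eps: float = 0.0,
    debounce: int = 1,
    path_efficiency_mode: str = "ideal-over-actual",
) -> TrialMetrics:
    """Segment one trial and compute every metric except position error."""
    meta = dict(
        subject_id=trial.subject_id,
        modality=trial.modality,
        block=trial.block,
        trial_id=trial.trial_id,
        target_distance=trial.target_distance,
    )
    velocity = estimate_velocity(trial, smooth_window)
    try:
        onset = detect_onset(trial, velocity, eps=eps, debounce=debounce)
    except OnsetNotFoundError:
        return TrialMetrics(completed=False, **meta)
    end = detect_end(trial, onset)
    if end is None:
        return TrialMetrics(completed=False, onset_time=float(trial.times[onset]), **meta)
    pv, tp = peak_velocity_and_time(velocity, trial.times, onset, end)
    return TrialMetrics(
        completed=True,
        onset_time=float(trial.times[onset]),
        end_time=float(trial.times[end]),
        time_to_target=time_to_target(float(trial.times[onset]), float(trial.times[end])),
        peak_velocity=pv,
        time_to_peak=tp,
        path_efficiency=path_efficiency(trial, onset, mode=path_efficiency_mode),
        **meta,
    )


def condition_reference(
    target_distance: float, mean_time_to_target: float, fs: float
) -> ReferenceTrace:
    """Minimum-jerk reference for a condition: 0 -> target center over the mean time."""
    return sample_mjt(MJTParams(x0=0.0, xf=target_distance, d=mean_time_to_target), fs)


def compute_metrics(
    trials: Iterable[Trial],
    smooth_window: int = 1,
    eps: float = 0.0,
    debounce: int = 1,
    path_efficiency_mode: str = "ideal-over-actual",
) -> pd.DataFrame:
    """Full two-pass metric table for a collection of trials.

    Pass 1 segments every trial; pass 2 builds each (modality, distance)
    condition's minimum-jerk reference from the mean time to target of its
    completed trials and scores each completed trial's RMS position error
    against it.  Incomplete trials keep NaN metrics but stay in the table
    for completion counting.
    """
    trials = list(trials)
    if not trials:
        return pd.DataFrame(columns=METRIC_COLUMNS)
    per_trial = [
        analyze_trial(
            t,
            smooth_window=smooth_window,
            eps=eps,
            debounce=debounce,
            path_efficiency_mode=path_efficiency_mode,
        )
        for t in trials
    ]
    df = pd.DataFrame([m.__dict__ for m in per_trial])[METRIC_COLUMNS]

    # condition references from mean time to target of completed trials
    done = df[df["completed"]]
    mean_ttt = done.groupby(["modality", "target_distance"])["time_to_target"].mean()
    refs: dict[tuple, ReferenceTrace] = {}
    for (modality, dist), d_mean in mean_ttt.items():
        fs = np.median([t.fs for t in trials if t.modality == modality])
        refs[(modality, dist)] = condition_reference(dist, float(d_mean), float(fs))

    errors = np.full(len(df), np.nan)
    for i, (trial, m) in enumerate(zip(trials, per_trial)):
        if not m.completed:
            continue
        ref = refs[(trial.modality, trial.target_distance)]
        onset = int(np.searchsorted(trial.times, m.onset_time))
        errors[i] = position_error(
            trial.times[onset:] - trial.times[onset], trial.positions[onset:], ref
        )
    df["position_error"] = errors
    return df


def mean_position_trace(
    trials: Sequence[Trial],
    metrics: pd.DataFrame,
    fs: float,
    duration: float,
) -> ReferenceTrace:
    """Onset-aligned mean trajectory of completed trials on a uniform grid.

    Trials are re-based at their detected onset and linearly interpolated
    onto a grid at ``fs`` spanning ``[0, duration]`` (trials that end early
    are held at their final value); velocities are the grid-wise gradient
    of the mean position.
    """
    grid = np.arange(int(round(duration * fs)) + 1) / fs
    key = lambda subject_id, block, trial_id: (subject_id, block, trial_id)
    by_id = {key(m.subject_id, m.block, m.trial_id): m for m in metrics.itertuples()}
    stack = []
    for trial in trials:
        m = by_id.get(key(trial.subject_id, trial.block, trial.trial_id))
        if m is None or not m.completed:
            continue
        onset = int(np.searchsorted(trial.times, m.onset_time))
        stack.append(
            np.interp(grid, trial.times[onset:] - trial.times[onset], trial.positions[onset:])
        )
    if not stack:
        raise UndefinedMetricError("no completed trials to average")
    mean_x = np.mean(stack, axis=0)
    return ReferenceTrace(grid, mean_x, np.gradient(mean_x, grid))


def summarize_conditions(
    trials: Sequence[Trial], metrics: pd.DataFrame, with_traces: bool = True
) -> list[ConditionSummary]:
    """Per-(modality, distance) means/SDs and optional mean position traces."""
    fields = ["time_to_target", "peak_velocity", "time_to_peak", "path_efficiency", "position_error"]
    out = []
    for (modality, dist), grp in metrics.groupby(["modality", "target_distance"], sort=True):
        done = grp[grp["completed"]]
        if done.empty:
            out.append(
                ConditionSummary(modality, float(dist), len(grp), 0, math.nan, {}, {})
            )
            continue
        mean_ttt = float(done["time_to_target"].mean())
        trace = None
        if with_traces:
            sub = [t for t in trials if t.modality == modality and t.target_distance == dist]
            fs = float(np.median([t.fs for t in sub]))
            trace = mean_position_trace(sub, grp, fs, mean_ttt)
        out.append(
            ConditionSummary(
                modality=modality,
                target_distance=float(dist),
                n_trials=len(grp),
                n_completed=len(done),
                mean_time_to_target=mean_ttt,
                means={f: float(done[f].mean()) for f in fields},
                sds={f: float(done[f].std(ddof=1)) if len(done) > 1 else 0.0 for f in fields},
                mean_trace=trace,
            )
        )
    return out
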