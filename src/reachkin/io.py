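"""Readers, writers and the end-to-end analysis driver.

On-disk formats are plain text: trials travel as tidy long CSV (one row
per sample), per-trial metrics and condition summaries as wide CSV, and
the statistical report as schema-versioned JSON.  Positions are stored
exclusively in percent of workspace width; :func:`pct_to_length` converts
to physical units given the workspace width (e.g. a 27-inch-wide screen).

Outputs are deterministic for a fixed seed and configuration: column
order is fixed, floats are written at fixed precision, and the only
non-reproducible field (a timestamp) lives in the run manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .kinematics import (
    METRIC_COLUMNS,
    Trial,
    completion_curve,
    compute_metrics,
    summarize_conditions,
)
from .simulate import SessionConfig, generate_cohort, trials_to_frame
from .stats import factorial_samples, scaling_regression, two_stage_analysis, variance_f_test

logger = logging.getLogger("reachkin")

REPORT_SCHEMA_VERSION = 1
FLOAT_FORMAT = "%.12g"

TRIAL_COLUMNS = [
    "subject_id",
    "modality",
    "block",
    "trial_id",
    "target_distance_pct",
    "t_s",
    "position_pct",
]

RESPONSE_VARIABLES = ["peak_velocity", "time_to_target", "position_error", "time_to_peak"]


class SchemaError(ValueError):
    """The input file does not match the expected column schema."""


def pct_to_length(pct: float, workspace_width: float = 27.0) -> float:
    """Convert % of workspace width to physical length (units of the width)."""
    return pct / 100.0 * workspace_width


# --------------------------------------------------------------------------
# trials


def read_trials(path: str | Path, mirror: str | bool = "auto") -> list[Trial]:
    """Load trials from tidy long CSV, direction-normalizing where needed.

    Trials already in the canonical convention (start near 0, movement
    positive-going) load verbatim.  A trial whose dominant excursion is
    negative-going (left-handed / mirrored conventions) is re-based to its
    first sample and sign-flipped so it starts at 0 and moves positive.
    ``mirror`` may be ``"auto"`` (flip negative-going trials), ``True``
    (always flip) or ``False`` (never).  Trials with non-monotone time
    are rejected with a log entry; the rest load normally.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    trials: list[Trial] = []
    n_rejected = 0
    keys = ["subject_id", "modality", "block", "trial_id"]
    for (subject, modality, block, trial_id), grp in df.groupby(keys, sort=False):
        t = grp["t_s"].to_numpy(dtype=float)
        x = grp["position_pct"].to_numpy(dtype=float)
        rel = x - x[0]
        flip = mirror is True or (mirror == "auto" and -rel.min() > rel.max())
        disp = -rel if flip else x
        try:
            trials.append(
                Trial(
                    subject_id=str(subject),
                    modality=str(modality),
                    block=int(block),
                    trial_id=str(trial_id),
                    target_distance=float(grp["target_distance_pct"].iloc[0]),
                    times=t,
                    positions=disp,
                )
            )
        except ValueError as exc:
            n_rejected += 1
            logger.warning("rejected trial %s: %s", trial_id, exc)
    logger.info("loaded %d trials (%d rejected)", len(trials), n_rejected)
    return trials


def write_trials(trials: list[Trial], path: str | Path) -> None:
    trials_to_frame(trials).to_csv(path, index=False, float_format=FLOAT_FORMAT)


# --------------------------------------------------------------------------
# metrics


def write_metrics(metrics: pd.DataFrame, path: str | Path) -> None:
    metrics[METRIC_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_metrics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df


# --------------------------------------------------------------------------
# stats report


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _as_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def build_stats_report(metrics: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Full statistical report over a per-trial metrics table.

    Runs the two-stage rank analysis for each response variable, per-
    modality scaling regressions of peak velocity and time to target on
    distance, and per-distance two-sided variance-ratio F tests across
    modalities for peak velocity, time to target and path efficiency.
    """
    done = metrics[metrics["completed"].astype(bool)]
    if done["modality"].nunique() >= 2:
        samples = {v: factorial_samples(metrics, v) for v in RESPONSE_VARIABLES}
        staged = two_stage_analysis(samples, alpha=alpha)
    else:  # single modality: the two-factor design is undefined
        staged = {}
    regressions: dict[str, dict] = {}
    for modality, grp in done.groupby("modality", sort=True):
        regressions[str(modality)] = {
            v: scaling_regression(grp["target_distance"].to_numpy(), grp[v].to_numpy())
            for v in ("peak_velocity", "time_to_target", "position_error")
            if grp[v].notna().any()
        }

    modalities = sorted(done["modality"].unique())
    variance_tests: dict[str, dict] = {}
    if len(modalities) == 2:
        m_a, m_b = modalities
        for v in ("peak_velocity", "time_to_target", "path_efficiency"):
            per_distance = {}
            for dist, grp in done.groupby("target_distance", sort=True):
                a = grp.loc[grp["modality"] == m_a, v].dropna().to_numpy()
                b = grp.loc[grp["modality"] == m_b, v].dropna().to_numpy()
                if a.size >= 2 and b.size >= 2:
                    per_distance[str(dist)] = variance_f_test(b, a)  # b vs a: second modality numerator
            variance_tests[v] = {"numerator": m_b, "denominator": m_a, "per_distance": per_distance}

    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "alpha": alpha,
        "n_trials": int(len(metrics)),
        "n_completed": int(metrics["completed"].astype(bool).sum()),
        "two_stage": _as_jsonable(staged),
        "regressions": _as_jsonable(regressions),
        "variance_tests": _as_jsonable(variance_tests),
    }


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


# --------------------------------------------------------------------------
# manifest + end-to-end driver


@dataclass(frozen=True)
class RunManifest:
    tool_version: str
    run_id: str  # digest of config + seed: identical runs share an id
    seed: int | None
    config: dict
    input_digests: dict
    n_subjects: int
    n_trials: int
    n_incomplete: int
    timestamp: str

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_report(
    out_dir: str | Path,
    trials_path: str | Path | None = None,
    config: SessionConfig | None = None,
    alpha: float = 0.05,
    smooth_window: int = 5,
    completion_grid_max: float = 10.0,
) -> dict:
    """Run the whole pipeline and write the analysis bundle to ``out_dir``.

    Either loads measured trials from ``trials_path`` or simulates a
    cohort from ``config``.  Emits trials (if simulated), per-trial
    metrics, condition summaries, completion curves, the stats report and
    a run manifest; returns the bundle in memory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    input_digests = {}
    if trials_path is not None:
        trials = read_trials(trials_path)
        input_digests[str(trials_path)] = _digest(Path(trials_path))
        seed = None
        config_echo = {}
    elif config is not None:
        trials, truth = generate_cohort(config)
        write_trials(trials, out / "trials.csv")
        truth.to_csv(out / "ground_truth.csv", index=False, float_format=FLOAT_FORMAT)
        seed = config.seed
        config_echo = dataclasses.asdict(config)
    else:
        raise ValueError("provide trials_path or a SessionConfig")

    metrics = compute_metrics(trials, smooth_window=smooth_window)
    write_metrics(metrics, out / "metrics.csv")

    summaries = summarize_conditions(trials, metrics, with_traces=False)
    pd.DataFrame(
        [
            {
                "modality": s.modality,
                "target_distance": s.target_distance,
                "n_trials": s.n_trials,
                "n_completed": s.n_completed,
                "mean_time_to_target": s.mean_time_to_target,
                **{f"mean_{k}": v for k, v in s.means.items()},
                **{f"sd_{k}": v for k, v in s.sds.items()},
            }
            for s in summaries
        ]
    ).to_csv(out / "condition_summary.csv", index=False, float_format=FLOAT_FORMAT)

    grid = np.round(np.arange(0.0, completion_grid_max + 1e-9, 0.1), 3)
    curves = []
    for (modality, dist), grp in metrics.groupby(["modality", "target_distance"], sort=True):
        frac = completion_curve(grp, grid)
        curves.append(
            pd.DataFrame(
                {"modality": modality, "target_distance": dist, "time_s": grid, "fraction_completed": frac}
            )
        )
    pd.concat(curves, ignore_index=True).to_csv(
        out / "completion_curves.csv", index=False, float_format=FLOAT_FORMAT
    )

    report = build_stats_report(metrics, alpha=alpha)
    write_report(report, out / "stats_report.json")

    run_id = hashlib.sha256(
        json.dumps({"config": config_echo, "seed": seed, "inputs": input_digests}, sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest = RunManifest(
        tool_version=__version__,
        run_id=run_id,
        seed=seed,
        config=config_echo,
        input_digests=input_digests,
        n_subjects=int(metrics["subject_id"].nunique()),
        n_trials=int(len(metrics)),
        n_incomplete=int((~metrics["completed"].astype(bool)).sum()),
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    manifest.write(out / "manifest.json")
    return {"metrics": metrics, "summaries": summaries, "report": report, "manifest": manifest}
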