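"""Segment every trial and compute the kinematic metric table.

Reads results/trials.csv, detects movement onset (first sustained positive
velocity) and end (first crossing of 95% of the target distance), and
derives time to target, peak velocity and its latency, RMS position error
against the condition's minimum-jerk reference, and path efficiency.
Writes per-trial metrics, per-condition summaries and completion curves.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from reachkin.io import FLOAT_FORMAT, read_trials, write_metrics
from reachkin.kinematics import completion_curve, compute_metrics, summarize_conditions

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--results-dir", type=Path, default=Path("results"))
parser.add_argument("--smooth-window", type=int, default=5)
args = parser.parse_args()

trials = read_trials(args.results_dir / "trials.csv")
metrics = compute_metrics(trials, smooth_window=args.smooth_window)
write_metrics(metrics, args.results_dir / "metrics.csv")

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
).to_csv(args.results_dir / "condition_summary.csv", index=False, float_format=FLOAT_FORMAT)

grid = np.round(np.arange(0.0, 10.0 + 1e-9, 0.1), 3)
curves = []
for (modality, dist), grp in metrics.groupby(["modality", "target_distance"], sort=True):
    curves.append(
        pd.DataFrame(
            {
                "modality": modality,
                "target_distance": dist,
                "time_s": grid,
                "fraction_completed": completion_curve(grp, grid),
            }
        )
    )
pd.concat(curves, ignore_index=True).to_csv(
    args.results_dir / "completion_curves.csv", index=False, float_format=FLOAT_FORMAT
)

done = metrics[metrics["completed"]]
print(f"{len(metrics)} trials, {len(done)} completed")
for modality, grp in done.groupby("modality"):
    print(
        f"  {modality:14s} time-to-target {grp.time_to_target.mean():.2f}±{grp.time_to_target.std():.2f} s, "
        f"peak velocity {grp.peak_velocity.mean():.0f}±{grp.peak_velocity.std():.0f} %/s, "
        f"path efficiency {grp.path_efficiency.mean():.1f}±{grp.path_efficiency.std():.1f} %"
    )
within_2s = completion_curve(metrics, [2.0])[0]
print(f"completed within 2 s: {100 * within_2s:.2f} % of all trials")
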