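"""Diagnostic figures: trace overlays, scaling plots, completion curves.

Optional step (requires matplotlib).  Renders onset-aligned mean position
and velocity traces with the minimum-jerk reference overlaid, peak
velocity versus distance, the normalized peak-velocity/time-to-target
ellipse summary, completion curves, and path-efficiency distributions.
Figures go under scratch/figures/ (they are diagnostics, not data).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from reachkin.io import read_metrics, read_trials
from reachkin.kinematics import (
    condition_reference,
    mean_position_trace,
    normalize_to_smallest_distance,
)

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--results-dir", type=Path, default=Path("results"))
parser.add_argument("--fig-dir", type=Path, default=Path("scratch/figures"))
args = parser.parse_args()
args.fig_dir.mkdir(parents=True, exist_ok=True)

trials = read_trials(args.results_dir / "trials.csv")
metrics = read_metrics(args.results_dir / "metrics.csv")
done = metrics[metrics["completed"]]

# mean position traces with MJT overlay, one panel per modality
fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
for ax, modality in zip(axes, sorted(done["modality"].unique())):
    for dist, grp in done[done["modality"] == modality].groupby("target_distance"):
        sub = [t for t in trials if t.modality == modality and t.target_distance == dist]
        d_mean = grp["time_to_target"].mean()
        trace = mean_position_trace(sub, grp, 60.0, d_mean)
        ref = condition_reference(dist, d_mean, 60.0)
        ax.plot(trace.times, trace.positions, lw=1.5)
        ax.plot(ref.times, ref.positions, "k--", lw=0.8)
    ax.set_title(modality)
    ax.set_xlabel("time from onset (s)")
axes[0].set_ylabel("position (% workspace)")
fig.tight_layout()
fig.savefig(args.fig_dir / "mean_traces.png", dpi=150)

# peak velocity vs distance
fig, ax = plt.subplots(figsize=(6, 4))
for modality, grp in done.groupby("modality"):
    agg = grp.groupby("target_distance")["peak_velocity"].agg(["mean", "std"])
    ax.errorbar(agg.index, agg["mean"], yerr=agg["std"], marker="o", capsize=3, label=modality)
ax.set_xlabel("movement distance (%)")
ax.set_ylabel("peak velocity (%/s)")
ax.legend()
fig.tight_layout()
fig.savefig(args.fig_dir / "peak_velocity_scaling.png", dpi=150)

# normalized ellipse summary
normalized, ellipses = normalize_to_smallest_distance(done)
fig, ax = plt.subplots(figsize=(6, 5))
from matplotlib.patches import Ellipse

colors = plt.cm.viridis(np.linspace(0, 1, ellipses["target_distance"].nunique()))
cmap = dict(zip(sorted(ellipses["target_distance"].unique()), colors))
for row in ellipses.itertuples():
    ax.add_patch(
        Ellipse(
            (row.norm_peak_velocity_mean, row.norm_time_to_target_mean),
            2 * row.norm_peak_velocity_std,
            2 * row.norm_time_to_target_std,
            alpha=0.35,
            facecolor=cmap[row.target_distance],
            edgecolor="k",
            lw=0.5,
        )
    )
ax.set_xlim(0, normalized["norm_peak_velocity"].quantile(0.99) * 1.2)
ax.set_ylim(0, normalized["norm_time_to_target"].quantile(0.99) * 1.2)
ax.set_xlabel("normalized peak velocity")
ax.set_ylabel("normalized time to target")
fig.tight_layout()
fig.savefig(args.fig_dir / "normalized_ellipses.png", dpi=150)

# completion curves
curves = pd.read_csv(args.results_dir / "completion_curves.csv")
fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
for ax, modality in zip(axes, sorted(curves["modality"].unique())):
    for dist, grp in curves[curves["modality"] == modality].groupby("target_distance"):
        ax.plot(grp["time_s"], 100 * grp["fraction_completed"], label=f"{dist:.0f}%")
    ax.set_xlim(0, 3)
    ax.set_title(modality)
    ax.set_xlabel("time (s)")
axes[0].set_ylabel("trials completed (%)")
axes[1].legend(fontsize=7, ncol=2)
fig.tight_layout()
fig.savefig(args.fig_dir / "completion_curves.png", dpi=150)

# path-efficiency distributions
fig, ax = plt.subplots(figsize=(6, 4))
data = [grp["path_efficiency"].dropna() for _, grp in done.groupby("modality")]
ax.violinplot(data, showmedians=True)
ax.set_xticks([1, 2], sorted(done["modality"].unique()))
ax.axhline(100, color="k", lw=0.6, ls=":")
ax.set_ylabel("path efficiency (%)")
fig.tight_layout()
fig.savefig(args.fig_dir / "path_efficiency.png", dpi=150)

print(f"figures written to {args.fig_dir}")
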