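"""Simulate the study cohort: 10 subjects x 2 control modalities.

Each subject completes 35 trials per modality (7 target distances x 5
blocks) under the default noise models, in which sonomyography-like
control is noisier than manipulandum-like control.  Writes the tidy trial
table and its ground truth under results/.
"""

import argparse
from pathlib import Path

from reachkin.io import FLOAT_FORMAT, write_trials
from reachkin.simulate import SessionConfig, generate_cohort

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=42)
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

config = SessionConfig(
    n_subjects=10, modalities=("manipulandum", "sonomyography"), seed=args.seed
)
trials, truth = generate_cohort(config)
args.out_dir.mkdir(parents=True, exist_ok=True)
write_trials(trials, args.out_dir / "trials.csv")
truth.to_csv(args.out_dir / "ground_truth.csv", index=False, float_format=FLOAT_FORMAT)

print(f"simulated {len(trials)} trials "
      f"({config.n_subjects} subjects x {len(config.modalities)} modalities x "
      f"{config.trials_per_subject_per_modality} trials) with seed {args.seed}")
print(f"wrote {args.out_dir / 'trials.csv'} and {args.out_dir / 'ground_truth.csv'}")
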