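"""Generate a small synthetic experiment and run the analysis pipeline.

Two synthetic participants complete the full schedule (channel trials
only); the pipeline filters the recordings, extracts sign-corrected
feedback intensities in the 180-230 ms window with neutral-profile
subtraction, normalises per participant, and fits the linear model
intensity ~ time-to-target + condition * schedule.  With contextual
switching as the generative mode, mixed-schedule responses replicate the
blocked ones, so the schedule term stays silent.
"""

import numpy as np

from ofcreach import generate_dataset, make_experiment
from ofcreach.analysis import analyze_dataset

rng = np.random.default_rng(7)
schedule = make_experiment("stop_first", rng=rng)
trials, meta = generate_dataset(schedule, 2, mode="switching", rng=rng, channel_only=True)
print(f"generated {len(trials)} channel trials for 2 participants")

result = analyze_dataset(trials)
print(f"analysed {len(result.records)} perturbed trials, "
      f"{len(result.exclusions)} excluded")

print("\nnormalized intensity by condition and schedule (cell means):")
print(result.cell_means.groupby(["condition", "phase"])["normalized"].mean().round(3).to_string())

print("\nlinear-model effect table (F, p):")
print(result.effects[["F", "PR(>F)"]].round(4).to_string())
print(
    "\nA silent schedule term and matching blocked/mixed cell means are the"
    "\nsignature of trial-by-trial controller switching; a universal-controller"
    "\ndataset (mode='universal') collapses the mixed-phase conditions instead."
)
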