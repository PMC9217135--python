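"""Experimental trial schedules: blocked and mixed phases.

Each 16-trial block of one condition holds 11 channel trials (5 perturbation
onset locations x 2 directions plus one zero-perturbation movement) and 5
free unperturbed movements, fully randomised within the block.  The blocked
phase presents 26 such blocks per condition back to back; the mixed phase
presents 26 blocks of 32 trials, each merging a 16-trial stop set and a
16-trial hit set in fully random order.  The realized run-length structure
of the mixed phase (how often a trial follows a condition switch, one
same-condition trial, two, ...) is the design statistic the schedule is
built to control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "TrialSpec",
    "Schedule",
    "ONSET_LOCATIONS",
    "make_block",
    "make_experiment",
    "switch_statistics",
    "run_length_counts",
]

#: the five perturbation onset distances (m): k * 25 cm / 6 for k = 1..5,
#: i.e. 4.2, 8.3, 12.5, 16.7 and 20.8 cm when rounded for display
ONSET_LOCATIONS = np.arange(1, 6) * 0.25 / 6

CONDITIONS = ("stop", "hit")


@dataclass(frozen=True)
class TrialSpec:
    """One experimental trial.

    ``onset_index`` is 1..5 for directional perturbations and ``None`` both
    for the zero-perturbation channel trial and for free movements; any
    perturbed trial runs inside the force channel.
    """

    condition: str
    onset_index: int | None
    direction: str | None
    channel_trial: bool
    phase: str = "blocked"
    block_index: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.onset_index is not None:
            if not 1 <= self.onset_index <= 5:
                raise ValueError("onset_index must be in 1..5")
            if self.direction not in ("left", "right"):
                raise ValueError("a located perturbation needs a direction")
            if not self.channel_trial:
                raise ValueError("perturbed trials are always channel trials")

    @property
    def perturbed(self) -> bool:
        return self.onset_index is not None

    @property
    def onset_location(self) -> float | None:
        return None if self.onset_index is None else float(ONSET_LOCATIONS[self.onset_index - 1])


@dataclass
class Schedule:
    """An ordered list of trials plus the onset-location table."""

    trials: list[TrialSpec]
    onset_locations: np.ndarray
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.trials)

    def phase_trials(self, phase: str) -> list[TrialSpec]:
        return [t for t in self.trials if t.phase == phase]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "trial": np.arange(len(self.trials)),
                "condition": [t.condition for t in self.trials],
                "phase": [t.phase for t in self.trials],
                "block_index": [t.block_index for t in self.trials],
                "onset_index": [t.onset_index for t in self.trials],
                "onset_location_m": [t.onset_location for t in self.trials],
                "direction": [t.direction for t in self.trials],
                "channel_trial": [t.channel_trial for t in self.trials],
            }
        )


def _block_trials(condition: str, phase: str, block_index: int) -> list[TrialSpec]:
    trials = [
        TrialSpec(condition, onset, direction, True, phase, block_index)
        for onset in range(1, 6)
        for direction in ("left", "right")
    ]
    trials.append(TrialSpec(condition, None, None, True, phase, block_index))  # zero-perturbation probe
    trials.extend(TrialSpec(condition, None, None, False, phase, block_index) for _ in range(5))
    return trials


def make_block(
    condition: str,
    rng: np.random.Generator,
    phase: str = "blocked",
    block_index: int = 0,
) -> list[TrialSpec]:
    """One fully randomised 16-trial block of a single condition."""
    trials = _block_trials(condition, phase, block_index)
    return [trials[i] for i in rng.permutation(len(trials))]


def make_experiment(order: str = "stop_first", rng: np.random.Generator | int | None = None) -> Schedule:
    """The full 1664-trial schedule: blocked phase then mixed phase.

    ``order`` selects which condition fills the first 26 blocked blocks.
    The mixed phase holds 26 blocks of 32 trials, each a random interleaving
    of one 16-trial set per condition.
    """
    if order not in ("stop_first", "hit_first"):
        raise ValueError("order must be 'stop_first' or 'hit_first'")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    first, second = ("stop", "hit") if order == "stop_first" else ("hit", "stop")
    trials: list[TrialSpec] = []
    for b in range(26):
        trials.extend(make_block(first, rng, "blocked", b))
    for b in range(26):
        trials.extend(make_block(second, rng, "blocked", 26 + b))
    for b in range(26):
        combined = _block_trials("stop", "mixed", b) + _block_trials("hit", "mixed", b)
        trials.extend(combined[i] for i in rng.permutation(len(combined)))
    return Schedule(trials=trials, onset_locations=ONSET_LOCATIONS.copy(), seed=seed)


def run_length_counts(conditions: Iterable[str]) -> np.ndarray:
    """For each trial after the first, the number of immediately preceding
    consecutive same-condition trials (0 = the trial follows a switch)."""
    seq = np.asarray(list(conditions))
    if len(seq) < 2:
        return np.zeros(0, dtype=int)
    counts = np.zeros(len(seq), dtype=int)
    for i in range(1, len(seq)):
        counts[i] = counts[i - 1] + 1 if seq[i] == seq[i - 1] else 0
    return counts[1:]


def switch_statistics(schedule: Schedule | Iterable[str], max_count: int = 5) -> dict[int, float]:
    """Run-length distribution of the mixed phase.

    Classifies every mixed-phase trial after the first by how many
    same-condition trials immediately precede it (block boundaries do not
    interrupt the count: the sequence is presented continuously).  Returns
    ``{0: fraction after a switch, 1: ..., ..., max_count: tail fraction of
    counts >= max_count}``; the fractions sum to one.
    """
    if isinstance(schedule, Schedule):
        seq = [t.condition for t in schedule.phase_trials("mixed")]
        if not seq:
            raise ValueError("schedule has no mixed phase")
    else:
        seq = list(schedule)
    counts = run_length_counts(seq)
    n = len(counts)
    stats = {k: float(np.mean(counts == k)) for k in range(max_count)}
    stats[max_count] = float(np.mean(counts >= max_count))
    assert abs(sum(stats.values()) - 1.0) < 1e-9 or n == 0
    return stats
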