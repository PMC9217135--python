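"""Feedback-intensity analysis pipeline for 1 kHz reaching recordings.

The pipeline mirrors a standard visuomotor-response workflow: zero-phase
low-pass filtering (a 5th-order Butterworth run forward and backward, i.e.
a tenth-order zero-phase-lag response, 15 Hz cutoff), movement-bound
detection from start- and target-circle geometry, extraction of the mean
lateral channel force over a 180-230 ms window after each perturbation
onset with the participant's neutral (zero-perturbation) force profile
subtracted over the matching window, sign correction so positive always
means a correction toward the shifted target, per-participant min-max
normalisation of cell-mean intensities, and a linear-model comparison of
conditions and schedules with time-to-target as a covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .perturbation import first_crossing_time  # noqa: F401  (re-exported convenience)
from .synth import RawTrial

__all__ = [
    "TrialExcluded",
    "preprocess",
    "movement_bounds",
    "neutral_window_mean",
    "extract_intensity",
    "normalize_participant",
    "compare_conditions",
    "analyze_dataset",
    "AnalysisResult",
    "INTENSITY_WINDOW",
]

#: force-averaging window (s) relative to the perturbation onset
INTENSITY_WINDOW = (0.180, 0.230)
START_RADIUS = 0.008  # start circle 1.6 cm diameter
TARGET_RADIUS = 0.006  # target circle 1.2 cm diameter
TARGET_POSITION = (0.0, 0.25)


class TrialExcluded(Exception):
    """A trial cannot enter the analysis; ``.reason`` is a short code."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def preprocess(raw: RawTrial, cutoff: float = 15.0, order: int = 10) -> RawTrial:
    """Zero-phase low-pass filter all series; enforce a uniform 1 kHz grid.

    ``order`` is the order of the zero-phase response: the filter is
    designed at ``order/2`` and applied forward and backward.
    """
    t = np.asarray(raw.t)
    if len(t) < 2:
        raise ValueError("series too short to filter")
    dts = np.diff(t)
    fs = raw.fs
    if not np.allclose(dts, 1.0 / fs, atol=1e-9):
        # resample onto an exact grid to absorb occasional missed samples
        grid = np.arange(t[0], t[-1] + 0.5 / fs, 1.0 / fs)
        interp = lambda s: np.interp(grid, t, s)  # noqa: E731
        raw = raw.copy_with(
            t=grid,
            x=interp(raw.x),
            y=interp(raw.y),
            vx=interp(raw.vx),
            vy=interp(raw.vy),
            force_x=interp(raw.force_x),
        )
        t = grid
    if order % 2:
        raise ValueError("order must be even (forward-backward application)")
    sos = butter(order // 2, cutoff / (fs / 2), output="sos")
    stacked = np.vstack([raw.x, raw.y, raw.vx, raw.vy, raw.force_x])
    if stacked.shape[1] <= 3 * (order // 2) * 2:
        raise ValueError("series too short for the filter's edge padding")
    fx, fy, fvx, fvy, ff = sosfiltfilt(sos, stacked, axis=1)
    return raw.copy_with(x=fx, y=fy, vx=fvx, vy=fvy, force_x=ff)


def movement_bounds(
    trial: RawTrial,
    start_radius: float = START_RADIUS,
    target_radius: float = TARGET_RADIUS,
    target_position: tuple[float, float] = TARGET_POSITION,
) -> tuple[float, float]:
    """Movement start and end times from circle geometry.

    Start is the last sample at which the cursor centre is still inside the
    start circle before it first leaves it; end is the last sample before
    the cursor centre first enters the target circle (for hit movements the
    cursor then continues into the stopping area — the bound is at target
    entry, not at rest).
    """
    x, y, t = np.asarray(trial.x), np.asarray(trial.y), np.asarray(trial.t)
    x0, y0 = x[0], y[0]
    r_start = np.hypot(x - x0, y - y0)
    if r_start[0] >= start_radius:
        raise TrialExcluded("starts_outside_start_circle")
    outside = np.nonzero(r_start >= start_radius)[0]
    if len(outside) == 0:
        raise TrialExcluded("never_left_start")
    start = t[outside[0] - 1]
    r_target = np.hypot(x - target_position[0], y - target_position[1])
    inside = np.nonzero(r_target < target_radius)[0]
    if len(inside) == 0:
        raise TrialExcluded("never_reached_target")
    if inside[0] == 0:
        raise TrialExcluded("starts_inside_target")
    end = t[inside[0] - 1]
    return float(start), float(end)


def _window_mean(t: np.ndarray, series: np.ndarray, t0: float, window: tuple[float, float]) -> float:
    lo, hi = t0 + window[0], t0 + window[1]
    if hi > t[-1] + 1e-9:
        raise TrialExcluded("window_past_trial_end")
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    return float(np.mean(series[mask]))


def neutral_window_mean(neutral: RawTrial, onset_location: float, window: tuple[float, float] = INTENSITY_WINDOW) -> float:
    """Mean lateral force of a zero-perturbation channel trial over the
    window aligned to its own crossing of ``onset_location``.

    Aligning on the position crossing mirrors how perturbations are
    triggered, so the neutral profile is sampled at the matching movement
    phase.
    """
    y = np.asarray(neutral.y)
    t = np.asarray(neutral.t)
    crossed = np.nonzero(y >= onset_location)[0]
    if len(crossed) == 0:
        raise TrialExcluded("neutral_never_crosses_onset")
    return _window_mean(t, np.asarray(neutral.force_x), float(t[crossed[0]]), window)


def extract_intensity(
    trial: RawTrial,
    neutral_mean: float,
    window: tuple[float, float] = INTENSITY_WINDOW,
) -> float:
    """Sign-corrected feedback intensity (N) of one perturbed channel trial.

    Mean lateral force over ``window`` after the perturbation onset, minus
    the neutral-profile mean over the matching window; responses to
    leftward jumps are negated so positive always means "toward the shifted
    target".
    """
    if trial.trigger_time is None:
        raise TrialExcluded("no_perturbation_onset")
    value = _window_mean(np.asarray(trial.t), np.asarray(trial.force_x), trial.trigger_time, window) - neutral_mean
    if trial.spec.direction == "left":
        value = -value
    return value


def normalize_participant(records: pd.DataFrame, value: str = "intensity") -> pd.DataFrame:
    """Min-max normalise cell-mean intensities to [0, 1] per participant.

    Cells are condition x phase x onset-location; every record receives its
    cell's normalised mean (the analysis operates on mean feedback
    responses).  Participants whose cell means are all equal carry no
    ordering information and are dropped with a ``degenerate`` flag.
    """
    out = records.copy()
    out["normalized"] = np.nan
    out["degenerate"] = False
    cells = ["condition", "phase", "onset_index"]
    for pid, grp in records.groupby("participant"):
        means = grp.groupby(cells, dropna=False)[value].mean()
        lo, hi = means.min(), means.max()
        idx = out["participant"] == pid
        if hi - lo <= 0:
            out.loc[idx, "degenerate"] = True
            continue
        normed = (means - lo) / (hi - lo)
        keys = list(zip(grp["condition"], grp["phase"], grp["onset_index"]))
        out.loc[grp.index, "normalized"] = [normed.loc[k] for k in keys]
    return out


def compare_conditions(records: pd.DataFrame, value: str = "normalized") -> pd.DataFrame:
    """Linear-model comparison: value ~ time_to_target + condition * schedule.

    Fits an OLS model with time-to-target as a continuous covariate and
    condition and schedule (phase) as categorical factors including their
    interaction, and returns the type-II ANOVA table (F and p per term).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    needed = {value, "time_to_target", "condition", "phase"}
    missing = needed - set(records.columns)
    if missing:
        raise ValueError(f"records lack columns {sorted(missing)}")
    if records["condition"].nunique() < 2:
        raise ValueError("need at least two conditions to compare; got one")
    data = records.dropna(subset=[value, "time_to_target"])
    model = smf.ols(f"{value} ~ time_to_target + C(condition) * C(phase)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        index={
            "C(condition)": "condition",
            "C(phase)": "schedule",
            "C(condition):C(phase)": "condition:schedule",
        }
    )
    return table


@dataclass
class AnalysisResult:
    """Outputs of the end-to-end pipeline."""

    records: pd.DataFrame  # one row per analysed perturbed trial
    cell_means: pd.DataFrame  # one row per participant x condition x phase x onset
    effects: pd.DataFrame  # ANOVA table from compare_conditions
    exclusions: pd.DataFrame  # one row per excluded trial with its reason


def analyze_dataset(
    trials: list[RawTrial],
    window: tuple[float, float] = INTENSITY_WINDOW,
    do_filter: bool = True,
) -> AnalysisResult:
    """Run the full pipeline on a collection of raw trials.

    Only channel trials enter the intensity analysis.  Neutral profiles are
    averaged per participant x condition x phase and aligned to each onset
    location by its position crossing.  Time-to-target of a perturbed trial
    is its movement end minus its perturbation onset time.  Every channel
    trial appears exactly once in the records or the exclusion log.
    """
    channel = [tr for tr in trials if tr.spec.channel_trial]
    if do_filter:
        channel = [preprocess(tr) for tr in channel]
    # neutral window means per (participant, condition, phase, onset_index)
    neutral_means: dict[tuple, list[float]] = {}
    exclusions = []
    for tr in channel:
        if tr.spec.perturbed:
            continue
        for onset_index, loc in enumerate(np.arange(1, 6) * 0.25 / 6, start=1):
            try:
                v = neutral_window_mean(tr, float(loc), window)
            except TrialExcluded:
                continue
            neutral_means.setdefault(
                (tr.participant_id, tr.spec.condition, tr.spec.phase, onset_index), []
            ).append(v)
    rows = []
    for tr in channel:
        spec = tr.spec
        if not spec.perturbed:
            continue  # neutral trials feed the baseline, not the records
        key = (tr.participant_id, spec.condition, spec.phase, spec.onset_index)
        try:
            if key not in neutral_means:
                raise TrialExcluded("no_neutral_profile")
            start, end = movement_bounds(tr)
            ttt = end - tr.trigger_time
            if ttt <= 0:
                raise TrialExcluded("perturbation_after_movement_end")
            inten = extract_intensity(tr, float(np.mean(neutral_means[key])), window)
        except TrialExcluded as exc:
            exclusions.append(
                {
                    "participant": tr.participant_id,
                    "condition": spec.condition,
                    "phase": spec.phase,
                    "onset_index": spec.onset_index,
                    "reason": exc.reason,
                }
            )
            continue
        rows.append(
            {
                "participant": tr.participant_id,
                "condition": spec.condition,
                "phase": spec.phase,
                "onset_index": spec.onset_index,
                "direction": spec.direction,
                "intensity": inten,
                "time_to_target": ttt,
                "onset_time": tr.trigger_time,
                "movement_start": start,
                "movement_end": end,
            }
        )
    records = pd.DataFrame(rows)
    if len(records) == 0:
        raise ValueError("no perturbed channel trials survived the pipeline")
    records = normalize_participant(records)
    cells = (
        records[~records["degenerate"]]
        .groupby(["participant", "condition", "phase", "onset_index"], as_index=False)
        .agg(intensity=("intensity", "mean"), normalized=("normalized", "mean"), time_to_target=("time_to_target", "mean"))
    )
    effects = compare_conditions(cells)
    return AnalysisResult(
        records=records,
        cell_means=cells,
        effects=effects,
        exclusions=pd.DataFrame(exclusions, columns=["participant", "condition", "phase", "onset_index", "reason"]),
    )
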