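"""Tests of the filtering, movement-bound, intensity and model stages."""

import numpy as np
import pandas as pd
import pytest

from ofcreach.analysis import (
    TrialExcluded,
    analyze_dataset,
    compare_conditions,
    extract_intensity,
    movement_bounds,
    neutral_window_mean,
    normalize_participant,
    preprocess,
)
from ofcreach.schedule import TrialSpec, make_experiment
from ofcreach.synth import ParticipantParams, RawTrial, generate_dataset


def _trial(y=None, x=None, force=None, n=2000, direction="right", trigger=None, condition="stop"):
    t = np.arange(n) / 1000.0
    y = np.zeros(n) if y is None else y
    x = np.zeros(n) if x is None else x
    force = np.zeros(n) if force is None else force
    spec = TrialSpec(condition, 3 if trigger is not None else None,
                     direction if trigger is not None else None,
                     True, "blocked", 0)
    return RawTrial(
        spec=spec, participant_id="P00", t=t, x=x, y=y,
        vx=np.gradient(x, 0.001), vy=np.gradient(y, 0.001), force_x=force,
        trigger_time=trigger, start_tone_delay=1.2,
    )


def _sine_attenuation(freq):
    n = 4000
    t = np.arange(n) / 1000.0
    sig = np.sin(2 * np.pi * freq * t)
    tr = _trial(force=sig, n=n)
    out = preprocess(tr).force_x
    core = slice(1000, 3000)  # avoid edge transients
    return np.max(np.abs(out[core])) / 1.0


def test_low_frequency_passes_unattenuated():
    assert _sine_attenuation(2.0) > 0.99


def test_fifty_hertz_attenuated_by_more_than_40_db():
    assert _sine_attenuation(50.0) < 10 ** (-40 / 20)


def test_zero_phase_pulse_peak_stays_put():
    n = 3000
    force = np.exp(-0.5 * ((np.arange(n) - 1500) / 120.0) ** 2)
    out = preprocess(_trial(force=force, n=n)).force_x
    assert abs(int(np.argmax(out)) - 1500) <= 1


def test_preprocess_idempotent_on_bandlimited_data():
    n = 3000
    t = np.arange(n) / 1000.0
    # 1 Hz tone under a Gaussian envelope: deep in the passband, zero edges
    force = np.sin(2 * np.pi * 1.0 * t) * np.exp(-0.5 * ((t - 1.5) / 0.25) ** 2)
    once = preprocess(_trial(force=force, n=n))
    twice = preprocess(once)
    assert np.max(np.abs(twice.force_x - once.force_x)) < 1e-9


def test_preprocess_resamples_irregular_grid():
    tr = _trial(n=2000)
    # drop a sample to emulate a recording glitch
    keep = np.r_[np.arange(900), np.arange(901, 2000)]
    broken = tr.copy_with(t=tr.t[keep], x=tr.x[keep], y=tr.y[keep],
                          vx=tr.vx[keep], vy=tr.vy[keep], force_x=tr.force_x[keep])
    fixed = preprocess(broken)
    assert np.allclose(np.diff(fixed.t), 0.001)


def test_movement_bounds_match_analytic_crossings():
    """Constant-velocity straight pass: bounds agree with the closed-form
    circle-crossing times to one sample."""
    n = 2000
    t = np.arange(n) / 1000.0
    v = 0.5  # m/s
    y = np.clip(v * (t - 0.2), 0.0, None)  # starts moving at 0.2 s
    tr = _trial(y=y, n=n)
    start, end = movement_bounds(tr)
    t_start = 0.2 + 0.008 / v  # leaves the 0.8 cm start radius
    t_end = 0.2 + (0.25 - 0.006) / v  # enters the 0.6 cm target circle
    assert abs(start - (t_start - 0.001)) <= 0.0015
    assert abs(end - (t_end - 0.001)) <= 0.0015


def test_stationary_cursor_excluded():
    with pytest.raises(TrialExcluded, match="never_left_start"):
        movement_bounds(_trial())


def test_bounds_end_at_target_entry_not_at_rest():
    """A hit-style pass through the target bounds at circle entry."""
    n = 2000
    t = np.arange(n) / 1000.0
    y = np.clip(0.5 * t, 0.0, 0.40)  # overshoots to 40 cm
    tr = _trial(y=y, n=n, condition="hit")
    _, end = movement_bounds(tr)
    assert end < (0.25 / 0.5)  # before reaching the 25 cm centre


def test_intensity_of_identical_traces_is_zero():
    force = np.random.default_rng(0).normal(size=2000) * 0.0 + 0.3
    tr = _trial(force=force.copy(), trigger=0.5)
    assert extract_intensity(tr, neutral_mean=0.3) == pytest.approx(0.0)


def test_intensity_recovers_planted_offset_and_sign():
    n = 2000
    base = np.full(n, 0.1)
    forceR = base.copy()
    w = slice(int((0.5 + 0.18) * 1000), int((0.5 + 0.23) * 1000) + 1)
    forceR[w] += 0.7
    right = _trial(force=forceR, trigger=0.5, direction="right")
    assert extract_intensity(right, neutral_mean=0.1) == pytest.approx(0.7)
    left = _trial(force=-forceR, trigger=0.5, direction="left")
    assert extract_intensity(left, neutral_mean=-0.1) == pytest.approx(0.7)


def test_intensity_window_past_end_excluded():
    tr = _trial(trigger=1.9)
    with pytest.raises(TrialExcluded, match="window_past_trial_end"):
        extract_intensity(tr, neutral_mean=0.0)


def test_minmax_normalisation_examples_and_affine_invariance():
    rows = []
    for i, (onset, val) in enumerate([(1, 1.0), (2, 2.0), (3, 3.0)]):
        rows.append(dict(participant="P0", condition="stop", phase="blocked",
                         onset_index=onset, intensity=val))
    df = pd.DataFrame(rows)
    out = normalize_participant(df)
    assert sorted(out["normalized"]) == [0.0, 0.5, 1.0]
    aff = df.assign(intensity=3.0 * df["intensity"] + 2.0)
    out2 = normalize_participant(aff)
    assert np.allclose(sorted(out2["normalized"]), [0.0, 0.5, 1.0])
    flat = df.assign(intensity=1.0)
    out3 = normalize_participant(flat)
    assert out3["degenerate"].all()


def test_compare_conditions_relabeled_schedule_has_no_effect():
    rng = np.random.default_rng(0)
    n = 200
    ttt = rng.uniform(0.1, 0.5, n)
    cond = np.where(rng.uniform(size=n) < 0.5, "stop", "hit")
    inten = 2.0 * ttt + (cond == "hit") * 0.5 + rng.normal(0, 0.05, n)
    df = pd.DataFrame(dict(normalized=inten, time_to_target=ttt, condition=cond,
                           phase=rng.permutation(np.r_[["blocked"] * 100, ["mixed"] * 100])))
    table = compare_conditions(df)
    assert table.loc["schedule", "F"] < 2.5
    assert table.loc["schedule", "PR(>F)"] > 0.05


def test_compare_conditions_recovers_planted_condition_effect():
    rng = np.random.default_rng(1)
    n = 300
    ttt = rng.uniform(0.1, 0.5, n)
    cond = np.where(np.arange(n) % 2 == 0, "stop", "hit")
    phase = np.where(np.arange(n) % 4 < 2, "blocked", "mixed")
    inten = 1.5 * ttt + (cond == "hit") * 0.4 + rng.normal(0, 0.05, n)
    df = pd.DataFrame(dict(normalized=inten, time_to_target=ttt, condition=cond, phase=phase))
    table = compare_conditions(df)
    assert table.loc["condition", "PR(>F)"] < 1e-6
    import statsmodels.formula.api as smf

    fit = smf.ols("normalized ~ time_to_target + C(condition) * C(phase)", df).fit()
    coef = fit.params.filter(like="C(condition)").iloc[0]
    assert coef == pytest.approx(-0.4, abs=0.03)  # hit is the reference level


def test_compare_conditions_single_condition_errors():
    df = pd.DataFrame(dict(normalized=[1, 2], time_to_target=[0.1, 0.2],
                           condition=["stop", "stop"], phase=["blocked", "mixed"]))
    with pytest.raises(ValueError, match="two conditions"):
        compare_conditions(df)


def test_pipeline_exclusion_accounting():
    """Every perturbed channel trial lands in the records or the exclusion
    log, exactly once."""
    sch = make_experiment("stop_first", rng=4)
    # a single participant, two blocked blocks' worth of channel trials
    wanted = [t for t in sch.trials if t.block_index in (0, 26)]
    small = type(sch)(trials=wanted, onset_locations=sch.onset_locations)
    trials, _ = generate_dataset(small, 1, "switching", rng=5, channel_only=True)
    # sabotage one trial so its window overruns the recording
    cut = None
    for i, tr in enumerate(trials):
        if tr.spec.perturbed:
            k = int((tr.trigger_time + 0.1) * 1000)
            trials[i] = tr.copy_with(t=tr.t[:k], x=tr.x[:k], y=tr.y[:k],
                                     vx=tr.vx[:k], vy=tr.vy[:k], force_x=tr.force_x[:k])
            cut = trials[i]
            break
    res = analyze_dataset(trials)
    n_perturbed = sum(tr.spec.perturbed for tr in trials)
    assert len(res.records) + len(res.exclusions) == n_perturbed
    assert len(res.exclusions) >= 1
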