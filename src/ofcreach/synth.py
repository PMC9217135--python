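"""Synthetic participant recordings for the stop/hit switching paradigm.

Each generated trial is a 1 kHz recording of cursor position, velocity and
lateral channel force with the statistical structure the analysis pipeline
assumes: forward kinematics taken from the task's LQR simulation (upsampled
by monotone cubic interpolation, velocities by differentiation), a ~150 ms
visuomotor latency between the target jump and the force response, a
per-participant multiplicative response gain, smooth additive sensorimotor
noise, and a target jump of 2 cm that returns after 250 ms.  Channel trials
treat the force channel as infinitely stiff: lateral cursor motion is
clamped to (near) zero and the commanded lateral force is what the wall —
and hence the force transducer — records.

The generator embodies the two competing control architectures as modes:
``switching`` participants use the task-appropriate controller on every
trial, so mixed-schedule responses replicate blocked ones; ``universal``
participants use a single controller interpolated between the hit and stop
cost sets throughout the mixed phase, so mixed-schedule hit and stop
responses collapse onto each other.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, sosfiltfilt

from .lqr import simulate
from .perturbation import DEFAULT_DELAY, DEFAULT_JUMP, PerturbationEvent, first_crossing_time
from .schedule import ONSET_LOCATIONS, Schedule, TrialSpec
from .tasks import TaskSpec, make_task, make_universal_task, task_controller

__all__ = [
    "ParticipantParams",
    "RawTrial",
    "ChannelWall",
    "generate_trial",
    "generate_dataset",
    "check_velocity_criteria",
    "draw_start_tone_delay",
]

FS = 1000  # Hz
JUMP_RETURN = 0.250  # s the target jump is maintained before returning
PRE_SAMPLES = 200  # stationary samples before movement onset
POST_SAMPLES = 250  # hold samples after movement end

#: peak-velocity compliance window (m/s) and peak-location window (m)
PEAK_SPEED_RANGE = (0.52, 0.68)
PEAK_LOCATION_RANGE = (0.1125, 0.1375)

# noise bandwidths (Hz): kinematic variability is slow (planning/execution
# drift), force noise somewhat faster; both well below the 15 Hz analysis
# filter so the pipeline's filtering behaves as it would on real data
KINEMATIC_NOISE_CUTOFF = 2.5
FORCE_NOISE_CUTOFF = 6.0


@dataclass(frozen=True)
class ChannelWall:
    """Viscoelastic force-channel wall of the experimental apparatus.

    The printed apparatus values are a stiffness of 2 N/m with damping of
    4000 N s/m; such a wall is so overdamped that the generator treats the
    channel as rigid, and these parameters are carried as configuration
    only.  ``plausible`` swaps the two numbers (4000 N/m stiffness, 2 N s/m
    damping — the usual regime for such an apparatus, suggesting a
    transposition in print).
    """

    stiffness: float = 2.0  # N/m
    damping: float = 4000.0  # N s/m

    @classmethod
    def preset(cls, name: str = "printed") -> "ChannelWall":
        if name == "printed":
            return cls()
        if name == "plausible":
            return cls(stiffness=4000.0, damping=2.0)
        raise ValueError("preset must be 'printed' or 'plausible'")


@dataclass(frozen=True)
class ParticipantParams:
    """Generative parameters of one synthetic participant."""

    participant_id: str = "P00"
    response_gain: float = 1.0  # scales the feedback force response
    latency_jitter_sd: float = 0.008  # s, trial-to-trial jitter of the 150 ms latency
    kinematic_noise_sd: float = 0.0008  # m, smooth positional noise
    force_noise_sd: float = 0.08  # N, smooth force noise
    controller_assignment: str = "switching"  # or "universal"
    universal_weight: float = 0.5  # stop share of the universal blend
    baseline_force_coef: float = 0.15  # N per m/s: small lateral bias force in the channel

    def __post_init__(self) -> None:
        if self.response_gain <= 0:
            raise ValueError("response_gain must be positive")
        for name in ("latency_jitter_sd", "kinematic_noise_sd", "force_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.controller_assignment not in ("switching", "universal"):
            raise ValueError("controller_assignment must be 'switching' or 'universal'")


@dataclass
class RawTrial:
    """One 1 kHz recording plus its trial metadata."""

    spec: TrialSpec
    participant_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    force_x: np.ndarray
    trigger_time: float | None  # s from recording start; None if unperturbed
    start_tone_delay: float
    fs: float = FS

    def copy_with(self, **kw) -> "RawTrial":
        return replace(self, **kw)


def draw_start_tone_delay(rng: np.random.Generator, lam: float = 0.7, lo: float = 1.0, hi: float = 2.0) -> float:
    """Exponential(lambda) start-tone delay truncated to [lo, hi] by inverse CDF."""
    u = rng.uniform(1.0 - np.exp(-lam * lo), 1.0 - np.exp(-lam * hi))
    return float(-np.log1p(-u) / lam)


def _smooth_noise(rng: np.random.Generator, n: int, sd: float, cutoff: float = 5.0) -> np.ndarray:
    """Low-pass filtered white noise rescaled to the requested SD."""
    if sd == 0:
        return np.zeros(n)
    sos = butter(2, cutoff / (FS / 2), output="sos")
    w = sosfiltfilt(sos, rng.standard_normal(n + 400))[200:-200]
    s = w.std()
    return w * (sd / s) if s > 0 else np.zeros(n)


class _SimCache:
    """Deterministic model pieces shared across trials.

    Caches, per controller task: the unperturbed forward kinematics
    upsampled to 1 kHz, and per (onset index, direction) the channel-mode
    lateral force response at 1 kHz relative to the trigger sample (the
    sample at which the model movement crosses the onset location).
    """

    def __init__(self) -> None:
        self._kin: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._force: dict[tuple[str, int, str], np.ndarray] = {}
        self._ctrl: dict[str, tuple] = {}

    def controller(self, task: TaskSpec):
        key = task.name
        if key not in self._ctrl:
            self._ctrl[key] = task_controller(task)
        return self._ctrl[key]

    def kinematics(self, task: TaskSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(y, vy, model trajectory times) of the unperturbed movement at 1 kHz."""
        if task.name not in self._kin:
            model, gains, costs = self.controller(task)
            traj = simulate(model, gains, reference=costs.target)
            t_ms = np.arange(int(round(traj.time[-1] * FS)) + 1) / FS
            interp = PchipInterpolator(traj.time, traj.forward_position())
            y = interp(t_ms)
            vy = np.gradient(y, 1.0 / FS)
            self._kin[task.name] = (y, vy, t_ms)
        return self._kin[task.name]

    def force_response(self, task: TaskSpec, onset_index: int, direction: str) -> np.ndarray:
        """Channel-mode lateral force (N) at 1 kHz, sample 0 = trigger."""
        key = (task.name, onset_index, direction)
        if key not in self._force:
            model, gains, costs = self.controller(task)
            dt = model.dt
            N = costs.horizon
            kin = simulate(model, gains, reference=costs.target)
            location = float(ONSET_LOCATIONS[onset_index - 1])
            cross = first_crossing_time(kin, location)
            if cross is None:
                raise RuntimeError(f"model movement never crosses onset location {location}")
            trig_step = int(round(cross / dt))
            sign = 1.0 if direction == "right" else -1.0
            onset = trig_step + int(round(DEFAULT_DELAY / dt))
            ref = np.tile(costs.target, (N + 1, 1))
            if onset < N:
                ret = min(N + 1, onset + int(round(JUMP_RETURN / dt)))
                ref[onset:ret, 0] += sign * DEFAULT_JUMP
            traj = simulate(model, gains, reference=ref, channel=True)
            fx = traj.lateral_force()[trig_step:]
            t_rel = np.arange(len(fx)) * dt
            if len(fx) >= 2:
                t_ms = np.arange(int(round(t_rel[-1] * FS)) + 1) / FS
                fx_ms = PchipInterpolator(t_rel, fx)(t_ms)
            else:  # trigger at the very last step
                fx_ms = fx
            self._force[key] = fx_ms
        return self._force[key]


_GLOBAL_CACHE = _SimCache()


def _movement_controller(spec: TrialSpec, participant: ParticipantParams) -> TaskSpec:
    if participant.controller_assignment == "universal" and spec.phase == "mixed":
        return make_universal_task(weight=participant.universal_weight)
    return make_task(spec.condition)


def generate_trial(
    spec: TrialSpec,
    participant: ParticipantParams,
    rng: np.random.Generator,
    cache: _SimCache | None = None,
) -> RawTrial:
    """Generate one 1 kHz recording for a trial of the schedule.

    The cursor rests in the start circle for 200 ms, executes the
    controller's movement, and holds its final position for 250 ms.  On
    perturbed trials the trigger is the first recorded sample at which the
    (noisy) forward position crosses the onset location, and the lateral
    force response — the assigned controller's channel-mode response,
    scaled by the participant's gain and shifted by the trial's latency
    jitter — is laid onto the force trace from that sample onward.
    """
    cache = cache or _GLOBAL_CACHE
    task = _movement_controller(spec, participant)
    y_mv, vy_mv, _ = cache.kinematics(task)
    n_mv = len(y_mv)
    n = PRE_SAMPLES + n_mv + POST_SAMPLES
    t = np.arange(n) / FS
    y = np.empty(n)
    y[:PRE_SAMPLES] = 0.0
    y[PRE_SAMPLES : PRE_SAMPLES + n_mv] = y_mv
    y[PRE_SAMPLES + n_mv :] = y_mv[-1]
    vy_clean = np.zeros(n)
    vy_clean[PRE_SAMPLES : PRE_SAMPLES + n_mv] = vy_mv

    y = y + _smooth_noise(rng, n, participant.kinematic_noise_sd, cutoff=KINEMATIC_NOISE_CUTOFF)
    lateral_sd = participant.kinematic_noise_sd * (0.05 if spec.channel_trial else 1.0)
    x = _smooth_noise(rng, n, lateral_sd, cutoff=KINEMATIC_NOISE_CUTOFF)
    vy = np.gradient(y, 1.0 / FS)
    vx = np.gradient(x, 1.0 / FS)

    force = _smooth_noise(rng, n, participant.force_noise_sd, cutoff=FORCE_NOISE_CUTOFF)
    trigger_time: float | None = None
    if spec.channel_trial:
        # small reproducible lateral bias against the wall; identical in
        # perturbed and neutral trials so it cancels under neutral subtraction
        force = force + participant.baseline_force_coef * vy_clean
    if spec.perturbed:
        crossed = np.nonzero(y >= spec.onset_location)[0]
        trig = int(crossed[0]) if len(crossed) else n - 1
        trigger_time = t[trig]
        resp = cache.force_response(task, spec.onset_index, spec.direction)
        jitter = int(round(rng.normal(0.0, participant.latency_jitter_sd) * FS))
        start = trig + jitter
        take = min(len(resp), n - start)
        if take > 0:
            seg = participant.response_gain * resp[:take]
            force[start : start + take] += seg
    return RawTrial(
        spec=spec,
        participant_id=participant.participant_id,
        t=t,
        x=x,
        y=y,
        vx=vx,
        vy=vy,
        force_x=force,
        trigger_time=trigger_time,
        start_tone_delay=draw_start_tone_delay(rng),
    )


def default_participants(
    n_participants: int,
    mode: str,
    rng: np.random.Generator,
    gain_sigma: float = 0.25,
) -> list[ParticipantParams]:
    """Draw a pool of participants with log-normal response gains (median 1)."""
    return [
        ParticipantParams(
            participant_id=f"P{i:02d}",
            response_gain=float(np.exp(rng.normal(0.0, gain_sigma))),
            controller_assignment=mode,
        )
        for i in range(n_participants)
    ]


def generate_dataset(
    schedule: Schedule,
    n_participants: int,
    mode: str = "switching",
    rng: np.random.Generator | int | None = None,
    participants: list[ParticipantParams] | None = None,
    channel_only: bool = False,
):
    """One RawTrial per schedule entry per participant, plus a metadata table.

    ``mode`` selects the control architecture every generated participant
    uses (``switching`` or ``universal``).  ``channel_only`` restricts the
    output to channel trials — the only trials the intensity analysis
    consumes — which cuts generation time roughly by a third.
    """
    if mode not in ("switching", "universal"):
        raise ValueError("mode must be 'switching' or 'universal'")
    if n_participants < 0:
        raise ValueError("n_participants must be nonnegative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if participants is None:
        participants = default_participants(n_participants, mode, rng)
    cache = _SimCache()
    trials: list[RawTrial] = []
    rows = []
    for part in participants:
        for i, spec in enumerate(schedule.trials):
            if channel_only and not spec.channel_trial:
                continue
            trial = generate_trial(spec, part, rng, cache)
            trials.append(trial)
            rows.append(
                {
                    "participant": part.participant_id,
                    "trial": i,
                    "condition": spec.condition,
                    "phase": spec.phase,
                    "block_index": spec.block_index,
                    "onset_index": spec.onset_index,
                    "direction": spec.direction,
                    "channel_trial": spec.channel_trial,
                    "trigger_time_s": trial.trigger_time,
                    "start_tone_delay_s": trial.start_tone_delay,
                }
            )
    import pandas as pd

    return trials, pd.DataFrame(rows)


def check_velocity_criteria(trial: RawTrial) -> tuple[bool, float, float]:
    """Peak-velocity compliance check: (passed, peak speed m/s, peak location m).

    A trial passes when its peak forward speed lies in 52-68 cm/s and the
    forward distance at which the peak occurs lies in 11.25-13.75 cm.
    """
    vy = np.asarray(trial.vy)
    if np.max(np.abs(vy)) < 0.05:
        raise ValueError("no movement detected in trial")
    i = int(np.argmax(vy))
    peak = float(vy[i])
    loc = float(trial.y[i] - trial.y[0])
    ok = PEAK_SPEED_RANGE[0] <= peak <= PEAK_SPEED_RANGE[1] and PEAK_LOCATION_RANGE[0] <= loc <= PEAK_LOCATION_RANGE[1]
    return ok, peak, loc
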