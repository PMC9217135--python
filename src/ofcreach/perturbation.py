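"""Virtual target-jump sweeps and feedback-intensity profiles.

For a given task controller the sweep perturbs one simulated movement per
movement timestep: the lateral target reference is shifted by a fixed jump,
delayed by the 150 ms visuomotor latency relative to its trigger, and the
model's corrective lateral force is averaged over a short window after the
shift (10-60 ms; the muscle model is a single low-pass filter so model
responses ramp fast, which is why this window is earlier than the 180-230 ms
window used on human recordings).  Each record carries the trigger time,
the time-to-target (time until the movement crosses the 25 cm measurement
distance), the time-to-movement-end and the forward position and velocity
at the trigger, so the same profile can be read in any of the three
reference frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lqr import StateSpaceModel, Trajectory, simulate
from .tasks import TaskSpec, task_controller

__all__ = [
    "PerturbationEvent",
    "IntensityProfile",
    "run_sweep",
    "first_crossing_time",
    "time_to_target",
    "profile_views",
]

#: visuomotor latency (s) between a perturbation trigger and the target shift
DEFAULT_DELAY = 0.150
#: lateral target jump magnitude (m)
DEFAULT_JUMP = 0.02
#: force-averaging window (s) relative to the target shift
DEFAULT_WINDOW = (0.010, 0.060)


@dataclass(frozen=True)
class PerturbationEvent:
    """A single target jump: triggered at a step, applied one latency later."""

    trigger_step: int
    delay: float = DEFAULT_DELAY
    jump: float = DEFAULT_JUMP
    dt: float = 0.01

    @property
    def onset_step(self) -> int:
        return self.trigger_step + int(round(self.delay / self.dt))

    def reference(self, base_reference: np.ndarray) -> np.ndarray:
        """Reference series with the lateral target shifted from onset onward."""
        ref = np.array(base_reference, dtype=float, copy=True)
        ref[self.onset_step :, 0] += self.jump
        return ref


@dataclass
class IntensityProfile:
    """Per-trigger feedback-intensity records of one sweep."""

    task: str
    jump: float
    delay: float
    trigger_time: np.ndarray
    time_to_target: np.ndarray
    time_to_movement_end: np.ndarray
    position: np.ndarray
    velocity: np.ndarray
    intensity: np.ndarray
    n_dropped: int = 0
    mode: str = "free"
    baseline: Trajectory | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.trigger_time)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "trigger_time_s": self.trigger_time,
                "time_to_target_s": self.time_to_target,
                "time_to_movement_end_s": self.time_to_movement_end,
                "position_m": self.position,
                "velocity_mps": self.velocity,
                "intensity_N": self.intensity,
            }
        )


def first_crossing_time(trajectory: Trajectory, distance: float) -> float | None:
    """First time the forward position crosses ``distance``.

    Linear interpolation between the bracketing samples; ``None`` if the
    movement never reaches the distance.
    """
    p = trajectory.forward_position()
    above = np.nonzero(p >= distance)[0]
    if len(above) == 0:
        return None
    i = int(above[0])
    if i == 0:
        return float(trajectory.time[0])
    frac = (distance - p[i - 1]) / (p[i] - p[i - 1])
    return float(trajectory.time[i - 1] + frac * trajectory.dt)


def time_to_target(trajectory: Trajectory, distance: float, trigger_time: float = 0.0) -> float:
    """Time from ``trigger_time`` until the movement crosses ``distance``.

    Movements that stop at (or just short of) the measurement distance never
    formally cross it, in which case the movement end stands in for the
    crossing — for the stop and hit tasks time-to-target and
    time-to-movement-end are then identical by construction.
    """
    crossing = first_crossing_time(trajectory, distance)
    if crossing is None:
        crossing = float(trajectory.time[-1])
    return crossing - trigger_time


def run_sweep(
    task: TaskSpec,
    jump: float = DEFAULT_JUMP,
    delay: float = DEFAULT_DELAY,
    mode: str = "free",
    model: StateSpaceModel | None = None,
    window: tuple[float, float] = DEFAULT_WINDOW,
    time_unit: str = "step",
) -> IntensityProfile:
    """Map the feedback-intensity profile of a task by a full trigger sweep.

    One movement is simulated per trigger step with exactly one perturbation
    each; intensity is the mean lateral force over ``window`` after the
    target shift, minus the unperturbed lateral force over the same absolute
    samples.  Triggers whose measurement window does not fit before the end
    of the movement are dropped (counted in ``n_dropped``).  ``mode`` is
    ``"free"`` (unconstrained movement) or ``"channel"`` (lateral kinematics
    clamped by an infinitely stiff channel while the commanded lateral force
    is recorded).
    """
    if mode not in ("free", "channel"):
        raise ValueError("mode must be 'free' or 'channel'")
    model, gains, costs = task_controller(task, model=model, time_unit=time_unit)
    if model.n_dims != 2:
        raise ValueError("the perturbation sweep requires a two-dimensional plant")
    dt = model.dt
    N = costs.horizon
    channel = mode == "channel"
    base = simulate(model, gains, reference=costs.target, channel=channel)
    base_ref = base.reference
    base_force = base.lateral_force()
    # kinematic context is read from an unconstrained movement even in
    # channel mode (the channel leaves the forward axis untouched anyway)
    kin = base if not channel else simulate(model, gains, reference=costs.target)
    crossing = first_crossing_time(kin, task.measurement_distance)
    end_time = N * dt
    if crossing is None:
        crossing = end_time
    w_lo = int(round(window[0] / dt))
    w_hi = int(round(window[1] / dt))
    records = {k: [] for k in ("trig", "ttt", "ttme", "pos", "vel", "inten")}
    n_dropped = 0
    for trig in range(N):
        event = PerturbationEvent(trigger_step=trig, delay=delay, jump=jump, dt=dt)
        onset = event.onset_step
        if onset + w_hi > N:
            n_dropped += 1
            continue
        traj = simulate(model, gains, reference=event.reference(base_ref), channel=channel)
        sl = slice(onset + w_lo, onset + w_hi + 1)
        inten = float(np.mean(traj.lateral_force()[sl]) - np.mean(base_force[sl]))
        records["trig"].append(trig * dt)
        records["ttt"].append(crossing - trig * dt)
        records["ttme"].append(end_time - trig * dt)
        records["pos"].append(float(kin.forward_position()[trig]))
        records["vel"].append(float(kin.forward_velocity()[trig]))
        records["inten"].append(inten)
    return IntensityProfile(
        task=task.name,
        jump=jump,
        delay=delay,
        trigger_time=np.array(records["trig"]),
        time_to_target=np.array(records["ttt"]),
        time_to_movement_end=np.array(records["ttme"]),
        position=np.array(records["pos"]),
        velocity=np.array(records["vel"]),
        intensity=np.array(records["inten"]),
        n_dropped=n_dropped,
        mode=mode,
        baseline=base,
    )


def profile_views(profile: IntensityProfile) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """The same records indexed on the three abscissae, each sorted ascending.

    Returns ``{"time_to_target": (x, intensity), "time_to_movement_end": ...,
    "position": ...}`` with no resampling — the records are merely reordered.
    """
    if len(profile) == 0:
        raise ValueError("profile has no records")
    out = {}
    for name, x in (
        ("time_to_target", profile.time_to_target),
        ("time_to_movement_end", profile.time_to_movement_end),
        ("position", profile.position),
    ):
        order = np.argsort(x)
        out[name] = (x[order], profile.intensity[order])
    return out
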