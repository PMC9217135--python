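"""The three reaching-task controller configurations: stop, hit, long-stop.

*stop* reaches 25 cm in 700 ms and halts at the target (terminal costs
``w_p = 1.5, w_v = 1, w_f = 0.1``, activation cost ``R = 3e-6``).  *hit*
reaches the same target in 620 ms with the terminal velocity and force
costs reduced 50-fold, removing the incentive to brake.  *long-stop* is a
control simulation: the stop cost set applied to a virtual target at 28 cm
over 800 ms, so the movement is still passing the real 25 cm target with
substantial speed — a hit-like movement produced by the stop controller.
To reshape the long-stop velocity profile towards the hit kinematics its
activation cost is modulated over time by a normalised exponential ramp
C(t) with mean one, so the total activation budget is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .lqr import ControllerGains, CostSchedule, StateSpaceModel, build_point_mass_model, solve_lqr

__all__ = [
    "TaskSpec",
    "make_task",
    "make_universal_task",
    "activation_profile",
    "task_cost_schedule",
    "task_controller",
    "MEASUREMENT_DISTANCE",
]

#: forward distance (m) whose crossing defines "target" events for every task
MEASUREMENT_DISTANCE = 0.25


@dataclass(frozen=True)
class TaskSpec:
    """One controller configuration.

    ``activation_params`` is ``None`` for a stationary activation cost, or
    the ``(p, q, r)`` constants of the exponential ramp
    ``C(t) ∝ exp((p t + q) / r)`` used by the long-stop task.
    """

    name: str
    target_distance: float  # m
    duration: float  # s
    w_p: float
    w_v: float
    w_f: float
    activation_cost: float
    activation_params: tuple[float, float, float] | None = None
    measurement_distance: float = MEASUREMENT_DISTANCE

    def horizon(self, dt: float = 0.01) -> int:
        return int(round(self.duration / dt))


_STOP = TaskSpec(
    name="stop",
    target_distance=0.25,
    duration=0.700,
    w_p=1.5,
    w_v=1.0,
    w_f=0.1,
    activation_cost=3e-6,
)
_HIT = replace(
    _STOP,
    name="hit",
    duration=0.620,
    w_v=1.0 / 50.0,
    w_f=0.1 / 50.0,
)
_LONG_STOP = replace(
    _STOP,
    name="long_stop",
    target_distance=0.28,
    duration=0.800,
    activation_params=(1.0, -1000.0, 65.0),
)

_TASKS = {"stop": _STOP, "hit": _HIT, "long_stop": _LONG_STOP}


def make_task(name: str) -> TaskSpec:
    """Return the named task configuration (``stop``, ``hit`` or ``long_stop``)."""
    try:
        return _TASKS[name]
    except KeyError:
        raise ValueError(f"unknown task {name!r}; expected one of {sorted(_TASKS)}") from None


def make_universal_task(weight: float = 0.5, duration: float | None = None) -> TaskSpec:
    """A single controller interpolated between the hit and stop cost sets.

    ``weight`` is the stop share of the blend (0.5 = arithmetic mean of the
    two weight vectors).  This is the generative embodiment of the
    universal-controller hypothesis: one feedback controller that, under a
    mixed presentation schedule, settles between the two task optima instead
    of switching.  Default duration is the mean of the two task durations.
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    stop, hit = _STOP, _HIT
    if duration is None:
        duration = 0.5 * (stop.duration + hit.duration)
    return TaskSpec(
        name="universal",
        target_distance=stop.target_distance,
        duration=duration,
        w_p=weight * stop.w_p + (1 - weight) * hit.w_p,
        w_v=weight * stop.w_v + (1 - weight) * hit.w_v,
        w_f=weight * stop.w_f + (1 - weight) * hit.w_f,
        activation_cost=stop.activation_cost,
    )


def activation_profile(task: TaskSpec, N: int, time_unit: str = "step") -> np.ndarray:
    """Per-step activation cost sequence ``R_t`` for ``t = 0..N-1``.

    Stationary tasks return a constant sequence.  For the long-stop ramp
    ``C(t) ∝ exp((p t + q) / r)``, normalised to ``mean(C) = 1`` so the
    total activation budget over the movement is preserved, ``t`` is by
    default the step index (the only reading that yields the intended
    gentle ramp; see the methods note).  ``time_unit`` may also be ``"ms"``
    (a steep ramp concentrated at the movement end) or ``"literal"``
    (``C ∝ exp(p t + q r)`` with t the step index, an explosive form kept
    for completeness).  The additive constant in the exponent cancels under
    normalisation in all readings.
    """
    R = task.activation_cost
    if task.activation_params is None:
        return np.full(N, R)
    p, q, r = task.activation_params
    t = np.arange(N, dtype=float)
    if time_unit == "step":
        expo = (p * t + q) / r
    elif time_unit == "ms":
        expo = (p * t * 1000.0 * _DT_DEFAULT + q) / r
    elif time_unit == "literal":
        expo = p * t + q * r
    else:
        raise ValueError("time_unit must be 'step', 'ms' or 'literal'")
    C = np.exp(expo - expo.max())  # subtract max for numerical stability
    C /= C.mean()
    return R * C


_DT_DEFAULT = 0.01


def task_cost_schedule(task: TaskSpec, dt: float = _DT_DEFAULT, n_dims: int = 2, time_unit: str = "step") -> CostSchedule:
    """Terminal-only cost schedule of a task at timestep ``dt``."""
    N = task.horizon(dt)
    return CostSchedule.terminal(
        horizon=N,
        w_p=task.w_p,
        w_v=task.w_v,
        w_f=task.w_f,
        r=activation_profile(task, N, time_unit=time_unit),
        target=task.target_distance,
        n_dims=n_dims,
    )


def task_controller(
    task: TaskSpec,
    model: StateSpaceModel | None = None,
    time_unit: str = "step",
) -> tuple[StateSpaceModel, ControllerGains, CostSchedule]:
    """Build the plant (if not given), the cost schedule and the LQR gains."""
    if model is None:
        model = build_point_mass_model()
    costs = task_cost_schedule(task, dt=model.dt, n_dims=model.n_dims, time_unit=time_unit)
    return model, solve_lqr(model, costs), costs
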