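"""Finite-horizon LQR for a planar point-mass reaching plant.

The plant is a unit point mass with intrinsic damping, driven per spatial
axis by a force actuator that low-pass filters the motor command with a
single time constant (a minimal muscle model).  Per axis the state is
``[position p, velocity v, force f]`` and the discrete dynamics are

    x_{t+1} = A x_t + B (u_t + xi_t)

with per-axis blocks

    A = [[1, dt,        0     ],          B = [0, 0, dt/tau]^T
         [0, 1 - b dt/m, dt/m ],
         [0, 0,          1 - dt/tau]]

For a two-dimensional plant the full matrices are block-diagonal over axes
with state ordering ``[p_x, v_x, f_x, p_y, v_y, f_y]`` (x lateral, y forward)
and one control per axis.  The controller minimises a quadratic performance
index with (by convention terminal-only) state costs on position error
relative to the target, velocity and force, plus a per-step activation cost
on the command, and is obtained by the backward Riccati recursion.  Gains
are expressed in target-relative coordinates, so they do not depend on the
target and a target jump is simply a step change of the reference series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StateSpaceModel",
    "CostSchedule",
    "ControllerGains",
    "Trajectory",
    "build_point_mass_model",
    "solve_lqr",
    "simulate",
]


@dataclass(frozen=True)
class StateSpaceModel:
    """Discrete-time point-mass plant with low-pass force actuators.

    Parameters are SI: mass ``m`` (kg), damping ``b`` (N s/m), actuator
    time constant ``tau`` (s), timestep ``dt`` (s).
    """

    m: float
    b: float
    tau: float
    dt: float
    n_dims: int
    A: np.ndarray = field(repr=False)
    B: np.ndarray = field(repr=False)

    @property
    def n_states(self) -> int:
        return 3 * self.n_dims

    @property
    def n_controls(self) -> int:
        return self.n_dims

    def position_indices(self) -> np.ndarray:
        return np.arange(self.n_dims) * 3

    def velocity_indices(self) -> np.ndarray:
        return np.arange(self.n_dims) * 3 + 1

    def force_indices(self) -> np.ndarray:
        return np.arange(self.n_dims) * 3 + 2


def build_point_mass_model(
    m: float = 1.0,
    b: float = 0.1,
    tau: float = 0.06,
    dt: float = 0.01,
    n_dims: int = 2,
) -> StateSpaceModel:
    """Build the discrete-time plant from physical parameters.

    Parameters
    ----------
    m, b, tau, dt
        Mass (kg), intrinsic damping (N s/m is tolerated as b >= 0),
        actuator time constant (s) and timestep (s).  ``m``, ``tau`` and
        ``dt`` must be strictly positive.
    n_dims
        Number of spatial dimensions (1 or 2).
    """
    if m <= 0 or tau <= 0 or dt <= 0:
        raise ValueError("m, tau and dt must be strictly positive")
    if b < 0:
        raise ValueError("damping b must be nonnegative")
    if n_dims not in (1, 2):
        raise ValueError("n_dims must be 1 or 2")
    A1 = np.array(
        [
            [1.0, dt, 0.0],
            [0.0, 1.0 - b * dt / m, dt / m],
            [0.0, 0.0, 1.0 - dt / tau],
        ]
    )
    B1 = np.array([[0.0], [0.0], [dt / tau]])
    A = np.kron(np.eye(n_dims), A1)
    B = np.kron(np.eye(n_dims), B1)
    return StateSpaceModel(m=m, b=b, tau=tau, dt=dt, n_dims=n_dims, A=A, B=B)


@dataclass
class CostSchedule:
    """Time-indexed quadratic costs for a finite-horizon regulator.

    ``w_p``, ``w_v``, ``w_f`` have shape ``(N + 1, n_dims)`` and weight the
    squared position error (relative to ``target``), velocity and force of
    each axis at each step; ``r`` has shape ``(N,)`` and weights the squared
    command at each step.  The terminal-only convention (all state weights
    zero except at ``t = N``) is produced by :meth:`terminal`.
    """

    horizon: int
    w_p: np.ndarray
    w_v: np.ndarray
    w_f: np.ndarray
    r: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        N = self.horizon
        if N < 1:
            raise ValueError("horizon must be at least 1")
        self.w_p = np.atleast_2d(np.asarray(self.w_p, dtype=float))
        self.w_v = np.atleast_2d(np.asarray(self.w_v, dtype=float))
        self.w_f = np.atleast_2d(np.asarray(self.w_f, dtype=float))
        self.r = np.asarray(self.r, dtype=float).reshape(-1)
        self.target = np.asarray(self.target, dtype=float).reshape(-1)
        for name, w in (("w_p", self.w_p), ("w_v", self.w_v), ("w_f", self.w_f)):
            if w.shape[0] != N + 1:
                raise ValueError(f"{name} must have N+1 = {N + 1} rows, got {w.shape[0]}")
            if np.any(w < 0):
                raise ValueError(f"{name} weights must be nonnegative")
        if self.r.shape[0] != N:
            raise ValueError(f"r must have N = {N} entries")
        if np.any(self.r <= 0):
            raise ValueError("activation cost r must be strictly positive")

    @property
    def n_dims(self) -> int:
        return self.w_p.shape[1]

    @classmethod
    def terminal(
        cls,
        horizon: int,
        w_p: float | np.ndarray,
        w_v: float | np.ndarray,
        w_f: float | np.ndarray,
        r: float | np.ndarray,
        target: float | np.ndarray,
        n_dims: int = 2,
    ) -> "CostSchedule":
        """Terminal-only state costs; scalar weights apply to every axis.

        ``target`` as a scalar is taken as the forward (last-axis) target
        distance with zero lateral target.
        """
        N = horizon

        def expand(w):
            w = np.asarray(w, dtype=float)
            if w.ndim == 0:
                w = np.full(n_dims, float(w))
            out = np.zeros((N + 1, n_dims))
            out[N] = w
            return out

        r_arr = np.asarray(r, dtype=float)
        if r_arr.ndim == 0:
            r_arr = np.full(N, float(r_arr))
        tgt = np.asarray(target, dtype=float)
        if tgt.ndim == 0:
            tgt = np.r_[np.zeros(n_dims - 1), float(tgt)]
        return cls(horizon=N, w_p=expand(w_p), w_v=expand(w_v), w_f=expand(w_f), r=r_arr, target=tgt)

    def state_weight_diag(self, t: int) -> np.ndarray:
        """Diagonal of Q_t in the interleaved state ordering."""
        d = np.empty(3 * self.n_dims)
        d[0::3] = self.w_p[t]
        d[1::3] = self.w_v[t]
        d[2::3] = self.w_f[t]
        return d


@dataclass
class ControllerGains:
    """Time-varying optimal gains L_t and the Riccati value matrices S_t."""

    L: np.ndarray  # (N, n_controls, n_states)
    S: np.ndarray  # (N + 1, n_states, n_states)

    @property
    def horizon(self) -> int:
        return self.L.shape[0]


def solve_lqr(model: StateSpaceModel, costs: CostSchedule) -> ControllerGains:
    """Solve the finite-horizon LQR by backward Riccati recursion.

    Returns the gain sequence ``L_t`` for ``t = 0..N-1`` together with the
    value matrices ``S_t``.  Gains depend only on ``A``, ``B`` and the cost
    weights, never on the target, because the recursion runs in
    target-relative coordinates.
    """
    if costs.n_dims != model.n_dims:
        raise ValueError("cost schedule dimensionality does not match the model")
    N = costs.horizon
    n, k = model.n_states, model.n_controls
    A, B = model.A, model.B
    S = np.empty((N + 1, n, n))
    L = np.empty((N, k, n))
    S[N] = np.diag(costs.state_weight_diag(N))
    for t in range(N - 1, -1, -1):
        St1 = S[t + 1]
        R = costs.r[t] * np.eye(k)
        G = R + B.T @ St1 @ B
        # R > 0 makes G positive definite; guard against degeneracy anyway.
        try:
            Lt = np.linalg.solve(G, B.T @ St1 @ A)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - unreachable for r > 0
            raise np.linalg.LinAlgError(
                f"singular control Hessian at step {t}; check activation costs"
            ) from exc
        Ad = A - B @ Lt
        St = np.diag(costs.state_weight_diag(t)) + Lt.T @ R @ Lt + Ad.T @ St1 @ Ad
        S[t] = 0.5 * (St + St.T)  # enforce symmetry against roundoff
        L[t] = Lt
    return ControllerGains(L=L, S=S)


@dataclass
class Trajectory:
    """Simulated state/control series of one movement.

    ``states`` has shape ``(N + 1, 3 * n_dims)``, ``controls`` shape
    ``(N, n_dims)``, ``reference`` shape ``(N + 1, n_dims)`` (target
    position per axis at each step) and ``cost`` is the realized value of
    the performance index along this trajectory.
    """

    time: np.ndarray
    states: np.ndarray
    controls: np.ndarray
    reference: np.ndarray
    cost: float
    dt: float

    @property
    def n_dims(self) -> int:
        return self.states.shape[1] // 3

    def position(self, axis: int) -> np.ndarray:
        return self.states[:, 3 * axis]

    def velocity(self, axis: int) -> np.ndarray:
        return self.states[:, 3 * axis + 1]

    def force(self, axis: int) -> np.ndarray:
        return self.states[:, 3 * axis + 2]

    # forward = last axis, lateral = first axis (identical in 1-D)
    def forward_position(self) -> np.ndarray:
        return self.position(self.n_dims - 1)

    def forward_velocity(self) -> np.ndarray:
        return self.velocity(self.n_dims - 1)

    def lateral_force(self) -> np.ndarray:
        return self.force(0)

    def to_frame(self):
        """Tidy tabular export (one row per sample; controls NaN-padded)."""
        import pandas as pd

        cols = {"t_s": self.time}
        ax_names = ["x", "y"] if self.n_dims == 2 else ["y"]
        for i, name in enumerate(ax_names):
            cols[f"p{name}_m"] = self.position(i)
            cols[f"v{name}_mps"] = self.velocity(i)
            cols[f"f{name}_N"] = self.force(i)
        for i, name in enumerate(ax_names):
            u = np.full(len(self.time), np.nan)
            u[:-1] = self.controls[:, i]
            cols[f"u{name}"] = u
            cols[f"ref_{name}_m"] = self.reference[:, i]
        return pd.DataFrame(cols)


def _reference_array(reference, N: int, n_dims: int) -> np.ndarray:
    ref = np.asarray(reference, dtype=float)
    if ref.ndim == 0:
        ref = np.r_[np.zeros(n_dims - 1), float(ref)]
    if ref.ndim == 1:
        ref = np.tile(ref, (N + 1, 1))
    if ref.shape[1] != n_dims:
        raise ValueError("reference must provide one target position per axis")
    if ref.shape[0] < N + 1:
        raise ValueError("reference series shorter than the simulation horizon")
    return ref[: N + 1]


def simulate(
    model: StateSpaceModel,
    gains: ControllerGains,
    x0: np.ndarray | None = None,
    reference: np.ndarray | float = 0.25,
    costs: CostSchedule | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    channel: bool = False,
) -> Trajectory:
    """Simulate the closed loop ``u_t = -L_t (x_t (-) ref_t)``.

    ``(-)`` subtracts the reference from the positional components of the
    state only; a target jump is represented as a step in ``reference``.
    ``noise_sd`` is the standard deviation of the additive i.i.d. Gaussian
    control noise per axis (default off: the model's predicted profiles are
    deterministic).  With ``channel=True`` the lateral (first-axis)
    position and velocity are clamped to zero after every transition,
    modelling an infinitely stiff mechanical channel, while the commanded
    lateral force state still evolves and is recorded.
    """
    N = gains.horizon
    n = model.n_states
    ref = _reference_array(reference, N, model.n_dims)
    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    if x.shape != (n,):
        raise ValueError(f"x0 must have shape ({n},)")
    if noise_sd and rng is None:
        rng = np.random.default_rng()
    pos_idx = model.position_indices()
    states = np.empty((N + 1, n))
    controls = np.empty((N, model.n_controls))
    states[0] = x
    ref_state = np.zeros(n)
    for t in range(N):
        ref_state[pos_idx] = ref[t]
        u = -gains.L[t] @ (x - ref_state)
        controls[t] = u
        w = rng.normal(0.0, noise_sd, size=model.n_controls) if noise_sd else 0.0
        x = model.A @ x + model.B @ (u + w)
        if channel and model.n_dims == 2:
            x[0] = 0.0
            x[1] = 0.0
        states[t + 1] = x
    cost = _realized_cost(states, controls, ref, costs, pos_idx)
    time = np.arange(N + 1) * model.dt
    return Trajectory(time=time, states=states, controls=controls, reference=ref, cost=cost, dt=model.dt)


def _realized_cost(states, controls, ref, costs: CostSchedule | None, pos_idx) -> float:
    if costs is None:
        return float("nan")
    N = costs.horizon
    err = states.copy()
    err[:, pos_idx] -= ref
    J = 0.0
    for t in range(N + 1):
        J += float(err[t] @ (costs.state_weight_diag(t) * err[t]))
    J += float(np.sum(costs.r * np.sum(controls**2, axis=1)))
    return J
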