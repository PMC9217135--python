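"""Unit and property tests of the plant, Riccati solver and simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ofcreach.lqr import CostSchedule, build_point_mass_model, simulate, solve_lqr
from ofcreach.tasks import make_task, task_controller


def test_plant_matrices_match_printed_form():
    m = build_point_mass_model(m=1.0, b=0.1, tau=0.06, dt=0.01, n_dims=2)
    A1 = np.array([[1, 0.01, 0], [0, 0.999, 0.01], [0, 0, 1 - 1 / 6]])
    B1 = np.array([[0], [0], [1 / 6]])
    assert np.allclose(m.A[:3, :3], A1)
    assert np.allclose(m.A[3:, 3:], A1)
    assert np.allclose(m.A[:3, 3:], 0) and np.allclose(m.A[3:, :3], 0)
    assert np.allclose(m.B[:3, 0], B1[:, 0]) and np.allclose(m.B[3:, 1], B1[:, 0])


def test_zero_damping_and_tau_equal_dt_degenerate_entries():
    m = build_point_mass_model(m=1.0, b=0.0, tau=0.01, dt=0.01, n_dims=1)
    assert m.A[1, 1] == 1.0  # no damping
    assert m.A[2, 2] == 0.0  # actuator settles in one step


@pytest.mark.parametrize("bad", [dict(m=0), dict(tau=0), dict(dt=-0.01), dict(b=-1), dict(n_dims=3)])
def test_invalid_plant_parameters_rejected(bad):
    with pytest.raises(ValueError):
        build_point_mass_model(**bad)


def test_fixed_control_iteration_matches_hand_rollout(model):
    """Three steps of A x + B u agree with a hand-written rollout."""
    rng = np.random.default_rng(0)
    x = rng.normal(size=6)
    us = rng.normal(size=(3, 2))
    x_hand = x.copy()
    for u in us:
        x_hand = model.A @ x_hand + model.B @ u
    x_mat = np.linalg.matrix_power(model.A, 3) @ x
    for k, u in enumerate(us):
        x_mat = x_mat + np.linalg.matrix_power(model.A, 2 - k) @ model.B @ u
    assert np.allclose(x_hand, x_mat, atol=1e-12)


def test_zero_state_cost_gives_zero_gains(model):
    costs = CostSchedule.terminal(horizon=10, w_p=0, w_v=0, w_f=0, r=1e-5, target=0.25)
    gains = solve_lqr(model, costs)
    assert np.allclose(gains.L, 0)


def test_one_step_scalar_gain_matches_closed_form_and_grid_search():
    m = build_point_mass_model(n_dims=1)
    q, r = 2.0, 1e-4
    costs = CostSchedule.terminal(horizon=1, w_p=q, w_v=0, w_f=0, r=r, target=0.0, n_dims=1)
    gains = solve_lqr(m, costs)
    A, B = m.A, m.B
    QN = np.diag([q, 0, 0])
    L_closed = np.linalg.solve(r + B.T @ QN @ B, B.T @ QN @ A)
    assert np.allclose(gains.L[0], L_closed, atol=1e-10)
    # grid-search oracle: minimise the 1-step cost for one concrete state
    x0 = np.array([0.3, -0.1, 0.05])
    us = np.linspace(-200, 200, 400001)
    x1 = np.outer(np.ones_like(us), A @ x0) + np.outer(us, B[:, 0])
    J = q * x1[:, 0] ** 2 + r * us**2
    u_star = us[np.argmin(J)]
    assert abs((-gains.L[0] @ x0).item() - u_star) < 1e-2  # grid resolution bound


def test_two_step_scalar_gains_match_hand_derived_recursion():
    m = build_point_mass_model(n_dims=1)
    q, r = 1.7, 3e-5
    costs = CostSchedule.terminal(horizon=2, w_p=q, w_v=0.4, w_f=0.02, r=r, target=0.0, n_dims=1)
    gains = solve_lqr(m, costs)
    A, B = m.A, m.B
    S2 = np.diag([q, 0.4, 0.02])
    L1 = np.linalg.solve(r + B.T @ S2 @ B, B.T @ S2 @ A)
    S1 = L1.T @ (r * np.eye(1)) @ L1 + (A - B @ L1).T @ S2 @ (A - B @ L1)
    L0 = np.linalg.solve(r + B.T @ S1 @ B, B.T @ S1 @ A)
    assert np.allclose(gains.L[1], L1, atol=1e-10)
    assert np.allclose(gains.L[0], L0, atol=1e-10)


def test_riccati_matrices_symmetric_positive_semidefinite():
    for name in ("stop", "hit", "long_stop"):
        _, gains, _ = task_controller(make_task(name))
        for S in gains.S:
            assert np.allclose(S, S.T, atol=1e-12)
            eig = np.linalg.eigvalsh(S)
            assert eig.min() > -1e-10


def test_gains_do_not_depend_on_target(model):
    c1 = CostSchedule.terminal(horizon=30, w_p=1.5, w_v=1, w_f=0.1, r=3e-6, target=0.25)
    c2 = CostSchedule.terminal(horizon=30, w_p=1.5, w_v=1, w_f=0.1, r=3e-6, target=0.4)
    assert np.allclose(solve_lqr(model, c1).L, solve_lqr(model, c2).L)


def test_rest_on_reference_stays_at_rest(model):
    task = make_task("stop")
    _, gains, costs = task_controller(task)
    x0 = np.array([0.0, 0, 0, costs.target[1], 0, 0])  # at the target, at rest
    traj = simulate(model, gains, x0=x0, reference=costs.target)
    assert np.allclose(traj.controls, 0, atol=1e-12)
    assert np.allclose(traj.states, x0, atol=1e-12)


def test_lqr_beats_randomly_perturbed_control_sequences(model):
    """Random-restart optimality oracle: no perturbed open-loop sequence
    achieves a lower realized cost than the LQR trajectory."""
    task = make_task("stop")
    _, gains, costs = task_controller(task)
    traj = simulate(model, gains, reference=costs.target, costs=costs)
    rng = np.random.default_rng(42)
    ref_state = np.zeros(6)
    ref_state[[0, 3]] = costs.target
    for _ in range(100):
        us = traj.controls + rng.normal(0, 0.5, size=traj.controls.shape)
        x = np.zeros(6)
        J = 0.0
        for t in range(costs.horizon):
            J += costs.r[t] * float(us[t] @ us[t])
            x = model.A @ x + model.B @ us[t]
        err = x - ref_state
        J += float(err @ (costs.state_weight_diag(costs.horizon) * err))
        assert J >= traj.cost - 1e-12


def test_stop_and_hit_terminal_speeds(model):
    for name, check in (("stop", lambda v: v < 0.01), ("hit", lambda v: v > 0.05)):
        _, gains, costs = task_controller(make_task(name))
        traj = simulate(model, gains, reference=costs.target)
        assert check(abs(traj.forward_velocity()[-1]))


def test_certainty_equivalence_mean_converges_to_deterministic(model):
    task = make_task("stop")
    _, gains, costs = task_controller(task)
    det = simulate(model, gains, reference=costs.target).states
    rng = np.random.default_rng(3)
    sd = 0.5

    def mean_dev(n):
        acc = np.zeros_like(det)
        for _ in range(n):
            acc += simulate(model, gains, reference=costs.target, noise_sd=sd, rng=rng).states
        return np.max(np.abs(acc / n - det))

    d20, d200 = mean_dev(20), mean_dev(200)
    # deviation shrinks roughly as 1/sqrt(n): a factor ~3 from 20 to 200
    assert d200 < 0.6 * d20
    # and the n=200 mean is close to the deterministic path on the force
    # scale the sd=0.5 N control noise sets
    assert d200 < 0.05


def test_jump_response_is_linear_in_jump_size(model):
    """Doubling the target jump doubles the perturbed-minus-unperturbed
    response, to numerical precision."""
    task = make_task("stop")
    _, gains, costs = task_controller(task)
    base = simulate(model, gains, reference=costs.target)
    N = costs.horizon

    def jump_traj(size):
        ref = np.tile(costs.target, (N + 1, 1))
        ref[30:, 0] += size
        return simulate(model, gains, reference=ref)

    d1 = jump_traj(0.01).states - base.states
    d2 = jump_traj(0.02).states - base.states
    assert np.allclose(d2, 2 * d1, rtol=1e-9, atol=1e-14)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    wp=st.floats(0.1, 10), wv=st.floats(0, 2), wf=st.floats(0, 1),
    r=st.floats(1e-7, 1e-3), N=st.integers(2, 40),
)
def test_riccati_psd_property(wp, wv, wf, r, N):
    m = build_point_mass_model(n_dims=1)
    costs = CostSchedule.terminal(horizon=N, w_p=wp, w_v=wv, w_f=wf, r=r, target=0.1, n_dims=1)
    gains = solve_lqr(m, costs)
    for S in gains.S:
        assert np.allclose(S, S.T, atol=1e-10)
        assert np.linalg.eigvalsh(S).min() > -1e-9


def test_trajectory_export_columns(model):
    _, gains, costs = task_controller(make_task("stop"))
    traj = simulate(model, gains, reference=costs.target)
    df = traj.to_frame()
    assert list(df.columns) == [
        "t_s", "px_m", "vx_mps", "fx_N", "py_m", "vy_mps", "fy_N",
        "ux", "ref_x_m", "uy", "ref_y_m",
    ]
    assert len(df) == costs.horizon + 1
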