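"""SVD-space reduction, specialization coordinates, and the closed-form
symmetric adaptation solution."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from taskgates import (Curriculum, DomainError, ModelState, ReducedState,
                       block_adaptation, exact_symmetric_solution,
                       gate_decomposition, init_state, integrate,
                       integrate_reduced, make_teachers, project, reduced_rhs,
                       specialization_rhs, specialized_state,
                       symmetric_adaptation)
from taskgates.errors import InvalidConfigurationError


# ---------------------------------------------------------------- projection

def _rank1_teachers(seed=3):
    return make_teachers(2, 8, 1, seed=seed)


def test_project_specialized_identity_and_degenerate_cases():
    ts = _rank1_teachers()
    u = [ts.svd(m)[0][0, 0] for m in range(2)]
    v = [ts.svd(m)[2][0] for m in range(2)]
    # students built exactly on the teacher singular directions
    students = np.stack([(u[p] * 1.0) * v[p][None, :] for p in range(2)])
    s = ModelState(students=students, gates=np.array([1.0, 0.0]))
    rs = project(s, ts)
    assert np.allclose(rs.w, np.eye(2), atol=1e-12)
    assert rs.coords[2] == pytest.approx(1.0)  # wbar
    # identical students: all specialization coordinates vanish
    same = ModelState(students=np.stack([students[0], students[0]]),
                      gates=np.array([0.5, 0.5]))
    w1, w2, wbar, _ = project(same, ts).coords
    assert w1 == w2 == wbar == 0.0
    zero = ModelState(students=np.zeros((2, 1, 8)), gates=np.array([0.5, 0.5]))
    assert np.allclose(project(zero, ts).w, 0.0)


def test_project_requires_two_teachers():
    ts = make_teachers(3, 16, 1, seed=0)
    s = init_state(2, 16, 1, seed=0)
    with pytest.raises(InvalidConfigurationError):
        project(s, ts)


# ------------------------------------------------------------- reduced RHS

def test_reduced_rhs_fixed_point_and_switch_signs():
    # perfect output with gates at the L1 regularization optimum: no motion
    rs = specialized_state()
    dw, dc = reduced_rhs(rs, target=0)
    assert np.allclose(dw, 0.0) and np.allclose(dc, 0.0, atol=1e-12)
    # immediately after a switch the wrong path's gate closes, the right
    # path's gate opens
    dw, dc = reduced_rhs(rs, target=1)
    assert dc[0] < 0 and dc[1] > 0


def test_gate_decomposition_is_an_exact_identity(rng):
    tau_c = 0.21
    for _ in range(100):
        rs = ReducedState(w=rng.normal(size=(2, 2)),
                          c=rng.normal(size=2), target=int(rng.integers(2)))
        t1, t2, reg = gate_decomposition(rs, lambda_norm=0.8, lambda_nonneg=0.3)
        _, dc = reduced_rhs(rs, rs.target, lambda_norm=0.8, lambda_nonneg=0.3,
                            tau_c=tau_c)
        assert np.allclose(t1 + t2 + reg, tau_c * dc, atol=1e-12)


def test_gate_decomposition_attenuated_by_small_students():
    rs = ReducedState(w=np.zeros((2, 2)), c=np.array([0.5, 0.5]), target=0)
    t1, t2, _ = gate_decomposition(rs)
    assert np.allclose(t1, 0.0) and np.allclose(t2, 0.0)
    # at fixed error, the drive terms are linear in the student projections:
    # term_m equals eps_m * w^p_m exactly
    rng = np.random.default_rng(8)
    rs = ReducedState(w=rng.normal(size=(2, 2)), c=rng.normal(size=2), target=1)
    eps = rs.error()
    t1, t2, _ = gate_decomposition(rs)
    assert np.allclose(t1, eps[0] * rs.w[:, 0], atol=1e-14)
    assert np.allclose(t2, eps[1] * rs.w[:, 1], atol=1e-14)


def test_specialization_rhs_zero_cases():
    # no gate separation -> no specialization drift
    rs = ReducedState(w=np.array([[0.6, 0.1], [0.1, 0.6]]),
                      c=np.array([0.5, 0.5]), target=0)
    dwbar, _ = specialization_rhs(rs)
    assert dwbar == pytest.approx(0.0)
    # unspecialized students -> no gate separation drift
    rs2 = ReducedState(w=np.array([[0.3, 0.3], [0.3, 0.3]]),
                       c=np.array([0.9, 0.1]), target=0)
    _, dcbar = specialization_rhs(rs2)
    assert dcbar == pytest.approx(0.0)


def test_specialization_rhs_consistent_with_euler_trajectory():
    """Forward differences of (wbar, cbar) along an integrated reduced
    trajectory equal the specialization drift while both gates stay
    positive (the L1 pull cancels path-wise)."""
    tau_w, tau_c = 1.0, 0.2
    tr = integrate_reduced(specialized_state(), target=1, horizon=0.3,
                           tau_w=tau_w, tau_c=tau_c, lambda_norm=1.0,
                           lambda_nonneg=1.0, dt=tau_c / 100, record_every=1)
    dt = tr.times[1] - tr.times[0]
    assert np.all(tr.c > -1e-12)
    for i in range(0, len(tr) - 1, 7):
        rs = ReducedState(tr.w[i], tr.c[i], target=1)
        dwbar, dcbar = specialization_rhs(rs, tau_w=tau_w, tau_c=tau_c)
        fd_w = (tr.wbar[i + 1] - tr.wbar[i]) / dt
        fd_c = (tr.cbar[i + 1] - tr.cbar[i]) / dt
        assert fd_w == pytest.approx(dwbar, abs=1e-6)
        assert fd_c == pytest.approx(dcbar, abs=1e-6)


# ----------------------------------------------------- closed-form solution

def test_exact_symmetric_solution_anchors():
    for ratio in (0.05, 0.5, 1.0, 2.0):
        assert exact_symmetric_solution(1.0, ratio, 1.0) == pytest.approx(1.0)
        assert exact_symmetric_solution(-1.0, ratio, 1.0) == pytest.approx(1.0)
    # frozen oracle: integrating the separable ODE
    # (tau_c/tau_w) dcbar/dwbar = 2 wbar / cbar from (1, 1) down to cbar = 0
    # at tau_c = tau_w gives wbar = sqrt(1/2)
    assert exact_symmetric_solution(0.0, 1.0, 1.0) == pytest.approx(
        0.70710678, abs=1e-6)


def test_exact_symmetric_solution_against_ode_oracle():
    # independent oracle: integrate dwbar/dcbar = (tau_c/(2 tau_w)) cbar/wbar
    tau_c, tau_w = 0.7, 1.1
    sol = solve_ivp(
        lambda cb, wb: (tau_c / (2 * tau_w)) * cb / wb,
        (1.0, -1.0), [1.0], t_eval=np.linspace(1.0, -1.0, 41),
        rtol=1e-11, atol=1e-13)
    pred = exact_symmetric_solution(sol.t, tau_c, tau_w)
    assert np.max(np.abs(sol.y[0] - pred)) < 1e-8


def test_exact_symmetric_solution_even_monotone_and_domain():
    cb = np.linspace(0, 1, 50)
    w = exact_symmetric_solution(cb, 0.9, 1.0)
    assert np.all(np.diff(w) >= 0)
    assert np.allclose(w, exact_symmetric_solution(-cb, 0.9, 1.0))
    with pytest.raises(DomainError):
        exact_symmetric_solution(1.5, 1.0, 1.0)
    with pytest.raises(DomainError):
        # tau_c/tau_w = 4 loses specialization at cbar = 0
        exact_symmetric_solution(0.0, 4.0, 1.0)


# ------------------------------------------------------- block adaptation

@pytest.mark.parametrize("tau_c", [0.1, 0.18, 0.32, 0.56, 1.00])
def test_block_adaptation_reaches_low_loss_and_tracks_closed_form(tau_c):
    traj = block_adaptation(tau_c=tau_c, tau_w=1.0)
    assert traj.task_loss[-1] < 1e-2
    pred = exact_symmetric_solution(traj.cbar, tau_c, 1.0)
    assert np.max(np.abs(traj.wbar - pred)) < 0.02
    # strong-L1 setting: total gate activity pinned to 1
    assert np.max(np.abs(traj.c.sum(axis=1) - 1.0)) < 1e-3


def test_block_adaptation_protection_limit():
    # tau_c/tau_w -> 0: the gates do all the switching, weights barely move
    traj = block_adaptation(tau_c=1e-3, tau_w=1.0, horizon=0.05)
    assert traj.wbar.min() > 0.999
    assert traj.cbar[-1] < -0.9


def test_symmetric_invariant_is_conserved():
    tau_c, tau_w = 0.5, 1.3
    tr = symmetric_adaptation(tau_c, tau_w)
    inv = tr.wbar**2 - (tau_c / (2 * tau_w)) * tr.cbar**2
    assert np.max(np.abs(inv - inv[0])) < 1e-6


# --------------------------------------------- exactness vs the full model

def test_full_model_projection_matches_reduced_trajectory():
    """Expectation-mode full dynamics, projected onto the teacher modes,
    coincide with the reduced dynamics when the students start inside the
    teacher subspace (same Euler discretization on both sides)."""
    ts = _rank1_teachers()
    u = [ts.svd(m)[0][0, 0] for m in range(2)]
    v = [ts.svd(m)[2][0] for m in range(2)]
    rng = np.random.default_rng(11)
    w0 = rng.normal(scale=0.01, size=(2, 2))
    students = np.stack([
        (u[0] * w0[p, 0]) * v[0][None, :] + (u[1] * w0[p, 1]) * v[1][None, :]
        for p in range(2)])
    tau_c, tau_w = 0.05, 1.3
    dt = tau_c / 50
    state = ModelState(students=students, gates=np.array([0.5, 0.5]),
                       tau_c=tau_c, tau_w=tau_w)
    curr = Curriculum(block_length=1.0, n_blocks=5)
    traj = integrate(state, ts, curr, dt=dt, record_every=5,
                     record_reduced=True)

    rs = project(state, ts)
    ws, cs = [], []
    for b in range(5):
        tr = integrate_reduced(rs, target=b % 2, horizon=1.0, tau_w=tau_w,
                               tau_c=tau_c, dt=dt, record_every=5)
        keep = slice(None, -1) if b < 4 else slice(None)
        ws.append(tr.w[keep])
        cs.append(tr.c[keep])
        rs = ReducedState(tr.w[-1], tr.c[-1])
    w_red = np.concatenate(ws)
    c_red = np.concatenate(cs)
    assert traj.reduced["w"].shape[0] == w_red.shape[0]
    assert np.max(np.abs(traj.reduced["w"][:, 0] - w_red)) < 1e-6
    assert np.max(np.abs(traj.gates - c_red)) < 1e-6
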