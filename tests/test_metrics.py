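"""Alignment measures, criterion timing, regime classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taskgates import (InsufficientDataError, ModelState, alignment,
                       classify_regime, init_state, make_teachers,
                       switch_speed_trend, time_to_criterion, total_alignment)
from taskgates.dynamics import Trajectory
from taskgates.errors import DomainError


def _traj(times, loss, block_length, final_state):
    times = np.asarray(times, float)
    blocks = np.minimum((times / block_length).astype(int),
                        int(times[-1] / block_length - 1e-9))
    T = len(times)
    return Trajectory(
        times=times, task_loss=np.asarray(loss, float),
        gates=np.zeros((T, 2)), alignments=np.zeros((T, 2, 2)),
        update_norms=np.zeros((T, 2)), student_norms=np.zeros((T, 2)),
        block_index=blocks, block_length=block_length, final_state=final_state)


def test_alignment_exact_cases():
    t = np.random.default_rng(0).standard_normal((4, 8))
    assert alignment(t, t) == pytest.approx(1.0)
    assert alignment(-t, t) == pytest.approx(-1.0)
    # rows orthogonal to the teacher rows
    ts = make_teachers(2, 16, 4, seed=1)
    assert alignment(ts.teachers[0], ts.teachers[1]) == pytest.approx(0.0, abs=1e-10)


def test_alignment_zero_row_contributes_zero_with_warning():
    t = np.ones((2, 3))
    s = np.array([[1.0, 1.0, 1.0], [0.0, 0.0, 0.0]])
    with pytest.warns(UserWarning):
        assert alignment(s, t) == pytest.approx(0.5)


@settings(max_examples=25, derandomize=True)
@given(a=st.floats(0.01, 100), b=st.floats(0.01, 100),
       sa=st.sampled_from([-1.0, 1.0]), sb=st.sampled_from([-1.0, 1.0]))
def test_alignment_scale_invariance(a, b, sa, sb):
    rng = np.random.default_rng(7)
    s = rng.standard_normal((3, 6))
    t = rng.standard_normal((3, 6))
    base = alignment(s, t)
    scaled = alignment(sa * a * s, sb * b * t)
    assert scaled == pytest.approx(sa * sb * base, rel=1e-9, abs=1e-12)


def test_total_alignment_matching_and_collapse():
    ts = make_teachers(2, 32, 4, seed=2)
    a, b = ts.teachers
    # swapped students: matching restores perfect alignment
    assert total_alignment(np.stack([b, a]), ts) == pytest.approx(1.0)
    # collapse onto one teacher stays strictly below 1
    assert total_alignment(np.stack([a, a]), ts) < 1.0 - 1e-6
    # positive scalar multiples are still perfect
    assert total_alignment(np.stack([2 * b, 0.3 * a]), ts) < 1.0
    assert total_alignment(np.stack([2 * a, 2 * b]), ts) == pytest.approx(1.0)


def test_total_alignment_small_initialization_near_zero():
    ts = make_teachers(2, 32, 8, seed=0)
    s = init_state(2, 32, 8, seed=0)
    assert abs(total_alignment(s.students, ts)) < 0.1


def test_total_alignment_path_permutation_invariant():
    ts = make_teachers(3, 32, 4, seed=3)
    rng = np.random.default_rng(4)
    students = rng.standard_normal((3, 4, 32))
    v = total_alignment(students, ts)
    assert total_alignment(students[::-1].copy(), ts) == pytest.approx(v)


def test_total_alignment_unequal_path_and_task_counts():
    ts = make_teachers(3, 32, 4, seed=5)
    # two students matching two of three teachers: injective matching
    students = ts.teachers[[2, 0]]
    assert total_alignment(students, ts) == pytest.approx(1.0)


def _dummy_state():
    return init_state(2, 8, 2, seed=0)


def test_time_to_criterion_examples():
    fs = _dummy_state()
    times = np.arange(0, 4.0, 0.01)
    always = _traj(times, np.full(len(times), 0.05), 1.0, fs)
    assert np.allclose(time_to_criterion(always, 0.1), 0.0)
    never = _traj(times, np.full(len(times), 5.0), 1.0, fs)
    assert np.allclose(time_to_criterion(never, 0.1), 1.0)  # sentinel
    # exponential decay restarting at each block: crossing at ln(10)
    tb = 4.0
    times = np.arange(0, tb, 0.001)
    decay = _traj(times, np.exp(-times), tb, fs)
    assert time_to_criterion(decay, 0.1)[0] == pytest.approx(np.log(10), abs=0.002)


def test_time_to_criterion_monotone_under_lower_loss():
    fs = _dummy_state()
    times = np.arange(0, 3.0, 0.01)
    loss = np.exp(-times % 1.0 * 3)
    hi = _traj(times, loss, 1.0, fs)
    lo = _traj(times, 0.5 * loss, 1.0, fs)
    assert np.all(time_to_criterion(lo, 0.1) <= time_to_criterion(hi, 0.1))


def test_classify_regime_on_hand_built_trajectory():
    ts = make_teachers(2, 32, 4, seed=6)
    perfect = ModelState(students=ts.teachers.copy(),
                         gates=np.array([1.0, 0.0]))
    times = np.arange(0, 8.0, 0.01)
    # criterion times shrink with every block
    loss = np.exp(-(times % 1.0) * (1 + times.astype(int)))
    traj = _traj(times, loss, 1.0, perfect)
    assert classify_regime(traj, ts) == "flexible"
    with pytest.raises(InsufficientDataError):
        classify_regime(_traj(np.arange(0, 2.0, 0.01), np.ones(200), 1.0,
                              perfect), ts)


def test_classify_regime_on_simulated_runs(flexible_run, forgetful_run,
                                           teachers_2x8):
    assert classify_regime(flexible_run, teachers_2x8) == "flexible"
    assert classify_regime(forgetful_run, teachers_2x8) == "forgetful"


def test_switch_speed_trend_constant_loss_is_flat():
    fs = _dummy_state()
    times = np.arange(0, 10.0, 0.01)
    traj = _traj(times, np.ones(len(times)), 1.0, fs)
    slope, sign = switch_speed_trend(traj)
    assert slope == 0.0 and sign == 0.0


def test_switch_speed_trend_needs_enough_blocks():
    fs = _dummy_state()
    times = np.arange(0, 0.9, 0.01)
    with pytest.raises(InsufficientDataError):
        switch_speed_trend(_traj(times, np.ones(len(times)), 1.0, fs))


def test_total_alignment_empty_raises():
    ts = make_teachers(2, 16, 2, seed=0)
    with pytest.raises(DomainError):
        total_alignment(np.empty((0, 2, 16)), ts)
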