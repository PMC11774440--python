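"""Two-layer fully-connected linear network with layer-wise timescales.

The explicitly gated architecture is a special case of a deep linear
network ``y = W2 W1 x``.  Mirroring the gate constraints, the second layer
gets a faster timescale (``tau_2 < tau_1``) and the gate regularizers are
applied to its rows (L1-normalization plus a nonnegativity hinge on the
entries).  Under blocked training this is sufficient for the first layer to
form task-specialized sub-students and the second layer to implement an
emergent gating readout; without the constraints the network stays
forgetful.

``sort_network`` recovers the emergent structure: each hidden unit is
assigned to the teacher whose rows it matches best (by absolute cosine of
its ``W1`` row), rows of ``W1`` and columns of ``W2`` are permuted
accordingly, and the mean of each sorted student's ``W2`` block is reported
as that student's effective gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .curriculum import Curriculum, TeacherSet
from .errors import (DimensionError, InstabilityError,
                     InvalidConfigurationError)

__all__ = ["DeepLinearState", "SortingResult", "DeepTrajectory",
           "init_deep_state", "deep_forward", "deep_integrate", "sort_network"]

LOSS_GUARD = 1e6


@dataclass
class DeepLinearState:
    """First layer ``W1`` (hidden x din), second layer ``W2`` (dout x hidden),
    per-layer time constants ``tau_2 < tau_1``, and gate-style regularization
    weights acting on ``W2``."""

    W1: np.ndarray
    W2: np.ndarray
    tau_1: float = 1.3
    tau_2: float = 0.03
    lambda_norm: float = 1.0
    lambda_nonneg: float = 1.0

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float)
        if self.W1.ndim != 2 or self.W2.ndim != 2:
            raise DimensionError("W1 and W2 must be matrices")
        if self.W2.shape[1] != self.W1.shape[0]:
            raise DimensionError(
                f"hidden sizes disagree: W1 {self.W1.shape} vs W2 {self.W2.shape}"
            )
        if self.tau_1 <= 0 or self.tau_2 <= 0:
            raise InvalidConfigurationError("timescales must be positive")

    @property
    def hidden(self) -> int:
        return self.W1.shape[0]

    @property
    def din(self) -> int:
        return self.W1.shape[1]

    @property
    def dout(self) -> int:
        return self.W2.shape[0]

    def copy(self) -> "DeepLinearState":
        return replace(self, W1=self.W1.copy(), W2=self.W2.copy())


@dataclass
class SortingResult:
    """Hidden-unit-to-teacher assignment and the correspondingly permuted
    layers; ``gates[m]`` is the mean of sorted student m's second-layer
    block."""

    assignment: np.ndarray  # (hidden,) teacher index per hidden unit
    permutation: np.ndarray  # hidden-unit order applied to W1 rows / W2 cols
    sorted_W1: np.ndarray
    sorted_W2: np.ndarray
    gates: np.ndarray  # (M,)


@dataclass
class DeepTrajectory:
    """Loss and layer-wise update norms over a deep-linear run."""

    times: np.ndarray
    task_loss: np.ndarray
    update_norms: np.ndarray  # (T, 2): (||dW1/dt||_F, ||dW2/dt||_F)
    block_index: np.ndarray
    block_length: float
    final_state: DeepLinearState
    snapshots: dict = field(default_factory=dict)  # block -> end-of-block state
    meta: dict = field(default_factory=dict)


def init_deep_state(
    din: int,
    dout: int,
    hidden: int | None = None,
    M: int = 2,
    seed: int = 0,
    sigma: float = 0.01,
    **hyper,
) -> DeepLinearState:
    """Small random initialization; hidden width defaults to ``M * dout`` so
    there is room for one specialized sub-student per task."""
    if hidden is None:
        hidden = M * dout
    if hidden < M * dout:
        raise InvalidConfigurationError(
            f"hidden={hidden} leaves no room for {M} specialized sub-students "
            f"of {dout} rows each"
        )
    rng = np.random.default_rng(seed)
    W1 = rng.standard_normal((hidden, din)) * (sigma / np.sqrt(din))
    W2 = rng.standard_normal((dout, hidden)) * (sigma / np.sqrt(hidden))
    return DeepLinearState(W1=W1, W2=W2, **hyper)


def deep_forward(state: DeepLinearState, x: np.ndarray) -> np.ndarray:
    """``y = W2 (W1 x)`` for a single input or a batch ``(n, din)``."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != state.din:
        raise DimensionError(f"input has {x.shape[-1]} features, expected {state.din}")
    return x @ (state.W2 @ state.W1).T


def _deep_gradients(state: DeepLinearState, teacher: np.ndarray):
    err = teacher - state.W2 @ state.W1  # (dout, din)
    dW1 = -state.W2.T @ err
    dW2 = -err @ state.W1.T
    # Gate-style regularization on the second layer, per output row.
    row_l1 = np.sum(np.abs(state.W2), axis=1, keepdims=True)
    g_norm = (row_l1 - 1.0) * np.sign(state.W2)
    g_nonneg = np.where(state.W2 < 0, -1.0, 0.0)
    dW2 = dW2 + state.lambda_norm * g_norm + state.lambda_nonneg * g_nonneg
    return dW1, dW2, 0.5 * float(np.sum(err**2))


def deep_integrate(
    state: DeepLinearState,
    teachers: TeacherSet,
    curriculum: Curriculum,
    dt: float | None = None,
    record_every: int = 10,
    snapshot_blocks: bool = False,
) -> DeepTrajectory:
    """Euler gradient flow with layer timescales over the blocked curriculum
    (expectation mode).  With ``snapshot_blocks=True`` the state at the end
    of every block is kept for sorting analyses."""
    if dt is None:
        dt = state.tau_2 / 50.0
    if dt <= 0 or dt > state.tau_2 / 10:
        raise InvalidConfigurationError(
            f"dt={dt} must be positive and <= tau_2/10 = {state.tau_2 / 10}"
        )
    order = curriculum.resolved_order(teachers.M)
    tau_b = curriculum.block_length
    n_steps = int(round(curriculum.total_time / dt))
    state = state.copy()

    ts, losses, upds, blocks = [], [], [], []
    snapshots: dict[int, DeepLinearState] = {}
    prev_block = 0
    for step in range(n_steps + 1):
        t = step * dt
        block = min(int(t / tau_b), max(curriculum.n_blocks - 1, 0))
        if snapshot_blocks and block != prev_block:
            snapshots[prev_block] = state.copy()
            prev_block = block
        task = order[block % len(order)]
        dW1, dW2, loss = _deep_gradients(state, teachers.teachers[task])
        if step % record_every == 0 or step == n_steps:
            if not np.isfinite(loss) or loss > LOSS_GUARD:
                raise InstabilityError(
                    f"loss {loss:.3g} diverged at t={t:.4g}; reduce dt={dt}"
                )
            ts.append(t)
            losses.append(loss)
            upds.append((np.linalg.norm(dW1) / state.tau_1,
                         np.linalg.norm(dW2) / state.tau_2))
            blocks.append(block)
        if step == n_steps:
            break
        state.W1 -= (dt / state.tau_1) * dW1
        state.W2 -= (dt / state.tau_2) * dW2
    if snapshot_blocks:
        snapshots[prev_block] = state.copy()

    return DeepTrajectory(
        times=np.array(ts), task_loss=np.array(losses),
        update_norms=np.array(upds), block_index=np.array(blocks, dtype=int),
        block_length=tau_b, final_state=state, snapshots=snapshots,
        meta={"dt": dt, "record_every": record_every},
    )


def sort_network(state: DeepLinearState, teachers: TeacherSet) -> SortingResult:
    """Assign each hidden unit to its best-matching teacher and permute the
    network into contiguous emergent students.

    Assignment maximizes ``|cos(W1 row, teacher row)|`` over all teacher
    rows (ties broken towards the lowest teacher index); the same hidden
    permutation is applied to ``W1`` rows and ``W2`` columns, so the
    input-output map is unchanged.
    """
    M = teachers.M
    rows = teachers.stacked()  # (M*dout, din)
    row_norms = np.linalg.norm(rows, axis=1)
    w1_norms = np.linalg.norm(state.W1, axis=1)
    denom = np.outer(np.where(w1_norms == 0, 1.0, w1_norms),
                     np.where(row_norms == 0, 1.0, row_norms))
    cos = (state.W1 @ rows.T) / denom  # (hidden, M*dout)
    cos[w1_norms == 0, :] = 0.0
    best_per_teacher = np.max(
        np.abs(cos).reshape(state.hidden, M, teachers.dout), axis=2
    )  # (hidden, M)
    assignment = np.argmax(best_per_teacher, axis=1)  # argmax -> lowest index ties

    permutation = np.argsort(assignment, kind="stable")
    sorted_W1 = state.W1[permutation]
    sorted_W2 = state.W2[:, permutation]
    sorted_assignment = assignment[permutation]
    gates = np.array([
        float(np.mean(sorted_W2[:, sorted_assignment == m]))
        if np.any(sorted_assignment == m) else 0.0
        for m in range(M)
    ])
    return SortingResult(
        assignment=assignment, permutation=permutation,
        sorted_W1=sorted_W1, sorted_W2=sorted_W2, gates=gates,
    )
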