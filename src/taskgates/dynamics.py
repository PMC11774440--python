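"""Gradient-flow integration of weights and gates over a blocked curriculum.

Gradient descent with small learning rates is treated as a continuous-time
flow with separate time constants::

    tau_w dW_p/dt = -grad_{W_p} L,    tau_c dc_p/dt = -grad_{c_p} L

discretized by explicit Euler steps of size ``dt`` (default ``tau_c / 50``,
guarded at ``tau_c / 10``).  The active teacher changes every
``block_length`` time units according to the curriculum.  In expectation
mode the gradients are the closed-form population gradients and the
trajectory is fully deterministic; in minibatch mode fresh Gaussian batches
are drawn each step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import metrics
from .curriculum import Curriculum, TeacherSet, sample_batch
from .errors import InstabilityError, InvalidConfigurationError
from .model import ModelState, expected_task_loss, reg_gradient

__all__ = ["Trajectory", "integrate", "forgetful_baseline"]

LOSS_GUARD = 1e6  # divergence sentinel
DT_FRACTION = 50  # default dt = tau_c / DT_FRACTION


@dataclass
class Trajectory:
    """Time-indexed record of a run.

    All series share the leading time axis; ``times`` are uniformly spaced by
    ``record_every * dt``.  ``final_state`` holds the model at the end of the
    run (used by regime classification).
    """

    times: np.ndarray
    task_loss: np.ndarray
    gates: np.ndarray
    alignments: np.ndarray  # (T, P, M)
    update_norms: np.ndarray  # (T, 2): (||dW/dt||_F, ||dc/dt||)
    student_norms: np.ndarray  # (T, P)
    block_index: np.ndarray
    block_length: float
    final_state: ModelState
    meta: dict = field(default_factory=dict)
    reduced: Optional[dict] = None

    def __len__(self) -> int:
        return len(self.times)


def forgetful_baseline(state: ModelState) -> ModelState:
    """The matched forgetful control: same model with ``tau_c = tau_w`` and
    both regularizers switched off.  Idempotent; weights and gates are
    untouched."""
    out = state.copy()
    return replace(out, tau_c=out.tau_w, lambda_norm=0.0, lambda_nonneg=0.0)


def _step_gradients(state: ModelState, teacher: np.ndarray,
                    batch: tuple | None) -> tuple[np.ndarray, np.ndarray]:
    """Total-loss gradients (dW, dc) on the fast path used by the
    integrator."""
    W, c = state.students, state.gates
    if batch is None:
        err = teacher - np.einsum("pi,pij->ij", state.gate_matrix(), W)
        if state.gate_granularity == "scalar":
            dW = -c[:, None, None] * err
            dc_task = -np.tensordot(W, err, axes=([1, 2], [0, 1]))
        else:
            dW = -c[:, :, None] * err
            dc_task = -np.sum(W * err, axis=2)
    else:
        from .model import gradients  # minibatch path shares the library code

        gp = gradients(state, teacher, mode="minibatch", batch=batch)
        return gp.dW, gp.dc
    g_norm, g_nonneg = reg_gradient(c, state.norm_order)
    dc = dc_task + state.lambda_norm * g_norm + state.lambda_nonneg * g_nonneg
    return dW, dc


def integrate(
    state: ModelState,
    teachers: TeacherSet,
    curriculum: Curriculum,
    dt: float | None = None,
    record_every: int = 10,
    record_reduced: bool = False,
) -> Trajectory:
    """Integrate the coupled weight/gate flow over the blocked curriculum.

    The recorded ``task_loss`` is always the closed-form expected loss for
    the currently active teacher, so criterion timing is free of sampling
    jitter even in minibatch mode.  With ``record_reduced=True`` (two
    orthogonal teachers, scalar gates) the per-mode reduced coordinates are
    recorded alongside, enabling exactness comparisons with the reduced
    dynamics.
    """
    if dt is None:
        dt = state.tau_c / DT_FRACTION
    if dt <= 0:
        raise InvalidConfigurationError("dt must be positive")
    if dt > state.tau_c / 10:
        raise InvalidConfigurationError(
            f"dt={dt} too large for gate timescale tau_c={state.tau_c}; "
            f"need dt <= tau_c/10"
        )
    if record_every < 1:
        raise InvalidConfigurationError("record_every must be >= 1")

    order = curriculum.resolved_order(teachers.M)
    tau_b = curriculum.block_length
    n_steps = int(round(curriculum.total_time / dt))
    state = state.copy()
    W, c = state.students, state.gates
    rng = np.random.default_rng(curriculum.seed)
    minibatch = curriculum.sampling_mode == "minibatch"

    rec: dict[str, list] = {k: [] for k in
                            ("t", "loss", "gates", "align", "upd", "wnorm", "block")}
    reduced_w: list[np.ndarray] = []
    if record_reduced:
        from .reduction import project  # deferred: reduction builds on model only

    if n_steps == 0:
        # Degenerate run (n_blocks == 0): empty trajectory, state untouched.
        P, M = state.P, teachers.M
        return Trajectory(
            times=np.empty(0), task_loss=np.empty(0),
            gates=np.empty((0,) + state.gates.shape),
            alignments=np.empty((0, P, M)), update_norms=np.empty((0, 2)),
            student_norms=np.empty((0, P)), block_index=np.empty(0, dtype=int),
            block_length=tau_b, final_state=state,
            meta={"dt": dt, "record_every": record_every,
                  "sampling_mode": curriculum.sampling_mode},
        )

    for step in range(n_steps + 1):
        t = step * dt
        block = min(int(t / tau_b), curriculum.n_blocks - 1)
        task = order[block % len(order)]
        teacher = teachers.teachers[task]

        batch = None
        if minibatch and step < n_steps:
            batch = sample_batch(teacher, curriculum.batch_size, rng)
        dW, dc = _step_gradients(state, teacher, batch)

        if step % record_every == 0 or step == n_steps:
            loss = expected_task_loss(state, teacher)
            if not np.isfinite(loss) or loss > LOSS_GUARD:
                raise InstabilityError(
                    f"task loss {loss:.3g} exceeded {LOSS_GUARD:.0e} at t={t:.4g}; "
                    f"reduce dt (currently {dt})"
                )
            rec["t"].append(t)
            rec["loss"].append(loss)
            rec["gates"].append(c.copy())
            rec["align"].append(metrics.alignment_table(W, teachers))
            rec["upd"].append(
                (np.linalg.norm(dW) / state.tau_w, np.linalg.norm(dc) / state.tau_c)
            )
            rec["wnorm"].append(np.linalg.norm(W, axis=(1, 2)))
            rec["block"].append(block)
            if record_reduced:
                reduced_w.append(np.stack(
                    [project(state, teachers, mode=a).w
                     for a in range(teachers.dout)]))
        if step == n_steps:
            break
        W -= (dt / state.tau_w) * dW
        c -= (dt / state.tau_c) * dc

    return Trajectory(
        times=np.array(rec["t"]),
        task_loss=np.array(rec["loss"]),
        gates=np.array(rec["gates"]),
        alignments=np.array(rec["align"]),
        update_norms=np.array(rec["upd"]),
        student_norms=np.array(rec["wnorm"]),
        block_index=np.array(rec["block"], dtype=int),
        block_length=tau_b,
        final_state=state,
        meta={"dt": dt, "record_every": record_every,
              "sampling_mode": curriculum.sampling_mode},
        reduced={"w": np.array(reduced_w)} if record_reduced else None,
    )
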