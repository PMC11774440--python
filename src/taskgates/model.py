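"""The gated linear student: forward map, losses, and exact gradients.

The network holds P student matrices ``W_p`` whose outputs are mixed by
gating variables ``c_p``::

    y = sum_p c_p W_p x                (scalar gates)
    y_i = sum_p c_{p,i} (W_p x)_i      (one gate per output row)

Weights and gates are trained jointly by gradient descent on
``L = L_task + lambda_norm * L_norm + lambda_nonneg * L_nonneg`` where the
norm term ``(||c||_k - 1)^2 / 2`` bounds total gate activity and the hinge
``sum_p max(0, -c_p)`` favors nonnegative gates.  Together they push the
model towards convex mixtures of its students without preferring any
particular specialization.

Two gradient modes are provided: ``expectation`` uses the closed form over
the standard-normal input distribution (the task loss becomes
``||W* - sum_q c_q W_q||_F^2 / 2``); ``minibatch`` uses empirical gradients
of the sampled loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .errors import DimensionError, InvalidConfigurationError

__all__ = [
    "ModelState",
    "GradientPair",
    "init_state",
    "forward",
    "effective_map",
    "task_loss",
    "expected_task_loss",
    "reg_loss",
    "reg_gradient",
    "gradients",
]

GATE_INIT = 0.5  # all gates start half-open
WEIGHT_INIT_SIGMA = 0.01  # std of W entries is sigma / sqrt(din)


@dataclass
class ModelState:
    """Students, gates, and the hyperparameters of the gradient flow.

    ``students`` has shape ``(P, dout, din)``; ``gates`` has shape ``(P,)``
    for scalar gating or ``(P, dout)`` when each output row of each student
    has its own gate (``gate_granularity='per_row'``).
    """

    students: np.ndarray
    gates: np.ndarray
    tau_w: float = 1.3
    tau_c: float = 0.03
    lambda_norm: float = 1.0
    lambda_nonneg: float = 1.0
    norm_order: Literal[1, 2] = 1
    gate_granularity: Literal["scalar", "per_row"] = "scalar"

    def __post_init__(self) -> None:
        self.students = np.asarray(self.students, dtype=float)
        self.gates = np.asarray(self.gates, dtype=float)
        if self.students.ndim != 3:
            raise DimensionError(
                f"students must have shape (P, dout, din); got {self.students.shape}"
            )
        P, dout, _ = self.students.shape
        if self.gate_granularity == "scalar":
            if self.gates.shape != (P,):
                raise DimensionError(
                    f"scalar gates must have shape ({P},); got {self.gates.shape}"
                )
        elif self.gate_granularity == "per_row":
            if self.gates.shape != (P, dout):
                raise DimensionError(
                    f"per_row gates must have shape ({P}, {dout}); got {self.gates.shape}"
                )
        else:
            raise InvalidConfigurationError(
                f"unknown gate_granularity {self.gate_granularity!r}"
            )
        if self.tau_w <= 0 or self.tau_c <= 0:
            raise InvalidConfigurationError("tau_w and tau_c must be positive")
        if self.lambda_norm < 0 or self.lambda_nonneg < 0:
            raise InvalidConfigurationError("regularization weights must be >= 0")
        if self.norm_order not in (1, 2):
            raise InvalidConfigurationError("norm_order must be 1 or 2")

    @property
    def P(self) -> int:
        return self.students.shape[0]

    @property
    def dout(self) -> int:
        return self.students.shape[1]

    @property
    def din(self) -> int:
        return self.students.shape[2]

    def gate_matrix(self) -> np.ndarray:
        """Gates broadcast to shape ``(P, dout)`` regardless of granularity."""
        if self.gate_granularity == "scalar":
            return np.broadcast_to(self.gates[:, None], (self.P, self.dout))
        return self.gates

    def copy(self) -> "ModelState":
        return replace(self, students=self.students.copy(), gates=self.gates.copy())

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            students=self.students,
            gates=self.gates,
            hyper=np.array(
                [self.tau_w, self.tau_c, self.lambda_norm, self.lambda_nonneg,
                 float(self.norm_order)]
            ),
            gate_granularity=np.array(self.gate_granularity),
        )

    @classmethod
    def load(cls, path) -> "ModelState":
        with np.load(path) as npz:
            h = npz["hyper"]
            return cls(
                students=npz["students"],
                gates=npz["gates"],
                tau_w=float(h[0]),
                tau_c=float(h[1]),
                lambda_norm=float(h[2]),
                lambda_nonneg=float(h[3]),
                norm_order=int(h[4]),
                gate_granularity=str(npz["gate_granularity"]),
            )


@dataclass
class GradientPair:
    """Gradients of the total loss, with the named additive parts."""

    dW: np.ndarray
    dc: np.ndarray
    components: dict = field(default_factory=dict)


def init_state(
    P: int,
    din: int,
    dout: int,
    seed: int = 0,
    sigma: float = WEIGHT_INIT_SIGMA,
    gate_granularity: Literal["scalar", "per_row"] = "scalar",
    **hyper,
) -> ModelState:
    """Small random initialization: ``W_p ~ N(0, sigma^2/din)``, gates at 1/2."""
    rng = np.random.default_rng(seed)
    students = rng.standard_normal((P, dout, din)) * (sigma / np.sqrt(din))
    shape = (P,) if gate_granularity == "scalar" else (P, dout)
    gates = np.full(shape, GATE_INIT)
    return ModelState(students=students, gates=gates,
                      gate_granularity=gate_granularity, **hyper)


def effective_map(state: ModelState) -> np.ndarray:
    """The end-to-end linear map ``sum_p c_p W_p`` of shape ``(dout, din)``."""
    return np.einsum("pi,pij->ij", state.gate_matrix(), state.students)


def forward(state: ModelState, x: np.ndarray) -> np.ndarray:
    """Model output for a single input ``(din,)`` or a batch ``(n, din)``."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != state.din:
        raise DimensionError(f"input has {x.shape[-1]} features, expected {state.din}")
    return x @ effective_map(state).T


def task_loss(state: ModelState, batch: tuple[np.ndarray, np.ndarray]) -> float:
    """Mean over the batch of ``||y* - y||^2 / 2``."""
    x, y_true = batch
    x, y_true = np.atleast_2d(x), np.atleast_2d(y_true)
    if x.shape[0] == 0:
        raise InvalidConfigurationError("batch must be nonempty")
    err = y_true - forward(state, x)
    return 0.5 * float(np.mean(np.sum(err**2, axis=1)))


def expected_task_loss(state: ModelState, teacher: np.ndarray) -> float:
    """Exact expectation of the task loss over unit-covariance Gaussian input.

    For whitened inputs this is ``||W* - sum_q c_q W_q||_F^2 / 2``.
    """
    err = np.asarray(teacher, dtype=float) - effective_map(state)
    return 0.5 * float(np.sum(err**2))


def reg_loss(state: ModelState) -> tuple[float, float]:
    """Unweighted ``(L_norm, L_nonneg)``.

    With per-row gates both penalties are applied independently to each output
    row's gate vector ``(c_{1,i}, ..., c_{P,i})`` and summed over rows.
    """
    c = state.gates
    if state.gate_granularity == "scalar":
        c = c[:, None]
    k = state.norm_order
    if k == 1:
        norms = np.sum(np.abs(c), axis=0)
    else:
        norms = np.sqrt(np.sum(c**2, axis=0))
    l_norm = 0.5 * float(np.sum((norms - 1.0) ** 2))
    l_nonneg = float(np.sum(np.maximum(0.0, -c)))
    return l_norm, l_nonneg


def reg_gradient(
    c: np.ndarray, norm_order: int
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of ``L_norm`` and ``L_nonneg`` w.r.t. a gate array.

    ``c`` has the paths on axis 0; any further axes are treated as independent
    gate vectors.  Subgradient conventions at the kinks: ``sign(0) = 0`` for
    the L1 norm and hinge slope 0 at ``c = 0``.
    """
    c = np.asarray(c, dtype=float)
    if norm_order == 1:
        norms = np.sum(np.abs(c), axis=0, keepdims=True)
        g_norm = (norms - 1.0) * np.sign(c)
    else:
        norms = np.sqrt(np.sum(c**2, axis=0, keepdims=True))
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(norms > 0, c / np.where(norms == 0, 1.0, norms), 0.0)
        g_norm = (norms - 1.0) * unit
    g_nonneg = np.where(c < 0, -1.0, 0.0)
    return g_norm, g_nonneg


def _expectation_task_gradients(
    state: ModelState, teacher: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    cmat = state.gate_matrix()
    err = np.asarray(teacher, dtype=float) - effective_map(state)  # (dout, din)
    dW = -np.einsum("pi,ij->pij", cmat, err)
    dc_rows = -np.einsum("pij,ij->pi", state.students, err)
    if state.gate_granularity == "scalar":
        return dW, dc_rows.sum(axis=1)
    return dW, dc_rows


def _minibatch_task_gradients(
    state: ModelState, batch: tuple[np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    x, y_true = batch
    x, y_true = np.atleast_2d(x), np.atleast_2d(y_true)
    n = x.shape[0]
    err = y_true - forward(state, x)  # (n, dout)
    cmat = state.gate_matrix()
    # dL/dW_p[i,:] = -c_{p,i} * mean_n err_{n,i} x_n
    err_x = err.T @ x / n  # (dout, din)
    dW = -np.einsum("pi,ij->pij", cmat, err_x)
    path_out = np.einsum("nj,pij->npi", x, state.students)  # (n, P, dout)
    dc_rows = -np.einsum("ni,npi->pi", err, path_out) / n
    if state.gate_granularity == "scalar":
        return dW, dc_rows.sum(axis=1)
    return dW, dc_rows


def gradients(
    state: ModelState,
    teacher: np.ndarray,
    mode: Literal["expectation", "minibatch"] = "expectation",
    batch: tuple[np.ndarray, np.ndarray] | None = None,
) -> GradientPair:
    """Gradients of the full regularized loss for the active teacher.

    In expectation mode the task part uses the error matrix
    ``E = W* - sum_q c_q W_q``: the weight gradient for path p is ``-c_p E``
    and the gate gradient is ``-<W_p, E>`` (Frobenius inner product).
    """
    if mode == "expectation":
        dW_task, dc_task = _expectation_task_gradients(state, teacher)
    elif mode == "minibatch":
        if batch is None:
            raise InvalidConfigurationError("minibatch mode requires a batch")
        dW_task, dc_task = _minibatch_task_gradients(state, batch)
    else:
        raise InvalidConfigurationError(f"unknown gradient mode {mode!r}")

    g_norm, g_nonneg = reg_gradient(state.gates, state.norm_order)
    dc = dc_task + state.lambda_norm * g_norm + state.lambda_nonneg * g_nonneg
    return GradientPair(
        dW=dW_task,
        dc=dc,
        components={
            "task": (dW_task, dc_task),
            "norm": g_norm,
            "nonneg": g_nonneg,
        },
    )
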