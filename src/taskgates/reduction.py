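"""Exact low-dimensional reduction of the learning dynamics.

For two orthogonal teachers, projecting each student onto the teachers'
singular vectors, ``w^p_m = u*_m^T W_p v*_m`` (per singular mode), collapses
the expectation-mode dynamics to a 2-vector per path plus its gate::

    tau_w dw^p/dt = c_p eps
    tau_c dc_p/dt = w^p . eps - lambda-weighted regularization gradient

with ``eps = y* - sum_p c_p w^p`` and ``y*`` the active teacher's unit
vector in the teacher basis.  The reduction is exact whenever the student
weights lie in the span of the teacher modes (small out-of-span components
only decay).

*Specialization coordinates* summarize the state:
``wbar_1 = w^1_1 - w^2_1``, ``wbar_2 = w^2_2 - w^1_2``,
``wbar = (wbar_1 + wbar_2)/2`` (how differently the two paths represent the
two teachers) and ``cbar = c_1 - c_2`` (gate separation).  Under the
symmetry ``wbar_1 = wbar_2`` and strong L1 gate normalization the adaptation
after a task switch obeys a separable ODE,
``(tau_c/tau_w) dcbar/dwbar = 2 wbar / cbar``, whose first integral from the
fully specialized start ``(cbar, wbar) = (1, 1)`` gives the closed form

    wbar^2 = 1 - (tau_c / (2 tau_w)) (1 - cbar^2).

Small ``tau_c/tau_w`` therefore *protects* specialization: the gates switch
before the weights can move.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .curriculum import TeacherSet
from .errors import DomainError, InvalidConfigurationError
from .model import ModelState, reg_gradient

__all__ = [
    "ReducedState",
    "ReducedTrajectory",
    "project",
    "reduced_rhs",
    "gate_decomposition",
    "specialization_rhs",
    "exact_symmetric_solution",
    "integrate_reduced",
    "block_adaptation",
    "symmetric_adaptation",
    "specialized_state",
]


@dataclass
class ReducedState:
    """Per-mode reduced coordinates: ``w`` of shape ``(P, 2)`` (stacked along
    the teacher index m) and ``c`` of shape ``(P,)``.

    ``target`` optionally records the currently active teacher (0-based) so
    the error vector is well defined.
    """

    w: np.ndarray
    c: np.ndarray
    target: Optional[int] = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.w.ndim != 2 or self.w.shape[1] != 2:
            raise DomainError(f"w must have shape (P, 2); got {self.w.shape}")
        if self.c.shape != (self.w.shape[0],):
            raise DomainError("c must have one gate per path")

    @property
    def P(self) -> int:
        return self.w.shape[0]

    def output(self) -> np.ndarray:
        """Reduced model output ``y = sum_p c_p w^p`` in the teacher basis."""
        return self.c @ self.w

    def error(self, target: Optional[int] = None) -> np.ndarray:
        """``eps = y* - y`` with ``y*`` the unit vector of the active
        teacher."""
        target = self.target if target is None else target
        if target is None:
            raise DomainError("no active teacher set on this ReducedState")
        if target not in (0, 1):
            raise DomainError("target must be 0 or 1 in the two-task reduction")
        y_star = np.zeros(2)
        y_star[target] = 1.0
        return y_star - self.output()

    def task_loss(self, target: Optional[int] = None) -> float:
        """Expected task loss of the reduced model, ``||eps||^2 / 2``."""
        return 0.5 * float(np.sum(self.error(target) ** 2))

    @property
    def coords(self) -> tuple[float, float, float, float]:
        """``(wbar_1, wbar_2, wbar, cbar)`` — defined for P = 2."""
        if self.P != 2:
            raise DomainError("specialization coordinates require P = 2")
        wbar1 = self.w[0, 0] - self.w[1, 0]
        wbar2 = self.w[1, 1] - self.w[0, 1]
        return wbar1, wbar2, 0.5 * (wbar1 + wbar2), self.c[0] - self.c[1]

    def copy(self) -> "ReducedState":
        return ReducedState(self.w.copy(), self.c.copy(), self.target)


@dataclass
class ReducedTrajectory:
    """Recorded reduced dynamics; coordinate series are derived columns."""

    times: np.ndarray
    w: np.ndarray  # (T, P, 2)
    c: np.ndarray  # (T, P)
    task_loss: np.ndarray
    target: int
    meta: dict = field(default_factory=dict)

    @property
    def wbar(self) -> np.ndarray:
        w1 = self.w[:, 0, 0] - self.w[:, 1, 0]
        w2 = self.w[:, 1, 1] - self.w[:, 0, 1]
        return 0.5 * (w1 + w2)

    @property
    def cbar(self) -> np.ndarray:
        return self.c[:, 0] - self.c[:, 1]

    def __len__(self) -> int:
        return len(self.times)


def specialized_state(P: int = 2) -> ReducedState:
    """The fully specialized, fully separated state ``w^p_m = delta_pm``,
    ``c_p = delta_p1`` (path 1 owns teacher 1 and its gate is open)."""
    if P != 2:
        raise DomainError("the specialized reference state is defined for P = 2")
    return ReducedState(w=np.eye(2), c=np.array([1.0, 0.0]), target=0)


def project(state: ModelState, teachers: TeacherSet, mode: int = 0) -> ReducedState:
    """Project a full model onto singular mode ``mode`` of two orthogonal
    teachers, yielding ``w^p_m = u*_m^T W_p v*_m`` and the current gates."""
    if teachers.M != 2:
        raise InvalidConfigurationError(
            f"the reduction is defined for M = 2 teachers, got M = {teachers.M}"
        )
    if state.gate_granularity != "scalar":
        raise InvalidConfigurationError("the reduction assumes scalar gates")
    if not 0 <= mode < teachers.dout:
        raise DomainError(f"mode {mode} out of range for dout={teachers.dout}")
    w = np.empty((state.P, 2))
    for m in range(2):
        u, _, vt = teachers.svd(m)
        ua, va = u[:, mode], vt[mode, :]
        for p in range(state.P):
            w[p, m] = ua @ state.students[p] @ va
    return ReducedState(w=w, c=state.gates.copy())


def reduced_rhs(
    rs: ReducedState,
    target: int,
    lambda_norm: float = 1.0,
    lambda_nonneg: float = 1.0,
    tau_w: float = 1.3,
    tau_c: float = 0.03,
    norm_order: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives ``(dw, dc)`` of the reduced dynamics for the given
    active teacher."""
    eps = rs.error(target)
    dw = np.outer(rs.c, eps) / tau_w
    g_norm, g_nonneg = reg_gradient(rs.c, norm_order)
    dc = (rs.w @ eps - lambda_norm * g_norm - lambda_nonneg * g_nonneg) / tau_c
    return dw, dc


def gate_decomposition(
    rs: ReducedState,
    target: Optional[int] = None,
    lambda_norm: float = 1.0,
    lambda_nonneg: float = 1.0,
    norm_order: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The three additive parts of ``tau_c dc_p/dt``: the error components
    resolved along each teacher axis plus the regularization pull,

        tau_c dc_p/dt = eps_1 w^p_1 + eps_2 w^p_2 - grad_{c_p} L_reg.

    Small students attenuate both error terms (they scale with ``w^p``),
    which is why gates barely move early in training.
    """
    eps = rs.error(target)
    term1 = eps[0] * rs.w[:, 0]
    term2 = eps[1] * rs.w[:, 1]
    g_norm, g_nonneg = reg_gradient(rs.c, norm_order)
    reg = -(lambda_norm * g_norm + lambda_nonneg * g_nonneg)
    return term1, term2, reg


def specialization_rhs(
    rs: ReducedState,
    target: Optional[int] = None,
    tau_w: float = 1.3,
    tau_c: float = 0.03,
) -> tuple[float, float]:
    """Drift of the specialization coordinates (regularization-free form;
    with positive gates the L1 pull is identical on both paths and cancels
    in ``cbar``):

        tau_c dcbar/dt = wbar_1 eps_1 - wbar_2 eps_2
        tau_w dwbar/dt = cbar (eps_1 - eps_2) / 2
    """
    wbar1, wbar2, _, cbar = rs.coords
    eps = rs.error(target)
    dcbar = (wbar1 * eps[0] - wbar2 * eps[1]) / tau_c
    dwbar = cbar * (eps[0] - eps[1]) / (2.0 * tau_w)
    return dwbar, dcbar


def exact_symmetric_solution(cbar, tau_c: float, tau_w: float):
    """Closed-form specialization ``wbar(cbar)`` during one block of
    adaptation, for the symmetric strong-L1 regime started fully specialized
    at ``(cbar, wbar) = (1, 1)``::

        wbar = sqrt(1 - (tau_c / (2 tau_w)) (1 - cbar^2))

    Even in ``cbar`` and monotone in ``|cbar|``; equals 1 at full separation
    ``cbar = +/-1`` for any timescale ratio.  Raises :class:`DomainError`
    outside ``|cbar| <= 1`` or when the radicand is negative (specialization
    lost — the timescale ratio is too large to protect the weights).
    """
    cbar_arr = np.asarray(cbar, dtype=float)
    if np.any(np.abs(cbar_arr) > 1.0 + 1e-12):
        raise DomainError("cbar must lie in [-1, 1]")
    if tau_c <= 0 or tau_w <= 0:
        raise DomainError("timescales must be positive")
    radicand = 1.0 - (tau_c / (2.0 * tau_w)) * (1.0 - np.clip(cbar_arr, -1, 1) ** 2)
    if np.any(radicand < -1e-12):
        raise DomainError(
            "negative radicand: specialization is not preserved for "
            f"tau_c/tau_w = {tau_c / tau_w:.3g} at cbar = {cbar}"
        )
    out = np.sqrt(np.maximum(radicand, 0.0))
    return float(out) if np.isscalar(cbar) or np.ndim(cbar) == 0 else out


def integrate_reduced(
    rs0: ReducedState,
    target: int,
    horizon: float,
    tau_w: float = 1.3,
    tau_c: float = 0.03,
    lambda_norm: float = 1.0,
    lambda_nonneg: float = 1.0,
    norm_order: int = 1,
    dt: float | None = None,
    record_every: int = 1,
    method: str = "euler",
) -> ReducedTrajectory:
    """Integrate the reduced dynamics for a fixed active teacher.

    ``method='euler'`` mirrors the full simulator step-for-step (same dt
    convention), which is what makes exactness comparisons meaningful;
    ``method='radau'`` uses a stiff implicit solver and is the right choice
    for strong regularization (large lambda_norm).
    """
    rs = rs0.copy()
    P = rs.P

    if method == "euler":
        if dt is None:
            dt = tau_c / 50.0
        if dt <= 0 or dt > tau_c / 10:
            raise InvalidConfigurationError(
                f"dt={dt} must be positive and <= tau_c/10 = {tau_c / 10}"
            )
        n_steps = int(round(horizon / dt))
        ts, ws, cs, losses = [], [], [], []
        for step in range(n_steps + 1):
            if step % record_every == 0 or step == n_steps:
                ts.append(step * dt)
                ws.append(rs.w.copy())
                cs.append(rs.c.copy())
                losses.append(rs.task_loss(target))
            if step == n_steps:
                break
            dw, dc = reduced_rhs(rs, target, lambda_norm, lambda_nonneg,
                                 tau_w, tau_c, norm_order)
            rs.w += dt * dw
            rs.c += dt * dc
        times = np.array(ts)
        w_arr = np.array(ws)
        c_arr = np.array(cs)
        loss_arr = np.array(losses)
    elif method == "radau":
        def rhs(_t, z):
            st = ReducedState(z[: 2 * P].reshape(P, 2), z[2 * P :])
            dw, dc = reduced_rhs(st, target, lambda_norm, lambda_nonneg,
                                 tau_w, tau_c, norm_order)
            return np.concatenate([dw.ravel(), dc])

        n_rec = max(int(round(horizon / (tau_c / 50.0 * record_every))), 50)
        times = np.linspace(0.0, horizon, n_rec + 1)
        z0 = np.concatenate([rs.w.ravel(), rs.c])
        sol = solve_ivp(rhs, (0.0, horizon), z0, method="Radau",
                        t_eval=times, rtol=1e-10, atol=1e-12)
        if not sol.success:  # pragma: no cover
            raise InvalidConfigurationError(f"stiff solve failed: {sol.message}")
        w_arr = sol.y[: 2 * P].T.reshape(-1, P, 2)
        c_arr = sol.y[2 * P :].T
        y_star = np.zeros(2)
        y_star[target] = 1.0
        eps = y_star[None, :] - np.einsum("tp,tpm->tm", c_arr, w_arr)
        loss_arr = 0.5 * np.sum(eps**2, axis=1)
    else:
        raise InvalidConfigurationError(f"unknown method {method!r}")

    return ReducedTrajectory(
        times=times, w=w_arr, c=c_arr, task_loss=loss_arr, target=target,
        meta={"tau_w": tau_w, "tau_c": tau_c, "lambda_norm": lambda_norm,
              "lambda_nonneg": lambda_nonneg, "norm_order": norm_order,
              "method": method},
    )


def block_adaptation(
    rs0: ReducedState | None = None,
    tau_c: float = 0.1,
    tau_w: float = 1.0,
    lambda_norm: float = 1000.0,
    lambda_nonneg: float = 1000.0,
    horizon: float = 4.0,
    record_every: int = 1,
) -> ReducedTrajectory:
    """One block of complete adaptation from teacher 1 to teacher 2.

    Starts (by default) from the fully specialized state and integrates the
    reduced dynamics with the *other* teacher active, under strong L1 gate
    normalization (the regime in which the closed-form ``wbar(cbar)`` path
    applies).  A stiff solver handles the large regularization weights.
    """
    if rs0 is None:
        rs0 = specialized_state()
    return integrate_reduced(
        rs0, target=1, horizon=horizon, tau_w=tau_w, tau_c=tau_c,
        lambda_norm=lambda_norm, lambda_nonneg=lambda_nonneg,
        record_every=record_every, method="radau",
    )


def symmetric_adaptation(
    tau_c: float,
    tau_w: float,
    horizon: float = 4.0,
    n_record: int = 400,
) -> ReducedTrajectory:
    """Adaptation restricted to the exact symmetric strong-L1 manifold.

    On the manifold (``wbar_1 = wbar_2 = wbar``, ``c_1 + c_2 = 1``,
    ``w^p_1 + w^p_2 = 1``) the dynamics close on the two specialization
    coordinates alone::

        tau_w dwbar/dt = -cbar (1 + wbar cbar) / 2
        tau_c dcbar/dt = -wbar (1 + wbar cbar)

    with task loss ``(1 + wbar cbar)^2 / 4``.  This is the system whose
    first integral is :func:`exact_symmetric_solution`.
    """

    def rhs(_t, z):
        wbar, cbar = z
        drive = 1.0 + wbar * cbar
        return [-cbar * drive / (2.0 * tau_w), -wbar * drive / tau_c]

    times = np.linspace(0.0, horizon, n_record + 1)
    sol = solve_ivp(rhs, (0.0, horizon), [1.0, 1.0], method="Radau",
                    t_eval=times, rtol=1e-11, atol=1e-13)
    if not sol.success:  # pragma: no cover
        raise InvalidConfigurationError(f"symmetric solve failed: {sol.message}")
    wbar, cbar = sol.y
    # Reconstruct the per-path representation on the manifold.
    w = np.empty((len(times), 2, 2))
    w[:, 0, 0] = (1.0 + wbar) / 2.0
    w[:, 0, 1] = (1.0 - wbar) / 2.0
    w[:, 1, 0] = (1.0 - wbar) / 2.0
    w[:, 1, 1] = (1.0 + wbar) / 2.0
    c = np.stack([(1.0 + cbar) / 2.0, (1.0 - cbar) / 2.0], axis=1)
    loss = (1.0 + wbar * cbar) ** 2 / 4.0
    return ReducedTrajectory(
        times=times, w=w, c=c, task_loss=loss, target=1,
        meta={"tau_w": tau_w, "tau_c": tau_c, "manifold": "symmetric-strong-L1"},
    )
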