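"""Teacher ensembles, blocked task schedules, and Gaussian input sampling.

A *teacher* is a ground-truth linear map ``W*_m`` (one per task) applied to
i.i.d. standard-normal inputs.  Teachers are generated so that distinct tasks
produce mutually orthogonal responses to the same input: the ``M * dout``
stacked teacher rows form an orthonormal set (scaled to ``row_norm``), which
requires ``M * dout <= din``.

Tasks are presented in contiguous blocks of duration ``block_length``,
cycling through ``task_order``; the model never receives the task identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .errors import DomainError, InvalidConfigurationError

__all__ = [
    "TeacherSet",
    "Curriculum",
    "make_teachers",
    "active_task",
    "sample_batch",
]


@dataclass(frozen=True)
class TeacherSet:
    """A set of M ground-truth linear maps defining the tasks.

    Parameters
    ----------
    teachers
        Array of shape ``(M, dout, din)``.
    orthogonal
        True when the stacked rows of all teachers are pairwise orthogonal.
    row_norm
        Euclidean norm given to every teacher row.
    """

    teachers: np.ndarray
    orthogonal: bool = True
    row_norm: float = 1.0
    _svd_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.teachers, dtype=float)
        if t.ndim != 3:
            raise InvalidConfigurationError(
                f"teachers must have shape (M, dout, din); got {t.shape}"
            )
        object.__setattr__(self, "teachers", t)

    @property
    def M(self) -> int:
        return self.teachers.shape[0]

    @property
    def dout(self) -> int:
        return self.teachers.shape[1]

    @property
    def din(self) -> int:
        return self.teachers.shape[2]

    def stacked(self) -> np.ndarray:
        """All teacher rows stacked into one ``(M*dout, din)`` matrix."""
        return self.teachers.reshape(self.M * self.dout, self.din)

    def svd(self, m: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Thin SVD ``(U, s, Vt)`` of teacher ``m`` (cached)."""
        if m not in self._svd_cache:
            self._svd_cache[m] = np.linalg.svd(self.teachers[m], full_matrices=False)
        return self._svd_cache[m]

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            teachers=self.teachers,
            orthogonal=np.array(self.orthogonal),
            row_norm=np.array(self.row_norm),
        )

    @classmethod
    def load(cls, path) -> "TeacherSet":
        with np.load(path) as npz:
            return cls(
                teachers=npz["teachers"],
                orthogonal=bool(npz["orthogonal"]),
                row_norm=float(npz["row_norm"]),
            )


@dataclass(frozen=True)
class Curriculum:
    """A blocked task schedule.

    ``task_order=None`` means the default cyclic order ``0, 1, ..., M-1``
    repeating; total simulated time is ``n_blocks * block_length``.
    """

    block_length: float
    n_blocks: int
    task_order: tuple[int, ...] | None = None
    sampling_mode: Literal["expectation", "minibatch"] = "expectation"
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_length <= 0:
            raise InvalidConfigurationError("block_length must be positive")
        if self.n_blocks < 0:
            raise InvalidConfigurationError("n_blocks must be nonnegative")
        if self.sampling_mode not in ("expectation", "minibatch"):
            raise InvalidConfigurationError(
                f"unknown sampling_mode {self.sampling_mode!r}"
            )
        if self.batch_size < 1:
            raise InvalidConfigurationError("batch_size must be >= 1")
        if self.task_order is not None:
            object.__setattr__(self, "task_order", tuple(int(i) for i in self.task_order))

    @property
    def total_time(self) -> float:
        return self.n_blocks * self.block_length

    def resolved_order(self, M: int) -> tuple[int, ...]:
        """The task order, defaulting to cyclic over ``M`` tasks."""
        order = self.task_order if self.task_order is not None else tuple(range(M))
        if any(i < 0 or i >= M for i in order):
            raise InvalidConfigurationError(
                f"task_order {order} contains indices outside 0..{M - 1}"
            )
        return order

    def with_order(self, order: Sequence[int]) -> "Curriculum":
        return replace(self, task_order=tuple(int(i) for i in order))


def make_teachers(
    M: int,
    din: int,
    dout: int,
    row_norm: float = 1.0,
    orthogonal: bool = True,
    correlation: float = 0.0,
    seed: int = 0,
) -> TeacherSet:
    """Randomly generate ``M`` teachers with orthogonal responses.

    A Gaussian ``(M*dout, din)`` matrix is row-orthonormalized (QR), rows are
    scaled to ``row_norm`` and split into ``M`` teachers of shape
    ``(dout, din)``.  With ``orthogonal=False`` and ``correlation=rho > 0``,
    row ``i`` of teacher ``m > 0`` is mixed with row ``i`` of teacher 0 so
    their cosine equals ``rho`` — a hook for studying non-orthogonal tasks.

    Raises
    ------
    InvalidConfigurationError
        If ``M*dout > din`` (orthogonal rows infeasible) or a correlation is
        requested together with ``orthogonal=True``.
    """
    if M < 1 or din < 1 or dout < 1:
        raise InvalidConfigurationError("M, din, dout must be positive")
    if M * dout > din:
        raise InvalidConfigurationError(
            f"cannot fit {M}*{dout}={M * dout} orthogonal rows in {din} dimensions"
        )
    if orthogonal and correlation != 0.0:
        raise InvalidConfigurationError("correlation requires orthogonal=False")
    if not 0.0 <= correlation < 1.0:
        raise InvalidConfigurationError("correlation must lie in [0, 1)")
    if row_norm <= 0:
        raise InvalidConfigurationError("row_norm must be positive")

    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((M * dout, din))
    # QR on the transpose yields orthonormal columns -> orthonormal rows.
    q, _ = np.linalg.qr(raw.T)
    rows = q.T[: M * dout]
    teachers = rows.reshape(M, dout, din).copy()

    if correlation > 0.0:
        rho = correlation
        base = teachers[0]
        for m in range(1, M):
            teachers[m] = rho * base + math.sqrt(1.0 - rho**2) * teachers[m]
        orthogonal = False

    teachers *= row_norm
    return TeacherSet(teachers=teachers, orthogonal=(orthogonal and correlation == 0.0),
                      row_norm=row_norm)


def active_task(t: float, curriculum: Curriculum, M: int) -> int:
    """Task index active at time ``t`` (half-open blocks ``[b*tauB, (b+1)*tauB)``)."""
    if t < 0:
        raise DomainError(f"time must be nonnegative, got {t}")
    order = curriculum.resolved_order(M)
    block = int(math.floor(t / curriculum.block_length))
    return order[block % len(order)]


def sample_batch(
    teacher: np.ndarray, n: int, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` i.i.d. standard-normal inputs and their teacher labels.

    Returns ``(X, Y)`` with ``X`` of shape ``(n, din)`` and ``Y = X @ W*.T``
    of shape ``(n, dout)``.  Bit-reproducible given an integer seed.
    """
    if n < 1:
        raise InvalidConfigurationError("batch size n must be >= 1")
    teacher = np.asarray(teacher, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.standard_normal((n, teacher.shape[1]))
    y = x @ teacher.T
    return x, y
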