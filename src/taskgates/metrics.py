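"""Observables: alignment, matched total alignment, time-to-criterion,
regime classification, and post-switch speed trends.

Two learning regimes are distinguished empirically.  In the *flexible*
regime the students specialize (one per teacher), gates do the switching,
and adaptation after a task switch accelerates with practice.  In the
*forgetful* regime both students re-align to every new teacher and
adaptation speed stays flat or degrades.
"""

from __future__ import annotations

import itertools
import warnings
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import stats

from .curriculum import TeacherSet
from .errors import DomainError, InsufficientDataError

if TYPE_CHECKING:  # pragma: no cover
    from .dynamics import Trajectory

__all__ = [
    "alignment",
    "alignment_table",
    "total_alignment",
    "time_to_criterion",
    "classify_regime",
    "switch_speed_trend",
]

_EXACT_MATCHING_LIMIT = 4  # exhaustive assignment up to the studied P, M


def alignment(student: np.ndarray, teacher: np.ndarray) -> float:
    """Row-averaged cosine similarity between a student and a teacher.

    Rows of exactly zero norm (the small-initialization start) contribute 0
    and raise a warning.
    """
    student = np.asarray(student, dtype=float)
    teacher = np.asarray(teacher, dtype=float)
    if student.shape != teacher.shape:
        raise DomainError(f"shape mismatch {student.shape} vs {teacher.shape}")
    sn = np.linalg.norm(student, axis=1)
    tn = np.linalg.norm(teacher, axis=1)
    dead = (sn == 0) | (tn == 0)
    if np.any(dead):
        warnings.warn("zero-norm row(s) contribute 0 to alignment", stacklevel=2)
    denom = np.where(dead, 1.0, sn * tn)
    cos = np.where(dead, 0.0, np.sum(student * teacher, axis=1) / denom)
    return float(np.mean(cos))


def alignment_table(students: np.ndarray, teachers: TeacherSet) -> np.ndarray:
    """Cosine alignment for every (path p, teacher m) pair, shape ``(P, M)``."""
    students = np.asarray(students, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.array(
            [[alignment(w, t) for t in teachers.teachers] for w in students]
        )


def _concat_cosine(students: np.ndarray, teachers: np.ndarray) -> float:
    a = students.ravel()
    b = teachers.ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def total_alignment(students: np.ndarray, teachers: TeacherSet) -> float:
    """Cosine between the concatenated students and the best-matched teachers.

    The assignment of paths to teachers is maximized over injective maps
    (exhaustive for min(P, M) <= 4, greedy above); a collapse where two
    students track the same teacher therefore scores strictly below 1.
    """
    students = np.asarray(students, dtype=float)
    P = students.shape[0]
    M = teachers.M
    if P == 0 or M == 0:
        raise DomainError("total_alignment needs at least one student and teacher")

    t = teachers.teachers
    if min(P, M) <= _EXACT_MATCHING_LIMIT:
        best = -np.inf
        if P <= M:
            for perm in itertools.permutations(range(M), P):
                best = max(best, _concat_cosine(students, t[list(perm)]))
        else:
            for perm in itertools.permutations(range(P), M):
                best = max(best, _concat_cosine(students[list(perm)], t))
        return best
    # Greedy fallback: repeatedly take the best remaining (path, teacher) pair.
    table = np.array([[_concat_cosine(students[p : p + 1], t[m : m + 1])
                       for m in range(M)] for p in range(P)])
    paths, tasks = list(range(P)), list(range(M))
    pairs: list[tuple[int, int]] = []
    while paths and tasks:
        p, m = max(((p, m) for p in paths for m in tasks), key=lambda pm: table[pm])
        pairs.append((p, m))
        paths.remove(p)
        tasks.remove(m)
    idx_p = [p for p, _ in pairs]
    idx_m = [m for _, m in pairs]
    return _concat_cosine(students[idx_p], t[idx_m])


def time_to_criterion(traj: "Trajectory", threshold: float = 0.1) -> np.ndarray:
    """Per block, time from block start until the task loss first drops
    below ``threshold``; the block length is used as a sentinel when the
    criterion is never reached within the block."""
    if threshold <= 0:
        raise DomainError("threshold must be positive")
    times = traj.times
    blocks = traj.block_index
    loss = traj.task_loss
    out = []
    for b in np.unique(blocks):
        sel = blocks == b
        t_block = times[sel]
        hit = np.nonzero(loss[sel] < threshold)[0]
        start = t_block[0]
        block_len = traj.block_length
        out.append(float(t_block[hit[0]] - start) if hit.size else float(block_len))
    return np.array(out)


def classify_regime(
    traj: "Trajectory",
    teachers: TeacherSet,
    align_threshold: float = 0.9,
    loss_threshold: float = 0.1,
) -> str:
    """Classify a finished run as ``'flexible'`` or ``'forgetful'``.

    Flexible requires both (a) final matched total alignment above
    ``align_threshold`` and (b) faster criterion times in the last quarter of
    blocks than in the first quarter.
    """
    n_blocks = int(traj.block_index.max()) + 1 if traj.block_index.size else 0
    if n_blocks < 8:
        raise InsufficientDataError(
            f"regime classification needs >= 8 blocks, got {n_blocks}"
        )
    final_align = total_alignment(traj.final_state.students, teachers)
    ttc = time_to_criterion(traj, loss_threshold)
    q = max(1, len(ttc) // 4)
    speeding_up = float(np.mean(ttc[-q:])) < float(np.mean(ttc[:q]))
    if final_align > align_threshold and speeding_up:
        return "flexible"
    return "forgetful"


def switch_speed_trend(
    traj: "Trajectory", window: float = 0.1
) -> tuple[float, float]:
    """Trend of post-switch difficulty over blocks.

    The mean task loss over the first ``window`` fraction of each block is
    regressed against the block index; returns ``(slope, sign)``.  A negative
    slope means switching gets faster with practice.
    """
    if not 0 < window <= 1:
        raise DomainError("window must be a fraction in (0, 1]")
    blocks = np.unique(traj.block_index)
    if blocks.size < 2:
        raise InsufficientDataError("switch trend needs at least 2 blocks")
    block_len = traj.block_length
    means = []
    for b in blocks:
        sel = traj.block_index == b
        t = traj.times[sel]
        in_window = t - t[0] <= window * block_len
        means.append(float(np.mean(traj.task_loss[sel][in_window])))
    means = np.asarray(means)
    if np.allclose(means, means[0]):
        return 0.0, 0.0
    slope = float(stats.linregress(blocks.astype(float), means).slope)
    return slope, float(np.sign(slope))


def spearman_monotonicity(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (thin wrapper used by the phase-diagram
    analysis)."""
    return float(stats.spearmanr(x, y).statistic)
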