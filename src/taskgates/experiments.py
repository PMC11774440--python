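"""Scripted, seeded experiment pipelines producing tidy tables.

Each function builds its own teachers/curriculum/model from a small set of
keyword parameters (defaults are the studied conditions), runs the
deterministic expectation-mode dynamics over a list of seeds, and returns
pandas DataFrames ready for summary or plotting:

- ``run_regime_comparison``: flexible model vs its forgetful control on the
  two-task blocked curriculum; per-block time-to-criterion and per-seed
  regime labels.
- ``run_task_composition`` / ``run_subtask_composition``: train on three
  teachers A, B, C, then switch the curriculum to their pairwise sums
  (A+B, A+C, B+C) or to row-interleaved combinations; compositional reuse
  shows up as much faster criterion times for the flexible model.
- ``run_phase_diagram``: grid of final matched total alignment over block
  length and either the regularization multiplier or the gate learning rate,
  at fixed total training time.
- ``run_switch_trend``: slope of post-switch loss against block index for
  both models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import metrics
from .curriculum import Curriculum, TeacherSet, make_teachers
from .dynamics import forgetful_baseline, integrate
from .errors import InsufficientDataError, InvalidConfigurationError
from .model import ModelState, init_state

__all__ = [
    "PhaseGrid",
    "run_regime_comparison",
    "run_task_composition",
    "run_subtask_composition",
    "run_phase_diagram",
    "run_switch_trend",
]

# Studied conditions for the two-task regime comparison: gate and weight
# timescales and block length as printed for the flexible model; network
# dimensions and regularization weights are package defaults.
FIG2 = dict(tau_c=0.03, tau_w=1.3, block_length=1.0, n_blocks=24,
            M=2, P=2, din=32, dout=8, lambda_norm=1.0, lambda_nonneg=1.0)


def _build(seed: int, *, M: int, P: int, din: int, dout: int, tau_c: float,
           tau_w: float, lambda_norm: float, lambda_nonneg: float,
           gate_granularity: str = "scalar",
           teacher_seed: int | None = None) -> tuple[ModelState, TeacherSet]:
    teachers = make_teachers(M, din, dout,
                             seed=teacher_seed if teacher_seed is not None else seed)
    state = init_state(P, din, dout, seed=seed, tau_c=tau_c, tau_w=tau_w,
                       lambda_norm=lambda_norm, lambda_nonneg=lambda_nonneg,
                       gate_granularity=gate_granularity)
    return state, teachers


def run_regime_comparison(
    seeds: Sequence[int] = range(10),
    criterion: float = 0.1,
    **overrides,
) -> dict[str, pd.DataFrame]:
    """Flexible vs forgetful two-task comparison.

    Returns ``per_block`` (model, seed, block, time_to_criterion),
    ``summary`` (per model and block: mean and standard error over seeds) and
    ``regimes`` (per model and seed: the regime classification).
    """
    params = {**FIG2, **overrides}
    rows, regime_rows = [], []
    for seed in seeds:
        state, teachers = _build(seed, **{k: params[k] for k in
                                          ("M", "P", "din", "dout", "tau_c",
                                           "tau_w", "lambda_norm", "lambda_nonneg")})
        curr = Curriculum(block_length=params["block_length"],
                          n_blocks=params["n_blocks"], seed=seed)
        for model_name, st in (("flexible", state),
                               ("forgetful", forgetful_baseline(state))):
            traj = integrate(st, teachers, curr)
            ttc = metrics.time_to_criterion(traj, criterion)
            rows += [dict(model=model_name, seed=seed, block=b, time_to_criterion=v)
                     for b, v in enumerate(ttc)]
            regime_rows.append(dict(
                model=model_name, seed=seed,
                regime=metrics.classify_regime(traj, teachers),
                final_total_alignment=metrics.total_alignment(
                    traj.final_state.students, teachers),
            ))
    per_block = pd.DataFrame(rows)
    summary = (per_block.groupby(["model", "block"])["time_to_criterion"]
               .agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x))
                    if len(x) > 1 else 0.0)
               .reset_index())
    return {"per_block": per_block, "summary": summary,
            "regimes": pd.DataFrame(regime_rows)}


def _composed_sum_teachers(base: TeacherSet) -> TeacherSet:
    """Pairwise additive compositions A+B, A+C, B+C."""
    a, b, c = base.teachers
    return TeacherSet(teachers=np.stack([a + b, a + c, b + c]), orthogonal=False,
                      row_norm=float(np.linalg.norm((a + b)[0])))


def _composed_row_teachers(base: TeacherSet) -> TeacherSet:
    """Row-interleaved compositions: even rows from the first teacher of the
    pair, odd rows from the second."""
    a, b, c = base.teachers
    out = []
    for first, second in ((a, b), (a, c), (b, c)):
        t = first.copy()
        t[1::2] = second[1::2]
        out.append(t)
    return TeacherSet(teachers=np.stack(out), orthogonal=False,
                      row_norm=base.row_norm)


def _composition_run(
    mode: Literal["task", "subtask"],
    seeds: Sequence[int],
    criterion: float,
    overrides: dict,
) -> dict[str, pd.DataFrame]:
    params = {**FIG2, **overrides}
    params.update(M=3, P=3)
    granularity = "per_row" if mode == "subtask" else "scalar"
    n_blocks_1 = params.pop("n_blocks_phase1", 30)
    n_blocks_2 = params.pop("n_blocks_phase2", 6)
    rows, gate_rows = [], []
    for seed in seeds:
        state, teachers = _build(
            seed, gate_granularity=granularity,
            **{k: params[k] for k in ("M", "P", "din", "dout", "tau_c", "tau_w",
                                      "lambda_norm", "lambda_nonneg")})
        composed = (_composed_sum_teachers(teachers) if mode == "task"
                    else _composed_row_teachers(teachers))
        for model_name, st in (("flexible", state),
                               ("forgetful", forgetful_baseline(state))):
            curr1 = Curriculum(block_length=params["block_length"],
                               n_blocks=n_blocks_1, seed=seed)
            traj1 = integrate(st, teachers, curr1)
            curr2 = Curriculum(block_length=params["block_length"],
                               n_blocks=n_blocks_2, seed=seed)
            traj2 = integrate(traj1.final_state, composed, curr2)
            for phase, traj in ((1, traj1), (2, traj2)):
                ttc = metrics.time_to_criterion(traj, criterion)
                rows += [dict(model=model_name, seed=seed, phase=phase, block=b,
                              task=(b % 3), time_to_criterion=v)
                         for b, v in enumerate(ttc)]
            # Gates at the end of each phase-2 block (last record per block).
            for b in range(n_blocks_2):
                sel = np.nonzero(traj2.block_index == b)[0]
                gate_rows.append(dict(model=model_name, seed=seed, block=b,
                                      task=(b % 3),
                                      gates=traj2.gates[sel[-1]].tolist()))
    per_block = pd.DataFrame(rows)
    phase2 = per_block[per_block.phase == 2]
    ratio = (phase2[phase2.model == "forgetful"]
             .groupby("seed")["time_to_criterion"].median()
             / phase2[phase2.model == "flexible"]
             .groupby("seed")["time_to_criterion"].median())
    summary = ratio.rename("forgetful_over_flexible_median_ttc").reset_index()
    return {"per_block": per_block, "gates": pd.DataFrame(gate_rows),
            "summary": summary}


def run_task_composition(seeds: Sequence[int] = range(5),
                         criterion: float = 0.1, **overrides):
    """Additive task composition (phase 2 cycles A+B, A+C, B+C)."""
    return _composition_run("task", seeds, criterion, overrides)


def run_subtask_composition(seeds: Sequence[int] = range(5),
                            criterion: float = 0.1, **overrides):
    """Row-level subtask composition with per-row gates."""
    return _composition_run("subtask", seeds, criterion, overrides)


@dataclass
class PhaseGrid:
    """Seed-averaged final total alignment over a 2-D hyperparameter grid at
    fixed total training time."""

    block_lengths: np.ndarray
    axis2_values: np.ndarray
    axis2: str  # 'lambda' or 'gate_lr'
    cells: np.ndarray  # (len(block_lengths), len(axis2_values)) means
    per_seed: np.ndarray  # (..., n_seeds)
    n_seeds: int
    total_time: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, tb in enumerate(self.block_lengths):
            for j, v in enumerate(self.axis2_values):
                rows.append(dict(block_length=tb, **{self.axis2: v},
                                 total_alignment=self.cells[i, j],
                                 n_seeds=self.n_seeds))
        return pd.DataFrame(rows)


def run_phase_diagram(
    block_lengths: Sequence[float],
    axis2_values: Sequence[float],
    axis2: Literal["lambda", "gate_lr"] = "lambda",
    total_time: float = 16.0,
    seeds: Sequence[int] = range(3),
    record_every: int = 100,
    **overrides,
) -> PhaseGrid:
    """Final matched total alignment over (block length) x (regularization
    multiplier or gate learning rate), all cells trained for the same total
    time (shorter blocks mean more switches, equal data).

    The interesting block lengths sit near the gate timescale: with the
    default model the forgetful-to-flexible transition happens for
    ``block_length`` between roughly 0.02 and 1."""
    params = {**FIG2, **overrides}
    block_lengths = np.asarray(list(block_lengths), dtype=float)
    axis2_arr = np.asarray(list(axis2_values), dtype=float)
    per_seed = np.full((len(block_lengths), len(axis2_arr), len(seeds)), np.nan)
    for j, v in enumerate(axis2_arr):
        cell_params = dict(params)
        if axis2 == "lambda":
            cell_params["lambda_norm"] = params["lambda_norm"] * v
            cell_params["lambda_nonneg"] = params["lambda_nonneg"] * v
        elif axis2 == "gate_lr":
            if v <= 0:
                raise InvalidConfigurationError("gate learning rate must be > 0")
            cell_params["tau_c"] = 1.0 / v
        else:
            raise InvalidConfigurationError(f"unknown axis2 {axis2!r}")
        for i, tb in enumerate(block_lengths):
            n_blocks = max(1, int(round(total_time / tb)))
            for s, seed in enumerate(seeds):
                state, teachers = _build(
                    seed, **{k: cell_params[k] for k in
                             ("M", "P", "din", "dout", "tau_c", "tau_w",
                              "lambda_norm", "lambda_nonneg")})
                curr = Curriculum(block_length=tb, n_blocks=n_blocks, seed=seed)
                try:
                    traj = integrate(state, teachers, curr,
                                     record_every=record_every)
                except Exception:
                    continue  # cell failure recorded as NaN, not fatal
                per_seed[i, j, s] = metrics.total_alignment(
                    traj.final_state.students, teachers)
    return PhaseGrid(
        block_lengths=block_lengths, axis2_values=axis2_arr, axis2=axis2,
        cells=np.nanmean(per_seed, axis=2), per_seed=per_seed,
        n_seeds=len(seeds), total_time=total_time,
    )


def run_switch_trend(
    seeds: Sequence[int] = range(10),
    window: float = 0.1,
    **overrides,
) -> dict[str, pd.DataFrame]:
    """Post-switch loss trend over blocks for both models.

    The mean loss over the first ``window`` fraction of each block is
    regressed on the block index; the flexible model speeds up with practice
    (negative slope) while the forgetful one does not.

    Blocks default to twice the regime-comparison length: the trend
    comparison presumes each task is mastered within its block (as in
    practiced task switching), which the forgetful control only achieves
    with the longer blocks.
    """
    params = {**FIG2, "block_length": 2.0, **overrides}
    if params["n_blocks"] < 20:
        raise InsufficientDataError("switch-trend analysis needs >= 20 blocks")
    slope_rows, block_rows = [], []
    for seed in seeds:
        state, teachers = _build(seed, **{k: params[k] for k in
                                          ("M", "P", "din", "dout", "tau_c",
                                           "tau_w", "lambda_norm",
                                           "lambda_nonneg")})
        curr = Curriculum(block_length=params["block_length"],
                          n_blocks=params["n_blocks"], seed=seed)
        for model_name, st in (("flexible", state),
                               ("forgetful", forgetful_baseline(state))):
            traj = integrate(st, teachers, curr)
            slope, sign = metrics.switch_speed_trend(traj, window)
            slope_rows.append(dict(model=model_name, seed=seed,
                                   slope=slope, sign=sign))
            for b in np.unique(traj.block_index):
                sel = traj.block_index == b
                t = traj.times[sel]
                in_win = t - t[0] <= window * traj.block_length
                block_rows.append(dict(
                    model=model_name, seed=seed, block=int(b),
                    post_switch_loss=float(np.mean(traj.task_loss[sel][in_win]))))
    slopes = pd.DataFrame(slope_rows)
    per_block = pd.DataFrame(block_rows)
    summary = (per_block.groupby(["model", "block"])["post_switch_loss"]
               .agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x))
                    if len(x) > 1 else 0.0).reset_index())
    return {"slopes": slopes, "per_block": per_block, "summary": summary}
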