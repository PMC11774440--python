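"""YAML run configuration, validation, and trajectory serialization.

A run is fully specified by a :class:`RunConfig` (model, curriculum, and
integration sections plus seeds); every saved artifact embeds the config
hash, seed, and package version so experiments replay exactly.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .curriculum import Curriculum, TeacherSet, make_teachers
from .dynamics import Trajectory
from .errors import InvalidConfigurationError
from .model import ModelState, init_state

__all__ = ["RunConfig", "load_config", "save_config", "config_hash",
           "build_run", "save_trajectory", "load_trajectory",
           "trajectory_to_frame"]


class ModelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    P: int = Field(2, ge=1)
    din: int = Field(32, ge=1)
    dout: int = Field(8, ge=1)
    tau_w: float = Field(1.3, gt=0)
    tau_c: float = Field(0.03, gt=0)
    lambda_norm: float = Field(1.0, ge=0)
    lambda_nonneg: float = Field(1.0, ge=0)
    norm_order: Literal[1, 2] = 1
    gate_granularity: Literal["scalar", "per_row"] = "scalar"
    sigma: float = Field(0.01, gt=0)


class CurriculumSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    M: int = Field(2, ge=1)
    block_length: float = Field(1.0, gt=0)
    n_blocks: int = Field(24, ge=0)
    task_order: Optional[list[int]] = None
    sampling_mode: Literal["expectation", "minibatch"] = "expectation"
    batch_size: int = Field(32, ge=1)
    row_norm: float = Field(1.0, gt=0)
    orthogonal: bool = True
    correlation: float = Field(0.0, ge=0, lt=1)


class IntegrationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    dt: Optional[float] = Field(None, gt=0)
    record_every: int = Field(10, ge=1)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    model: ModelSection = ModelSection()
    curriculum: CurriculumSection = CurriculumSection()
    integration: IntegrationSection = IntegrationSection()
    init_seed: int = 0
    data_seed: int = 0
    output_dir: Optional[str] = None

    def validate_joint(self) -> None:
        if self.curriculum.orthogonal and \
                self.curriculum.M * self.model.dout > self.model.din:
            raise InvalidConfigurationError(
                f"M*dout = {self.curriculum.M * self.model.dout} orthogonal "
                f"teacher rows do not fit in din = {self.model.din}"
            )
        if self.integration.dt is not None and \
                self.integration.dt > self.model.tau_c / 10:
            raise InvalidConfigurationError(
                f"integration.dt = {self.integration.dt} exceeds tau_c/10 = "
                f"{self.model.tau_c / 10}"
            )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are
    rejected with the offending key named."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise InvalidConfigurationError(str(exc)) from exc
    cfg.validate_joint()
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=False)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the full configuration."""
    payload = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def build_run(cfg: RunConfig, seed: int | None = None
              ) -> tuple[ModelState, TeacherSet, Curriculum]:
    """Instantiate model, teachers, and curriculum from a config.

    ``seed`` overrides both the initialization and data seeds, keeping a
    single knob for seed-averaged comparisons.
    """
    init_seed = cfg.init_seed if seed is None else seed
    data_seed = cfg.data_seed if seed is None else seed
    cfg.validate_joint()
    teachers = make_teachers(
        cfg.curriculum.M, cfg.model.din, cfg.model.dout,
        row_norm=cfg.curriculum.row_norm, orthogonal=cfg.curriculum.orthogonal,
        correlation=cfg.curriculum.correlation, seed=data_seed,
    )
    state = init_state(
        cfg.model.P, cfg.model.din, cfg.model.dout, seed=init_seed,
        sigma=cfg.model.sigma, gate_granularity=cfg.model.gate_granularity,
        tau_w=cfg.model.tau_w, tau_c=cfg.model.tau_c,
        lambda_norm=cfg.model.lambda_norm, lambda_nonneg=cfg.model.lambda_nonneg,
        norm_order=cfg.model.norm_order,
    )
    curriculum = Curriculum(
        block_length=cfg.curriculum.block_length,
        n_blocks=cfg.curriculum.n_blocks,
        task_order=tuple(cfg.curriculum.task_order)
        if cfg.curriculum.task_order else None,
        sampling_mode=cfg.curriculum.sampling_mode,
        batch_size=cfg.curriculum.batch_size,
        seed=data_seed,
    )
    return state, teachers, curriculum


def save_trajectory(traj: Trajectory, path, cfg: RunConfig | None = None,
                    seed: int | None = None) -> None:
    """Lossless archive of a trajectory (compressed arrays + metadata)."""
    meta = dict(traj.meta)
    meta.update(version=__version__, seed=seed,
                config_hash=config_hash(cfg) if cfg is not None else None,
                block_length=traj.block_length)
    np.savez_compressed(
        path,
        times=traj.times, task_loss=traj.task_loss, gates=traj.gates,
        alignments=traj.alignments, update_norms=traj.update_norms,
        student_norms=traj.student_norms, block_index=traj.block_index,
        final_students=traj.final_state.students,
        final_gates=traj.final_state.gates,
        final_hyper=np.array([traj.final_state.tau_w, traj.final_state.tau_c,
                              traj.final_state.lambda_norm,
                              traj.final_state.lambda_nonneg,
                              float(traj.final_state.norm_order)]),
        gate_granularity=np.array(traj.final_state.gate_granularity),
        meta_json=np.array(json.dumps(meta)),
    )


def load_trajectory(path, expect_config: RunConfig | None = None) -> Trajectory:
    """Reload a trajectory archive; a config-hash mismatch is reported as a
    warning."""
    with np.load(path) as npz:
        meta = json.loads(str(npz["meta_json"]))
        if expect_config is not None:
            expected = config_hash(expect_config)
            if meta.get("config_hash") != expected:
                warnings.warn(
                    f"config hash mismatch: archive {meta.get('config_hash')} "
                    f"vs expected {expected}", stacklevel=2)
        h = npz["final_hyper"]
        final_state = ModelState(
            students=npz["final_students"], gates=npz["final_gates"],
            tau_w=float(h[0]), tau_c=float(h[1]), lambda_norm=float(h[2]),
            lambda_nonneg=float(h[3]), norm_order=int(h[4]),
            gate_granularity=str(npz["gate_granularity"]),
        )
        return Trajectory(
            times=npz["times"], task_loss=npz["task_loss"], gates=npz["gates"],
            alignments=npz["alignments"], update_norms=npz["update_norms"],
            student_norms=npz["student_norms"],
            block_index=npz["block_index"],
            block_length=float(meta["block_length"]),
            final_state=final_state, meta=meta,
        )


def trajectory_to_frame(traj: Trajectory) -> "pd.DataFrame":
    """Tidy per-record table (one row per recorded time)."""
    import pandas as pd

    P = traj.student_norms.shape[1] if traj.student_norms.size else 0
    data = {
        "time": traj.times,
        "block": traj.block_index,
        "task_loss": traj.task_loss,
        "update_norm_w": traj.update_norms[:, 0] if len(traj) else [],
        "update_norm_c": traj.update_norms[:, 1] if len(traj) else [],
    }
    gates2d = traj.gates.reshape(len(traj), -1) if len(traj) else traj.gates
    for p in range(gates2d.shape[1] if len(traj) else 0):
        data[f"gate_{p}"] = gates2d[:, p]
    for p in range(P):
        data[f"student_norm_{p}"] = traj.student_norms[:, p]
    return pd.DataFrame(data)
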