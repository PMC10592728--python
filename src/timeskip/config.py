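"""Run configuration: schema-validated YAML/JSON configs and seed splitting."""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .surrogates import ANNEAL_HORIZON_DEFAULT
from .tasks import TASK_IDS
from .training import TrainConfig, desk_preset

__all__ = ["RunConfig", "load_config", "dump_config", "split_seed"]


class RunConfig(BaseModel):
    """Validated union of training, surrogate and task settings.

    Unknown keys are rejected; defaults follow the full-scale protocol
    unless ``desk_preset`` is set, in which case the small-scale preset
    values are used as the baseline and explicit fields override them.
    """

    model_config = ConfigDict(extra="forbid")

    task: str = "go"
    method: str = "base"
    theta: int = Field(10, ge=1)
    beta0: float = Field(0.5, gt=0.0, le=1.0)
    step_count: int = Field(5, ge=1)
    horizon: int = Field(ANNEAL_HORIZON_DEFAULT, ge=1)
    strategic: bool = False
    cohort_size: int = Field(100, ge=1)
    batch_size: int = Field(64, ge=1)
    learning_rate: float = Field(1e-3, gt=0.0)
    max_training_steps: int = Field(40_000, ge=1)
    eval_every: int = Field(100, ge=1)
    eval_batch: int = Field(512, ge=1)
    criterion: float = Field(0.99, gt=0.0, le=1.0)
    seed: int = 0
    n_units: int = Field(256, ge=2)
    sigma_noise: float = Field(0.01, ge=0.0)
    dt: float = Field(5.0, gt=0.0)
    grad_clip: float = Field(1.0, gt=0.0)
    timing: dict[str, int] | None = None
    n_trials: int = Field(5, ge=1)
    desk_preset: bool = False
    out_dir: str = "runs"

    @model_validator(mode="after")
    def _check(self):
        if self.task not in TASK_IDS + ("rulerev",):
            raise ValueError(f"unknown task {self.task!r}")
        if self.method not in ("base", "cd", "sctt", "dasc"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method != "base" and self.max_training_steps < self.horizon:
            raise ValueError(
                "max_training_steps must be >= the anneal horizon"
            )
        return self

    def to_train_config(self) -> TrainConfig:
        explicit = self.model_dump(exclude_unset=True)
        if self.desk_preset:
            base = desk_preset(self.task, self.method)
        else:
            base = TrainConfig(task_id=self.task, method=self.method)
        rename = {"task": "task_id", "seed": "seed_base"}
        for k, v in explicit.items():
            if k in ("desk_preset", "out_dir"):
                continue
            setattr(base, rename.get(k, k), v)
        base.__post_init__()
        return base


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run config."""
    path = Path(path)
    text = path.read_text()
    data = (json.loads(text) if path.suffix == ".json"
            else yaml.safe_load(text))
    if data is None:
        data = {}
    return RunConfig(**data)


def dump_config(cfg: RunConfig, path) -> None:
    """Echo the fully resolved config (provenance for reruns)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg.model_dump(), indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))


def split_seed(seed: int, *labels) -> np.random.SeedSequence:
    """Derive an independent child seed stream from a global seed.

    Labels are hashed into the spawn key so that, e.g.,
    ``split_seed(s, "network", 7)`` and ``split_seed(s, "trial", 7)`` give
    uncorrelated streams from one user-facing seed.
    """
    key = [zlib.crc32(str(l).encode()) for l in labels]
    return np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))
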