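"""Run configuration, validation and seed management.

Every CLI run is driven by a YAML config validated against a versioned
pydantic schema; the resolved config, the seed, the package version and the
functional-group vocabulary hash are persisted next to every run's outputs
so results can be traced back to their exact inputs.
"""

from __future__ import annotations

import hashlib
import json
import random
from pathlib import Path
from typing import Any, Literal

import numpy as np
import yaml
from pydantic import BaseModel, Field, ValidationError

from .exceptions import ConfigurationError

SCHEMA_VERSION = 1


class ModelSection(BaseModel):
    d_model: int = 64
    n_layers: int = 2
    n_heads: int = 4
    K_bins: int = 16
    mag_hidden: int = 32
    max_len: int = 256
    dropout: float = 0.0
    pocket_dim: int = 0


class TrainSection(BaseModel):
    epochs: int = 400
    lr: float = 3e-3
    batch_size: int = 32
    loss_target: float = 0.05


class RLSection(BaseModel):
    steps: int = 40
    batch_size: int = 8
    sigma: float = 120.0
    lr: float = 1e-4
    temperature: float = 1.0


class RunConfig(BaseModel):
    """Top-level run configuration (one YAML per stage)."""

    schema_version: int = SCHEMA_VERSION
    stage: Literal[
        "annotate", "encode", "fixtures", "pretrain", "finetune", "rl",
        "generate", "evaluate",
    ]
    seed: int = 0
    out_dir: str = "runs/latest"
    log_level: str = "INFO"
    data: dict[str, Any] = Field(default_factory=dict)
    model: ModelSection = Field(default_factory=ModelSection)
    train: TrainSection = Field(default_factory=TrainSection)
    rl: RLSection = Field(default_factory=RLSection)


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        cfg = RunConfig(**raw)
    except ValidationError as exc:
        raise ConfigurationError(f"invalid run config {path}: {exc}") from exc
    if cfg.schema_version != SCHEMA_VERSION:
        raise ConfigurationError(
            f"config schema_version {cfg.schema_version} != supported {SCHEMA_VERSION}"
        )
    return cfg


def set_global_seed(seed: int) -> None:
    """Seed the process-wide RNGs; module-level code derives from this."""
    if seed < 0:
        raise ConfigurationError("seed must be non-negative")
    random.seed(seed)
    np.random.seed(seed % (2**32))


def derive_seed(seed: int, label: str) -> int:
    """Stable per-purpose sub-seed (< 2^31) derived from a global seed."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def write_run_manifest(
    out_dir: str | Path,
    config: RunConfig | dict,
    fg_vocab_hash: str | None = None,
) -> Path:
    """Persist the resolved config + provenance next to the run outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    resolved = config.model_dump() if isinstance(config, RunConfig) else dict(config)
    manifest = {
        "config": resolved,
        "seed": resolved.get("seed"),
        "package_version": __version__,
        "fg_vocab_hash": fg_vocab_hash,
    }
    path = out_dir / "run_manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
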