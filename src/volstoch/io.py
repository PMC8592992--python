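"""Configuration parsing and file I/O shared by the CLI and library users.

Configs are YAML with a flat JSON-compatible schema: an ``experiment`` key
naming a registered design plus optional ``n_sims``, ``n_particles``,
``seed``, ``full`` and an ``overrides`` mapping, and/or a ``model`` block
holding :class:`~volstoch.inference.ModelParams` fields for filter runs on
user-supplied outcome files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .experiments import EXPERIMENT_REGISTRY, ExperimentConfig
from .inference import ModelParams

__all__ = [
    "RunConfig",
    "parse_config",
    "read_outcomes_csv",
    "write_outcomes_csv",
    "write_metadata",
]

_TOP_LEVEL_KEYS = {
    "experiment", "n_sims", "n_particles", "seed", "full", "overrides", "model",
}


@dataclass
class RunConfig:
    """Fully resolved run configuration."""

    experiment: Optional[str] = None
    n_sims: Optional[int] = None
    n_particles: int = 100
    seed: int = 0
    full: bool = False
    overrides: dict = field(default_factory=dict)
    model: Optional[ModelParams] = None

    def to_experiment_config(self) -> ExperimentConfig:
        if self.experiment is None:
            raise ValueError("config does not name an experiment")
        return ExperimentConfig(
            name=self.experiment, n_sims=self.n_sims,
            n_particles=self.n_particles, seed=self.seed,
            full=self.full, overrides=dict(self.overrides),
        )

    def to_dict(self) -> dict:
        d = {
            "experiment": self.experiment, "n_sims": self.n_sims,
            "n_particles": self.n_particles, "seed": self.seed,
            "full": self.full, "overrides": dict(self.overrides),
        }
        if self.model is not None:
            d["model"] = self.model.to_dict()
        return d


def parse_config(source) -> RunConfig:
    """Parse and validate a YAML config (path, file object or dict).

    Unknown keys and out-of-range values raise ``ValueError`` naming the
    offending key.
    """
    if isinstance(source, dict):
        raw = dict(source)
    else:
        path = Path(source)
        raw = yaml.safe_load(path.read_text())
        if raw is None:
            raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = set(raw) - _TOP_LEVEL_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    experiment = raw.get("experiment")
    if experiment is not None and experiment not in EXPERIMENT_REGISTRY:
        raise ValueError(
            f"unknown experiment {experiment!r}; available: "
            f"{sorted(EXPERIMENT_REGISTRY)}"
        )
    model = None
    if "model" in raw and raw["model"] is not None:
        try:
            model = ModelParams.from_dict(raw["model"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid model block: {exc}") from exc
    cfg = RunConfig(
        experiment=experiment,
        n_sims=raw.get("n_sims"),
        n_particles=int(raw.get("n_particles", 100)),
        seed=int(raw.get("seed", 0)),
        full=bool(raw.get("full", False)),
        overrides=dict(raw.get("overrides") or {}),
        model=model,
    )
    if cfg.n_sims is not None and cfg.n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if cfg.n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    return cfg


def read_outcomes_csv(path) -> np.ndarray:
    """Read a one-outcome-per-trial CSV (columns: trial, outcome)."""
    df = pd.read_csv(path)
    if "outcome" not in df.columns:
        raise ValueError("outcomes CSV must have an 'outcome' column")
    return df["outcome"].to_numpy(dtype=float)


def write_outcomes_csv(path, outcomes, x_true=None, v_true=None, s_true=None) -> None:
    """Write an outcome series as a headered CSV (trial is 1-based)."""
    outcomes = np.asarray(outcomes, dtype=float)
    data = {"trial": np.arange(1, outcomes.size + 1), "outcome": outcomes}
    for name, arr in (("x_true", x_true), ("v_true", v_true), ("s_true", s_true)):
        if arr is not None:
            data[name] = np.asarray(arr, dtype=float)
    pd.DataFrame(data).to_csv(path, index=False)


def write_metadata(path, config: dict, extra: Optional[dict] = None) -> None:
    """JSON sidecar recording the resolved config (and software version)."""
    from . import __version__

    payload = {"config": config, "version": __version__}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
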