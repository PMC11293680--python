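"""Configuration, seeding, and result serialization.

Runs are configured by a small YAML/JSON mapping validated into
:class:`ExperimentConfig`.  Size parameters default to the *paper* scale
(10,000 agents x 5,000 generations x 500 trials for single-task runs; 1,000
agents and 100 simulations for multiple-task runs); the *desk* preset is a
scaled-down configuration suitable for a workstation, and *smoke* is a
seconds-long functional check.  A single master seed fans out into labeled
sub-streams so that scaling one component never reshuffles another's
randomness.  Outputs are tidy CSV tables plus a JSON manifest that echoes
the configuration and seed, which together reproduce the run bit-for-bit
(only the manifest timestamp varies).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "EXPERIMENTS",
    "SCALE_PRESETS",
    "ExperimentConfig",
    "RunManifest",
    "load_config",
    "config_from_mapping",
    "derive_substreams",
    "write_results",
]

EXPERIMENTS = ("single_task", "multiple_task", "assay", "heatmap")

#: Size presets per scale and experiment family.  ``replicates`` means
#: independent evolutionary runs (per task for single-task, simulations per
#: condition for multiple-task).
SCALE_PRESETS: dict[str, dict[str, dict[str, int]]] = {
    "paper": {
        "single_task": dict(n_agents=10_000, n_generations=5_000, n_trials=500, replicates=10),
        "multiple_task": dict(n_agents=1_000, n_generations=5_000, n_trials=500, replicates=100),
    },
    "desk": {
        "single_task": dict(n_agents=500, n_generations=500, n_trials=200, replicates=5),
        "multiple_task": dict(n_agents=200, n_generations=300, n_trials=200, replicates=10),
    },
    "smoke": {
        "single_task": dict(n_agents=50, n_generations=20, n_trials=50, replicates=2),
        "multiple_task": dict(n_agents=50, n_generations=20, n_trials=50, replicates=2),
    },
}


@dataclass
class ExperimentConfig:
    """Validated run configuration with scale defaults filled in."""

    experiment: str
    scale: str = "paper"
    n_agents: int | None = None
    n_trials: int | None = None
    n_generations: int | None = None
    replicates: int | None = None
    n_risk_seeking: int = 2
    variant: str = "asymmetric"
    seed: int = 0
    out_dir: str = "results"
    task: str | None = None
    d_magnitude: float = 20.0
    beta: float = 0.25
    step: float = 0.01
    repeats: int = 1
    assay_window: int = 100

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"experiment must be one of {EXPERIMENTS}, got {self.experiment!r}"
            )
        if self.scale not in SCALE_PRESETS:
            raise ValueError(f"unknown scale preset: {self.scale!r}")
        family = "single_task" if self.experiment in ("single_task", "heatmap") else "multiple_task"
        preset = SCALE_PRESETS[self.scale][family]
        for name in ("n_agents", "n_trials", "n_generations", "replicates"):
            if getattr(self, name) is None:
                setattr(self, name, preset[name])
        for name in ("n_agents", "n_trials", "n_generations", "replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.n_risk_seeking <= 4:
            raise ValueError("n_risk_seeking must be between 0 and 4")
        if self.experiment in ("single_task", "heatmap") and not self.task:
            raise ValueError(f"experiment {self.experiment!r} requires a task label")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def config_from_mapping(mapping: Mapping) -> ExperimentConfig:
    """Validate a parsed configuration mapping, naming any unknown field."""
    if not isinstance(mapping, Mapping):
        raise ValueError("configuration must be a mapping")
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    for key in mapping:
        if key not in known:
            raise ValueError(f"unknown config field: {key!r}")
    if "experiment" not in mapping:
        raise ValueError("config must name an experiment")
    return ExperimentConfig(**dict(mapping))


def load_config(path: str | Path) -> ExperimentConfig:
    """Read and validate a YAML or JSON experiment configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return config_from_mapping(data)


def derive_substreams(
    master_seed: int, labels: list[str]
) -> dict[str, np.random.Generator]:
    """Deterministic, collision-resistant random stream per label.

    Each label is hashed (SHA-256) and combined with the master seed into a
    :class:`numpy.random.SeedSequence`, so streams for different labels are
    statistically independent and adding a label never perturbs the others.
    """
    if len(set(labels)) != len(labels):
        raise ValueError("substream labels must be unique")
    streams = {}
    for label in labels:
        digest = hashlib.sha256(label.encode()).digest()
        words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
        streams[label] = np.random.default_rng(
            np.random.SeedSequence([int(master_seed), *words])
        )
    return streams


@dataclass
class RunManifest:
    """What a finished run wrote, and everything needed to reproduce it."""

    config: dict
    master_seed: int
    package_version: str
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    files: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    *,
    config: ExperimentConfig | None = None,
    seed: int | None = None,
    extra: dict | None = None,
) -> list[Path]:
    """Write CSV tables plus a JSON manifest; return the file inventory.

    CSV contents are a pure function of the run (re-running with the same
    seed yields byte-identical tables); only the manifest timestamp differs.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, table in tables.items():
        path = out / f"{name}.csv"
        table.to_csv(path, index=False)
        written.append(path)
    manifest = RunManifest(
        config=config.to_dict() if config is not None else {},
        master_seed=seed if seed is not None else (config.seed if config else 0),
        package_version=__version__,
        files=[p.name for p in written],
        extra=extra or {},
    )
    manifest_path = out / "manifest.json"
    manifest_path.write_text(manifest.to_json())
    written.append(manifest_path)
    return written
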