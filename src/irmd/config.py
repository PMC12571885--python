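"""Structured run configuration (YAML) for the CLI and the learning loop.

All stochastic stages take explicit seeds — there is no implicit global
randomness anywhere in the package.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml


@dataclass
class RunConfig:
    """Active-learning / MD run parameters.

    Defaults follow the standard protocol: 0.5 fs steps, Langevin friction
    0.01 fs⁻¹, exploration at 300/500/700 K, 5 structures acquired per
    temperature (15 per molecule per iteration), an ensemble of 3 models
    retrained from scratch, 80:20 train/test split, stopping at a harmonic
    frequency MAE of 5 cm⁻¹ or 40 iterations.
    """

    # molecules
    n_molecules: int = 8
    size_range: Tuple[int, int] = (2, 5)
    # MD
    temperatures: Tuple[float, ...] = (300.0, 500.0, 700.0)
    timestep_fs: float = 0.5
    friction: float = 0.01
    explore_ps: float = 5.0
    thermalize_ps: float = 5.0
    production_ps: float = 50.0
    record_every: int = 10
    # committee / acquisition
    committee_size: int = 3
    per_temperature: int = 5
    frames_per_mode: int = 10
    sample_t_ref: float = 300.0
    split_ratio: float = 0.8
    abort_threshold: float = 0.5
    # stopping
    mae_threshold_cm1: float = 5.0
    max_iterations: int = 40
    # randomness / paths
    seed: int = 0
    workdir: Optional[str] = None

    def __post_init__(self) -> None:
        counts = {
            "n_molecules": self.n_molecules,
            "committee_size": self.committee_size,
            "per_temperature": self.per_temperature,
            "frames_per_mode": self.frames_per_mode,
            "max_iterations": self.max_iterations,
            "record_every": self.record_every,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must be in (0, 1)")
        if self.timestep_fs <= 0 or self.explore_ps <= 0:
            raise ValueError("timestep and exploration length must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f: data[f] for f in data if f in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        for tup_field in ("size_range", "temperatures"):
            setattr(cfg, tup_field, tuple(getattr(cfg, tup_field)))
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["size_range"] = list(self.size_range)
        d["temperatures"] = list(self.temperatures)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
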