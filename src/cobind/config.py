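"""Run configuration with defaults matching the published protocol."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    expand_bp: int = 50
    min_sites: int = 3
    eta: float = 0.1
    max_iter: int = 2000
    seeds: tuple[int, ...] = (1, 2, 3)
    z_cut: float = 1.0
    group_cutoff: float = 0.5
    match_threshold: float = 0.5
    usage_z_axis: str = "region"
    n_perm: int = 200
    rf_n_estimators: int = 500
    rf_seeds: tuple[int, ...] = (1, 2, 3, 4, 5)
    rf_test_size: float = 0.2

    def __post_init__(self) -> None:
        if self.expand_bp < 0:
            raise ValueError("expand_bp must be >= 0")
        if self.min_sites < 1:
            raise ValueError("min_sites must be >= 1")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        self.seeds = tuple(self.seeds)
        self.rf_seeds = tuple(self.rf_seeds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["seeds"] = list(self.seeds)
        data["rf_seeds"] = list(self.rf_seeds)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
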