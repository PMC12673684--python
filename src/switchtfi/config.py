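"""Run configuration: one dataclass per pipeline stage, YAML round-trip.

A run is fully described by a single mapping with sections ``impute``,
``weight``, ``test``, ``rank`` and ``validate`` plus the input paths;
every run writes its fully resolved configuration next to its outputs so
results are self-describing.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["ImputeConfig", "WeightConfig", "TestConfig", "RankConfig",
           "ValidateConfig", "RunConfig"]


@dataclass
class ImputeConfig:
    enabled: bool = True
    t: int = 1
    k: int | None = None
    ka: int = 4
    decay: float = 2.0
    n_pca: int | None = 20


@dataclass
class WeightConfig:
    min_coexpression_fraction: float = 0.20


@dataclass
class TestConfig:
    n_permutations: int = 1000
    alpha: float = 0.05
    seed: int = 0
    empty_class_policy: str = "omit"


@dataclass
class RankConfig:
    mode: str = "pagerank"
    damping: float = 0.85
    top_k: int = 10


@dataclass
class ValidateConfig:
    n_samples: int = 1000
    seed: int = 0


_SECTIONS = {
    "impute": ImputeConfig,
    "weight": WeightConfig,
    "test": TestConfig,
    "rank": RankConfig,
    "validate": ValidateConfig,
}


@dataclass
class RunConfig:
    """Paths plus per-stage settings for one end-to-end run."""

    counts: str = ""
    grn: str = ""
    labels: str = ""
    out_dir: str = "switchtfi_out"
    matrix_format: str = "dense_csv"
    orientation: str = "cells_by_genes"
    genes_path: str | None = None
    cells_path: str | None = None
    progenitor_token: str = "progenitor"
    offspring_token: str = "offspring"
    impute: ImputeConfig = field(default_factory=ImputeConfig)
    weight: WeightConfig = field(default_factory=WeightConfig)
    test: TestConfig = field(default_factory=TestConfig)
    rank: RankConfig = field(default_factory=RankConfig)
    validate: ValidateConfig = field(default_factory=ValidateConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = dict(data)
        for name, section_cls in _SECTIONS.items():
            if name in kwargs and isinstance(kwargs[name], dict):
                known = {f.name for f in fields(section_cls)}
                unknown = set(kwargs[name]) - known
                if unknown:
                    raise ValueError(f"unknown key(s) in section '{name}': {sorted(unknown)}")
                kwargs[name] = section_cls(**kwargs[name])
        known = {f.name for f in fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
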