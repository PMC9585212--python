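"""Pipeline configuration and reproducible per-stage seeding.

One master seed lives in the config; every stochastic stage derives its own
sub-seed by hashing the stage name together with the master seed, so any
stage can be re-run in isolation and reproduce its output.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError

GENOME_WIDE_P = 5e-8
SUGGESTIVE_P = 1e-6

DEFAULT_COVARIATES = ["age", "sex", "array"] + [f"pc{i}" for i in range(1, 11)]


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic sub-seed for a named stage (< 2**31).

    SHA-256 of the stage name is folded with the master seed so that stages
    draw from independent streams while remaining individually reproducible.
    """
    digest = hashlib.sha256(stage.encode("utf-8")).digest()
    stage_int = int.from_bytes(digest[:4], "big")
    return (int(master_seed) ^ stage_int) % (2**31 - 1)


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, stage))


@dataclass
class QCThresholds:
    """Variant-level exclusion thresholds (strict inequalities on the removal side)."""

    max_missing_rate: float = 0.05
    min_maf: float = 0.01
    min_hwe_p: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("max_missing_rate", "min_maf", "min_hwe_p"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigError(f"QC threshold {name}={v} must be in (0, 1]")


@dataclass
class ClumpParams:
    p_threshold: float = GENOME_WIDE_P
    r2_threshold: float = 0.1
    merge_window: int = 250_000  # bp; leads closer than this merge into one locus

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ConfigError(f"clump p_threshold must be in (0, 1], got {self.p_threshold}")
        if not (0 < self.r2_threshold <= 1):
            raise ConfigError(f"clump r2_threshold must be in (0, 1], got {self.r2_threshold}")
        if self.merge_window < 0:
            raise ConfigError(f"clump merge_window must be >= 0, got {self.merge_window}")


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; serialisable to/from YAML."""

    seed: int = 2022
    n_strata: int = 4
    # "auto" selects the least-Spearman-correlated stratum pair;
    # or a fixed pair like ["Q1", "Q4"].
    stratum_pair: object = "auto"
    covariates: list = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    qc: QCThresholds = field(default_factory=QCThresholds)
    clump: ClumpParams = field(default_factory=ClumpParams)
    genome_wide_p: float = GENOME_WIDE_P
    suggestive_p: float = SUGGESTIVE_P
    simulation: dict = field(default_factory=dict)  # passed to SimulationConfig

    def __post_init__(self) -> None:
        if self.n_strata < 2:
            raise ConfigError(f"n_strata must be >= 2, got {self.n_strata}")
        for name in ("genome_wide_p", "suggestive_p"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigError(f"{name}={v} must be in (0, 1]")
        if self.stratum_pair != "auto":
            pair = list(self.stratum_pair)
            if len(pair) != 2 or pair[0] == pair[1]:
                raise ConfigError(f"stratum_pair must be 'auto' or two distinct labels, got {pair}")
            self.stratum_pair = pair

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "qc" in d and isinstance(d["qc"], dict):
            d["qc"] = QCThresholds(**d["qc"])
        if "clump" in d and isinstance(d["clump"], dict):
            d["clump"] = ClumpParams(**d["clump"])
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
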