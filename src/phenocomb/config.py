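"""Run configuration: YAML parsing, validation and hashing.

Every output file written by the pipeline carries the configuration hash
and master seed in its header, so two runs under equal configurations are
byte-identical and any artifact can be traced to its settings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import List, Optional, Tuple

import yaml

from .simgen import COMPONENT_NAMES, ComponentArchitecture, default_architecture

__all__ = ["RunConfig", "ConfigError", "load_config", "default_config_dict"]


class ConfigError(ValueError):
    """Named configuration validation failure."""


@dataclass
class ArchitectureConfig:
    h2: Optional[List[float]] = None
    prevalence: Optional[List[float]] = None
    genetic_corr_internal: float = 0.9
    genetic_corr_external: float = 0.75
    env_corr_internal: float = 0.5
    exclusion_rate: float = 0.0245

    def build(self) -> ComponentArchitecture:
        return default_architecture(
            h2=self.h2,
            prevalence=self.prevalence,
            genetic_corr_internal=self.genetic_corr_internal,
            genetic_corr_external=self.genetic_corr_external,
            env_corr_internal=self.env_corr_internal,
            exclusion_rate=self.exclusion_rate,
        )


@dataclass
class SimulationConfig:
    n: int = 4000
    m: int = 1500
    n_chrom: int = 10
    maf_bounds: Tuple[float, float] = (0.05, 0.5)
    bp_spacing: int = 300_000
    ld_block_size: int = 4
    ld_copy_prob: float = 0.9
    missing_rate: float = 0.0
    seed: int = 11
    external_traits: List[str] = field(default_factory=lambda: ["external_md"])
    n_external: int = 20_000
    architecture: ArchitectureConfig = field(default_factory=ArchitectureConfig)


@dataclass
class EstimationConfig:
    k_policy: str = "sample_prevalence_pre_exclusion"
    mhc_chrom: int = 6
    mhc_start_bp: int = 28_866_528
    mhc_end_bp: int = 33_775_446
    n_blocks: int = 200
    ld_window_bp: int = 1_000_000
    jackknife_seed: int = 1234


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    estimation: EstimationConfig = field(default_factory=EstimationConfig)
    components: List[str] = field(default_factory=lambda: list(COMPONENT_NAMES))
    outdir: str = "phenocomb_out"

    def validate(self) -> None:
        s = self.simulation
        if s.n < 2 or s.m < 2:
            raise ConfigError("simulation.n and simulation.m must both be >= 2")
        if not (0 < s.maf_bounds[0] <= s.maf_bounds[1] <= 0.5):
            raise ConfigError("simulation.maf_bounds must satisfy 0 < lo <= hi <= 0.5")
        if s.n_external < 100:
            raise ConfigError("simulation.n_external must be >= 100")
        e = self.estimation
        if e.n_blocks < 2:
            raise ConfigError("estimation.n_blocks must be >= 2")
        if e.k_policy != "sample_prevalence_pre_exclusion":
            raise ConfigError(
                f"unknown estimation.k_policy {e.k_policy!r}; the supported policy "
                "is 'sample_prevalence_pre_exclusion'"
            )
        if len(set(self.components)) != len(self.components):
            raise ConfigError("phenotype components must be unique")
        try:
            s.architecture.build()
        except ValueError as exc:
            raise ConfigError(f"invalid architecture: {exc}") from exc

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _merge(dc, data: dict, path: str):
    for key, val in data.items():
        if not hasattr(dc, key):
            raise ConfigError(f"unknown config key {path}{key}")
        cur = getattr(dc, key)
        if isinstance(val, dict) and hasattr(cur, "__dataclass_fields__"):
            _merge(cur, val, f"{path}{key}.")
        else:
            if key == "maf_bounds" and val is not None:
                val = tuple(float(v) for v in val)
            setattr(dc, key, val)


def load_config(path_or_dict) -> RunConfig:
    """Build and validate a RunConfig from a YAML path or a nested dict."""
    if isinstance(path_or_dict, dict):
        data = path_or_dict
    else:
        with open(path_or_dict) as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    cfg = RunConfig()
    _merge(cfg, data, "")
    cfg.validate()
    return cfg


def default_config_dict() -> dict:
    return RunConfig().to_dict()
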