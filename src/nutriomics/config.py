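"""Pipeline configuration.

A single structured YAML file drives the end-to-end run; command-line
flags override file values.  All thresholds mirror the per-stage defaults:
BH level 0.01 for the gene layer and 0.05 for the miRNA layer, DMP rule
(adjusted p < 0.1, |Δβ| >= 0.10), DMR rule (>= 3 probes within 1 kb,
region FDR 5%, peak |Δβ| > 0.10), consensus threshold of 5 of 9 target
prediction algorithms, and a top-40 pathway comparison.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .containers import ConfigError
from .simdata import SimConfig


@dataclass
class PipelineConfig:
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)

    # which layers to run
    expression: bool = True
    mirna: bool = True
    methylation: bool = True

    # per-layer thresholds
    alpha_genes: float = 0.01
    alpha_mirna: float = 0.05
    dmp_p_adj_max: float = 0.1
    dmp_min_abs_delta: float = 0.10
    dmr_max_gap: int = 1000
    dmr_min_probes: int = 3
    dmr_fdr_max: float = 0.05
    dmr_min_peak_delta: float = 0.10
    max_detection_p: float = 0.01
    min_algorithms: int = 5
    top_k: int = 40
    use_mvalues: bool = False

    outdir: str | None = None
    verbosity: int = 1

    def validate(self) -> None:
        for name in ("alpha_genes", "alpha_mirna", "dmp_p_adj_max", "dmr_fdr_max",
                     "max_detection_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")
        for name in ("dmp_min_abs_delta", "dmr_min_peak_delta"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigError(f"{name} must lie in [0, 1), got {v}")
        if self.dmr_max_gap < 1:
            raise ConfigError(f"dmr_max_gap must be >= 1, got {self.dmr_max_gap}")
        if self.dmr_min_probes < 1:
            raise ConfigError(f"dmr_min_probes must be >= 1, got {self.dmr_min_probes}")
        if not 1 <= self.min_algorithms <= 9:
            raise ConfigError(f"min_algorithms must lie in [1, 9], got {self.min_algorithms}")
        if self.top_k < 1:
            raise ConfigError(f"top_k must be >= 1, got {self.top_k}")
        self.sim.validate()

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Copy with the global seed propagated into the simulator."""
        return replace(self, seed=seed, sim=replace(self.sim, seed=seed))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim_data = data.pop("sim", {}) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        sim_known = {f.name for f in fields(SimConfig)}
        sim_unknown = set(sim_data) - sim_known
        if sim_unknown:
            raise ConfigError(f"unknown sim config keys: {sorted(sim_unknown)}")
        cfg = cls(sim=SimConfig(**sim_data), **data)
        if "seed" in data and "seed" not in sim_data:
            cfg = cfg.with_seed(data["seed"])
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def override(self, **kwargs) -> "PipelineConfig":
        """Apply non-None keyword overrides (CLI flags beat file values)."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        cfg = replace(self, **updates)
        if "seed" in updates:
            cfg = cfg.with_seed(updates["seed"])
        return cfg


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    cfg = PipelineConfig.from_yaml(path) if path else PipelineConfig()
    cfg = cfg.override(**overrides)
    cfg.validate()
    return cfg
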