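"""Run configuration: a flat, validated key-value record (YAML on disk)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Parameters for an end-to-end pipeline run on a simulated genome.

    Every field has a default; unknown keys in a config file are
    rejected.  CLI flags override config-file values.
    """

    out_dir: str = "hybriseg_run"
    seed: int = 1

    # synthetic genome
    n_chromosomes: int = 16
    chromosome_length: int = 60_000
    coding_fraction: float = 0.7
    divergence_coding: float = 0.20
    divergence_noncoding: float = 0.38
    ploidy_min: int = 0
    ploidy_max: int = 3
    n_translocations: int = 6
    unit_depth: float = 50.0
    dispersion: float = 0.0

    # depth / copy number
    region_size: int = 10_000
    mismatch_cutoff_a: int = 0
    mismatch_cutoff_b: int = 5
    rounding_tolerance: float = 0.3

    # detection
    bin_size: int = 1000
    min_segment: int = 10_000
    telomere_zone: int = 20_000

    # chimeric genes
    junction_rule: str = "region_start"

    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        for name in (
            "n_chromosomes", "chromosome_length", "region_size", "bin_size",
            "min_segment", "n_translocations", "telomere_zone",
        ):
            if getattr(self, name) < 0 or (
                name not in ("n_translocations", "telomere_zone")
                and getattr(self, name) == 0
            ):
                raise ValueError(f"{name} must be positive")
        for name in ("coding_fraction", "divergence_coding", "divergence_noncoding"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.ploidy_min <= self.ploidy_max <= 3:
            raise ValueError("ploidy range must satisfy 0 <= min <= max <= 3")
        if self.unit_depth <= 0:
            raise ValueError("unit_depth must be positive")
        if self.junction_rule not in ("region_start", "region_end", "midpoint"):
            raise ValueError("unknown junction_rule")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must hold a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
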