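"""Pipeline configuration: YAML loading, validation, paper-default thresholds."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class Thresholds:
    breadth: float = 0.75
    min_group_reads: int = 4
    activity_window_bp: int = 10_000
    host_p: float = 0.05
    dedup_identity: float = 0.95
    dedup_coverage: float = 0.95
    known_species_ani: float = 0.95
    differential_alpha: float = 0.05
    # RdRp clustering thresholds are deliberately default-free: the classify
    # stage refuses to cluster without explicit values.
    rdrp_genus_identity: float | None = None
    rdrp_species_identity: float | None = None

    def validate(self) -> None:
        if not (0.0 <= self.breadth <= 1.0):
            raise ValueError(f"breadth threshold must be in [0,1], got {self.breadth}")
        if self.min_group_reads < 0:
            raise ValueError("min_group_reads must be nonnegative")
        if self.activity_window_bp <= 0:
            raise ValueError("activity_window_bp must be positive")
        if not (0.0 <= self.host_p <= 1.0):
            raise ValueError("host_p must be in [0,1]")
        if not (0.0 < self.differential_alpha < 1.0):
            raise ValueError("differential_alpha must be in (0,1)")


@dataclass
class PipelineConfig:
    input_dir: str = "."
    output_dir: str = "run"
    seed: int = 0
    n_permutations: int = 9999
    nmds_starts: int = 20
    thresholds: Thresholds = field(default_factory=Thresholds)
    per_replicate_filter: bool = False
    priming_min_active_replicates: int = 1
    priming_use_presence: bool = False
    simulation: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.thresholds.validate()
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    thr = Thresholds(**raw.pop("thresholds", {}))
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = PipelineConfig(thresholds=thr, **raw)
    cfg.validate()
    return cfg


def config_to_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d
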