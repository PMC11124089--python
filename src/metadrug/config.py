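"""Pipeline configuration: every numeric convention lives here, with the
published defaults (alpha 0.05, feature fraction 0.5, preselection 0.4,
confidence floor 700, top-k 50, consensus tier, 1000 percolation reps)."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    output_dir: str = "metadrug_run"
    alpha: float = 0.05
    feature_fraction: float = 0.5
    preselect_threshold: float = 0.4
    min_conf: int = 700
    top_k: int = 50
    min_methods: int = 6
    epc_reps: int = 1000
    seed: int = 0
    filters: tuple[bool, bool, bool, bool] = (True, True, True, True)
    cohorts: tuple[str, ...] = ("EC-like", "WC-like")
    sources: tuple[str, ...] = ("synthetic-screen",)
    # synthetic-universe knobs forwarded to SynthConfig
    synth: dict = field(default_factory=dict)
    # optional paths for running on user-supplied files instead of simulation
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.feature_fraction <= 1:
            raise ValueError("feature_fraction must lie in (0, 1]")
        if not 0 <= self.preselect_threshold <= 1:
            raise ValueError("preselect_threshold must lie in [0, 1]")
        if not 0 <= self.min_conf <= 1000:
            raise ValueError("min_conf must lie in [0, 1000]")
        if self.top_k < 1 or self.epc_reps < 1:
            raise ValueError("top_k and epc_reps must be positive")
        if not 1 <= self.min_methods <= 12:
            raise ValueError("min_methods must lie in [1, 12]")
        self.filters = tuple(bool(f) for f in self.filters)
        self.cohorts = tuple(self.cohorts)
        self.sources = tuple(self.sources)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
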