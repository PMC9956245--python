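"""Pipeline configuration: every tunable threshold in one declarative object.

Defaults are the thresholds the analysis is defined by: E-value 1e-4 for
the all-vs-all search, 80% coverage / 50% similarity for family edges,
50% coverage / 30% identity for paralog calls, 95% ANI for species
delineation and a 54% GC ceiling for the read contamination filter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    evalue_threshold: float = 1e-4
    family_coverage: float = 0.80
    family_similarity: float = 0.50
    paralog_coverage: float = 0.50
    paralog_identity: float = 0.30
    ani_threshold: float = 95.0
    gc_filter_max: float = 0.54
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_K: float = 0.041
    prefilter_k: int | None = 5
    min_retained_strains: int | None = None  # None = all retained strains
    seed: int = 0
    focal_cluster: str = "Ia"
    retained_phenotype: str = "Sp-"
    lost_phenotype: str = "Sp+"
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be positive")
        for name in ("family_coverage", "family_similarity",
                     "paralog_coverage", "paralog_identity", "gc_filter_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 <= self.ani_threshold <= 100.0):
            raise ValueError("ani_threshold must be in [0, 100]")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")

    def alignment_params(self):
        from .align import AlignmentParams

        return AlignmentParams(
            gap_open=self.gap_open, gap_extend=self.gap_extend,
            karlin_lambda=self.karlin_lambda, karlin_K=self.karlin_K,
            evalue_threshold=self.evalue_threshold)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
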