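"""Run configuration: merge tolerances, presence thresholds, statistics options.

Defaults are the processing constants of the study design this pipeline
implements: m/z tolerance +-0.01 Th and RT tolerance +-0.3 min for cross-batch
feature matching; blank removal at mean height >500 counts; presence at
height >1000 (FIELD) or >3000 (HYDRO) in strictly more than half of a group's
samples — the threefold threshold ratio mirrors the threefold higher
concentration of the hydroponic samples.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    tol_mz: float = 0.01  # Th
    tol_rt: float = 0.3  # minutes
    blank_threshold: float = 500.0  # counts
    field_presence_threshold: float = 1000.0  # counts
    hydro_presence_threshold: float = 3000.0  # counts
    majority_rule: str = "strict_more_than_half"
    blank_rule: str = "or"  # remove if EITHER blank class exceeds the threshold
    alpha: float = 0.05
    fdr_method: str = "benjamini_hochberg"
    fdr_family: str = "within_species"  # or "all_pairwise"
    top_n: int = 100
    rank_statistic: str = "mean"  # or "median"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "tol_mz",
            "tol_rt",
            "blank_threshold",
            "field_presence_threshold",
            "hydro_presence_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.majority_rule != "strict_more_than_half":
            raise ValueError(f"unsupported majority rule {self.majority_rule!r}")
        if self.blank_rule not in ("or", "and"):
            raise ValueError(f"blank_rule must be 'or' or 'and', got {self.blank_rule!r}")
        if self.fdr_method != "benjamini_hochberg":
            raise ValueError(f"unsupported fdr method {self.fdr_method!r}")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from YAML (JSON accepted as a subset of YAML)."""
        text = Path(path).read_text(encoding="utf-8")
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError:
            data = json.loads(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def threshold_for_batch(self, batch: str) -> float:
        if batch == "FIELD":
            return self.field_presence_threshold
        if batch == "HYDRO":
            return self.hydro_presence_threshold
        raise ValueError(f"unknown batch {batch!r}")
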