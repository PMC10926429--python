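"""Pipeline configuration: every tunable parameter with its default.

Defaults reproduce the pipeline's standard settings, so a bare run applies
the 240-bp length floor, perfect-overlap merging, the min-unique-size-5
abundance floor, the flank-15 / 0.002 conserved-base rule, and the 0.0023
guide SNP cutoff without any flags.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .snpcall import AlignScores


@dataclass(frozen=True)
class PipelineConfig:
    min_len: int = 240
    min_overlap: int = 20
    bin_k: int = 31
    bin_min_score: int = 10
    max_n_frac: float = 0.1
    min_unique_size: int = 5
    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -6.0
    gap_extend: float = -1.0
    score_floor: float = 0.0
    flank: int = 15
    window_max_freq: float = 0.002
    guide_max_freq: float = 0.0023
    guide_thresholds: tuple[float, ...] = (5.0, 1.0, 0.5)
    rank_n_max: int = 250
    min_support: int = 5
    merge_rate: float = 0.40
    read_pairs_available: int = 40000
    seed: int = 1

    def __post_init__(self) -> None:
        if self.min_len < 1 or self.min_overlap < 1 or self.bin_k < 1:
            raise ValueError("min_len, min_overlap and bin_k must be >= 1")
        if self.min_unique_size < 1 or self.min_support < 1:
            raise ValueError("min_unique_size and min_support must be >= 1")
        if not 0 < self.merge_rate <= 1:
            raise ValueError("merge_rate must be in (0, 1]")
        if not 0 < self.window_max_freq <= 1 or not 0 < self.guide_max_freq <= 1:
            raise ValueError("frequency thresholds must be in (0, 1]")
        if self.flank < 0 or self.rank_n_max < 1:
            raise ValueError("flank must be >= 0 and rank_n_max >= 1")
        if list(self.guide_thresholds) != sorted(self.guide_thresholds, reverse=True):
            raise ValueError("guide_thresholds must be descending")

    @property
    def align_scores(self) -> AlignScores:
        return AlignScores(self.match, self.mismatch, self.gap_open, self.gap_extend)

    def to_dict(self) -> dict:
        data = asdict(self)
        data["guide_thresholds"] = list(self.guide_thresholds)
        return data

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "guide_thresholds" in data:
            data["guide_thresholds"] = tuple(data["guide_thresholds"])
        return cls(**data)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_dict(data)
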