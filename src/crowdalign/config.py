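"""Pipeline configuration.

One dataclass gathers every tunable across the stages; the documented
defaults mirror the original game protocol (7-20 rows, 4-10
columns, ~0.15 elongation probability, 45 solutions per puzzle over 3
budget variants, about two-thirds of solutions excluded) and the
evaluation protocol (KC 400 tips x 100 replicates, triplet 100 x 5,
sub-alignments of 50 sequences, 150 most populated columns).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .io import ValidationError
from .puzzles import PuzzleParams


@dataclass(frozen=True)
class PipelineConfig:
    # puzzle generation
    min_rows: int = 7
    max_rows: int = 20
    min_width: int = 4
    max_width: int = 10
    elong_prob: float = 0.15
    token_cap: int = 10
    mirror: bool = True
    offset_prob: float = 0.1
    max_offset: int = 1
    full_row_bonus: int = 2
    min_improvement: int = 2
    budget_floor: int = 0
    filter_puzzles: bool = True
    # cohorts
    cohort_size: int = 45
    n_variants: int = 3
    # solution filtering
    keep_fraction: float = 1.0 / 3.0
    w_opt: float = 1.0
    w_cons: float = 1.0
    # realignment
    prior_weight: float = 0.5
    slack: int = 0
    # benchmark tiling (synthetic experiments)
    region_width: int = 8
    region_stride: int = 4
    # evaluation protocol
    kc_sample_tips: int = 400
    kc_replicates: int = 100
    triplet_sample_tips: int = 100
    triplet_replicates: int = 5
    gap_subsample_size: int = 50
    top_k_populated: int = 150
    gap_fraction_max: float = 0.5

    def __post_init__(self) -> None:
        if not self.min_rows <= self.max_rows:
            raise ValidationError("min_rows > max_rows")
        if not self.min_width <= self.max_width:
            raise ValidationError("min_width > max_width")
        if not 0 < self.keep_fraction <= 1:
            raise ValidationError("keep_fraction must be in (0, 1]")
        if self.cohort_size < self.n_variants:
            raise ValidationError("cohort_size smaller than n_variants")
        if not 0 <= self.elong_prob <= 1:
            raise ValidationError("elong_prob must be in [0, 1]")

    @property
    def players_per_puzzle(self) -> int:
        """Cohort size split over the budget variants (45 / 3 = 15)."""
        return self.cohort_size // self.n_variants

    def puzzle_params(self) -> PuzzleParams:
        return PuzzleParams(
            min_rows=self.min_rows,
            max_rows=self.max_rows,
            min_width=self.min_width,
            max_width=self.max_width,
            elong_prob=self.elong_prob,
            token_cap=self.token_cap,
            mirror=self.mirror,
            offset_prob=self.offset_prob,
            max_offset=self.max_offset,
            full_row_bonus=self.full_row_bonus,
            min_improvement=self.min_improvement,
            budget_floor=self.budget_floor,
        )

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.as_dict(), handle, sort_keys=True)
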