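"""Two-criterion consensus filtering of player solutions.

Per puzzle, each solution is scored on (1) its distance from optimality
— the score deficit against the best solution that used the same number
of gap tokens — and (2) its Euclidean distance from the cohort centroid
on binary (row, column)-occupancy vectors.  Both distances are
standardized within the puzzle, combined with configurable weights, and
the best ``keep_fraction`` of solutions is retained (default one third,
i.e. about two thirds excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import ValidationError
from .puzzles import Puzzle, Solution


def placement_vector(puzzle: Puzzle, solution: Solution) -> np.ndarray:
    """Binary occupancy indicator over (row, local column) cells."""
    vec = np.zeros((len(puzzle.rows), puzzle.width))
    for ri, cols in enumerate(solution.placement):
        for c in cols:
            vec[ri, c] = 1.0
    return vec.ravel()


def optimality_distances(solutions: list[Solution]) -> np.ndarray:
    """d_opt per solution: deficit vs the best score at equal gap count."""
    if not solutions:
        raise ValidationError("no solutions")
    best: dict[int, int] = {}
    for s in solutions:
        best[s.gaps_used] = max(best.get(s.gaps_used, s.score), s.score)
    return np.array([best[s.gaps_used] - s.score for s in solutions], float)


def consensus_centroid(vectors: np.ndarray) -> np.ndarray:
    """Arithmetic mean of placement vectors (per-cell occupancy in [0,1])."""
    if len(vectors) == 0:
        raise ValidationError("no solutions")
    return vectors.mean(axis=0)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


@dataclass(frozen=True)
class FilterReport:
    player_id: str
    d_opt: float
    d_cons: float
    badness: float
    kept: bool

    def as_dict(self) -> dict:
        return {
            "player_id": self.player_id,
            "d_opt": self.d_opt,
            "d_cons": self.d_cons,
            "badness": self.badness,
            "kept": self.kept,
        }


@dataclass(frozen=True)
class FilterResult:
    kept: tuple[Solution, ...]
    report: tuple[FilterReport, ...]


def filter_solutions(
    puzzle: Puzzle,
    solutions: list[Solution],
    keep_fraction: float = 1.0 / 3.0,
    w_opt: float = 1.0,
    w_cons: float = 1.0,
) -> FilterResult:
    """Keep the ceil(keep_fraction * n) least-anomalous solutions.

    Badness b = w_opt * z(d_opt) + w_cons * z(d_cons), with z the
    within-puzzle standardization (zero variance maps to zero).  Ties are
    broken by lower d_opt, then input order.
    """
    if not solutions:
        raise ValidationError("no solutions to filter")
    if not 0.0 < keep_fraction <= 1.0:
        raise ValidationError("keep_fraction must be in (0, 1]")
    for s in solutions:
        if s.puzzle_id != puzzle.id:
            raise ValidationError(
                f"solution by {s.player_id!r} is for puzzle "
                f"{s.puzzle_id!r}, not {puzzle.id!r}"
            )
    n = len(solutions)
    d_opt = optimality_distances(solutions)
    vectors = np.stack([placement_vector(puzzle, s) for s in solutions])
    centroid = consensus_centroid(vectors)
    d_cons = np.linalg.norm(vectors - centroid, axis=1)
    badness = w_opt * _standardize(d_opt) + w_cons * _standardize(d_cons)
    n_keep = math.ceil(keep_fraction * n)
    order = sorted(range(n), key=lambda i: (badness[i], d_opt[i], i))
    kept_idx = set(order[:n_keep])
    report = tuple(
        FilterReport(
            player_id=s.player_id,
            d_opt=float(d_opt[i]),
            d_cons=float(d_cons[i]),
            badness=float(badness[i]),
            kept=i in kept_idx,
        )
        for i, s in enumerate(solutions)
    )
    kept = tuple(s for i, s in enumerate(solutions) if i in kept_idx)
    return FilterResult(kept=kept, report=report)
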