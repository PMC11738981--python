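"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own dynamic programs:
joint placements are enumerated recursively, monotone assignments come
from itertools.combinations, and tree topologies are cross-checked
through dendropy.  They are slow and only run on tiny instances.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from crowdalign.io import Msa
from crowdalign.puzzles import (
    Guide,
    Puzzle,
    PuzzleRow,
    Region,
    gaps_used,
    score_row,
)

BASES = "ACGU"


@pytest.fixture
def toy_msa() -> Msa:
    return Msa(
        ids=("a", "b", "c"),
        rows=("AC-U", "ACGU", "AC-U"),
    )


def make_random_puzzle(
    rng: np.random.Generator,
    max_rows: int = 5,
    max_width: int = 6,
    max_budget: int = 4,
) -> Puzzle:
    """A random small puzzle with arbitrary guides, rows and budget."""
    width = int(rng.integers(2, max_width + 1))
    n_rows = int(rng.integers(1, max_rows + 1))
    guides = tuple(
        Guide(BASES[int(rng.integers(4))], 1.0)
        if rng.random() < 0.85
        else Guide(None, 0.0)
        for _ in range(width)
    )
    rows = []
    for ri in range(n_rows):
        length = int(rng.integers(1, width + 1))
        residues = "".join(BASES[int(rng.integers(4))] for _ in range(length))
        rows.append(
            PuzzleRow(
                seq_id=f"s{ri}",
                residues=residues,
                source_cols=tuple(range(length)),
            )
        )
    return Puzzle(
        id="rand",
        region=Region(0, width, tuple(r.seq_id for r in rows)),
        rows=tuple(rows),
        guides=guides,
        width=width,
        token_budget=int(rng.integers(0, max_budget + 1)),
        par_score=0,
    )


def enumerate_row_placements(length: int, width: int):
    return list(itertools.combinations(range(width), length))


def brute_force_optimum(puzzle: Puzzle, full_row_bonus: int = 2) -> int:
    """Exhaustive max score over all joint placements within budget."""
    best = -1

    def recurse(row_idx: int, budget_left: int, acc: int) -> None:
        nonlocal best
        if row_idx == len(puzzle.rows):
            best = max(best, acc)
            return
        row = puzzle.rows[row_idx]
        L = len(row.residues)
        for cols in enumerate_row_placements(L, puzzle.width):
            cost = cols[-1] + 1 - L if cols else 0
            if cost > budget_left:
                continue
            s = score_row(row.residues, cols, puzzle.guides, full_row_bonus)
            recurse(row_idx + 1, budget_left - cost, acc + s)

    recurse(0, puzzle.token_budget, 0)
    return best


def brute_force_assignment_max(weights: np.ndarray) -> float:
    """Exhaustive max-weight monotone assignment (tiny L and slot counts)."""
    L, n_slots = weights.shape
    best = -np.inf
    for slots in itertools.combinations(range(n_slots), L):
        total = sum(weights[i, s] for i, s in enumerate(slots))
        best = max(best, total)
    return float(best)


def random_rooted_newick(
    n_tips: int, rng: np.random.Generator, with_lengths: bool = False
) -> str:
    """A uniformly split random rooted binary tree over L0..L{n-1}."""
    labels = [f"L{i}" for i in range(n_tips)]

    def build(group: list[str]) -> str:
        if len(group) == 1:
            leaf = group[0]
            if with_lengths:
                return f"{leaf}:{rng.random() + 0.01:.3f}"
            return leaf
        perm = [group[i] for i in rng.permutation(len(group))]
        cut = int(rng.integers(1, len(group)))
        left, right = build(perm[:cut]), build(perm[cut:])
        if with_lengths:
            return f"({left},{right}):{rng.random() + 0.01:.3f}"
        return f"({left},{right})"

    perm = [labels[i] for i in rng.permutation(n_tips)]
    cut = int(rng.integers(1, n_tips))
    return f"({build(perm[:cut])},{build(perm[cut:])});"
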