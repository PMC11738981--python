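"""Positional votes and vote-guided realignment.

Filtered solutions become votes: each residue placed in a puzzle casts
one vote for a global column slot, found through the puzzle's
source-column bookkeeping, its guide offset and its orientation (so
mirrored-puzzle solutions land on the same slots as their forward
twins).  Votes are normalized per residue — a residue seen by 40
solutions and one seen by 10 weigh the same — and residues no solution
touched fall back to a pseudo-vote at their scaffold column.

Realignment then solves, independently per sequence, the monotone
assignment of residues to slots maximizing total vote weight:

    M[i][c] = max(M[i][c-1], M[i-1][c-1] + W[i][c-1])

a Needleman-Wunsch-style skip/consume recurrence with no explicit gap
penalty (missing vote mass is the penalty).  Traceback ties prefer the
residue's scaffold slot, then the leftmost slot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .io import GAP, Msa, ValidationError
from .puzzles import Puzzle, Solution, local_to_global


@dataclass
class SlotAxis:
    """Totally ordered output slots: scaffold columns plus optional
    insertion slots after region-boundary columns."""

    slot_columns: tuple[int | None, ...]  # scaffold column, or None (insertion)
    col_to_slot: tuple[int, ...]

    @classmethod
    def build(cls, width: int, boundaries: Iterable[int] = (), slack: int = 0):
        boundary_set = set(boundaries) if slack > 0 else set()
        slots: list[int | None] = []
        col_to_slot = []
        for c in range(width):
            col_to_slot.append(len(slots))
            slots.append(c)
            if c in boundary_set:
                slots.extend([None] * slack)
        return cls(tuple(slots), tuple(col_to_slot))

    @property
    def n_slots(self) -> int:
        return len(self.slot_columns)


@dataclass
class VoteMatrix:
    """Sparse per-sequence residue-by-slot support weights."""

    axis: SlotAxis
    votes: dict  # seq_id -> {residue_index -> {slot -> weight}}
    coverage: dict  # seq_id -> {residue_index -> n_solutions}
    log: list = field(default_factory=list)

    @property
    def n_slots(self) -> int:
        return self.axis.n_slots

    def copy(self) -> "VoteMatrix":
        return VoteMatrix(
            axis=self.axis,
            votes={
                sid: {r: dict(slots) for r, slots in res.items()}
                for sid, res in self.votes.items()
            },
            coverage={sid: dict(c) for sid, c in self.coverage.items()},
            log=list(self.log),
        )


def solutions_to_votes(
    puzzles: Iterable[Puzzle] | Mapping[str, Puzzle],
    kept_solutions: Iterable[Solution],
    scaffold: Msa,
    slack: int = 0,
) -> VoteMatrix:
    """Accumulate raw vote counts on the global slot axis."""
    if isinstance(puzzles, Mapping):
        by_id = dict(puzzles)
    else:
        by_id = {p.id: p for p in puzzles}
    boundaries = {p.region.col_end - 1 for p in by_id.values()}
    axis = SlotAxis.build(scaffold.width, boundaries, slack)
    res_count = {sid: len(scaffold.ungapped(sid)) for sid in scaffold.ids}
    col_to_res = {
        sid: {c: i for i, c in enumerate(scaffold.residue_columns(sid))}
        for sid in scaffold.ids
    }
    vm = VoteMatrix(axis=axis, votes={}, coverage={})
    for sol in kept_solutions:
        puzzle = by_id.get(sol.puzzle_id)
        if puzzle is None:
            raise ValidationError(f"solution references unknown puzzle {sol.puzzle_id!r}")
        for row, cols in zip(puzzle.rows, sol.placement):
            sid = row.seq_id
            for src, local in zip(row.source_cols, cols):
                res_idx = col_to_res[sid].get(src)
                if res_idx is None or res_idx >= res_count[sid]:
                    raise ValidationError(
                        f"corrupt solution for puzzle {sol.puzzle_id!r}, "
                        f"row {sid!r}: source column {src} is not a residue"
                    )
                g = local_to_global(puzzle, local)
                if g < 0:
                    vm.log.append(
                        f"clipped vote {sid}[{res_idx}] col {g} -> 0"
                    )
                    g = 0
                elif g >= scaffold.width:
                    vm.log.append(
                        f"clipped vote {sid}[{res_idx}] col {g} -> "
                        f"{scaffold.width - 1}"
                    )
                    g = scaffold.width - 1
                slot = axis.col_to_slot[g]
                res_votes = vm.votes.setdefault(sid, {}).setdefault(res_idx, {})
                res_votes[slot] = res_votes.get(slot, 0.0) + 1.0
                cov = vm.coverage.setdefault(sid, {})
                cov[res_idx] = cov.get(res_idx, 0) + 1
    return vm


def normalize_votes(raw: VoteMatrix) -> VoteMatrix:
    """Scale each voted residue's weights to sum to one (coverage-free)."""
    vm = raw.copy()
    for sid, res in vm.votes.items():
        for r, slots in res.items():
            total = sum(slots.values())
            if total > 0:
                for slot in slots:
                    slots[slot] /= total
    return vm


def fill_unvoted(
    votes: VoteMatrix, scaffold: Msa, prior_weight: float = 0.5
) -> VoteMatrix:
    """Give every unvoted residue one pseudo-vote at its scaffold slot."""
    if prior_weight <= 0:
        raise ValidationError("prior_weight must be > 0")
    vm = votes.copy()
    for sid in scaffold.ids:
        cols = scaffold.residue_columns(sid)
        res = vm.votes.setdefault(sid, {})
        for r, c in enumerate(cols):
            if r not in res or not res[r]:
                res[r] = {vm.axis.col_to_slot[c]: prior_weight}
    return vm


def dense_weights(vm: VoteMatrix, seq_id: str, n_residues: int) -> np.ndarray:
    w = np.zeros((n_residues, vm.n_slots))
    for r, slots in vm.votes.get(seq_id, {}).items():
        for slot, weight in slots.items():
            w[r, slot] = weight
    return w


def realign_sequence(
    weights: np.ndarray,
    scaffold_slots: tuple[int, ...] | None = None,
) -> tuple[tuple[int, ...], float]:
    """Maximum-weight monotone residue->slot assignment via DP.

    ``weights`` is (L, n_slots) with nonnegative entries.  Returns the
    assignment (strictly increasing slots, one per residue) and its
    score.  Ties in the traceback prefer the residue's scaffold slot,
    then the leftmost slot.
    """
    L, n_slots = weights.shape
    if L > n_slots:
        raise ValidationError(
            f"{L} residues cannot fit in {n_slots} slots"
        )
    if L == 0:
        return (), 0.0
    NEG = -np.inf
    M = np.full((L + 1, n_slots + 1), NEG)
    M[0, :] = 0.0
    for i in range(1, L + 1):
        cand = M[i - 1, :-1] + weights[i - 1]
        M[i, 1:] = np.maximum.accumulate(cand)
        # cells with c < i stay -inf implicitly via the accumulate of -inf
    assignment = [0] * L
    i, c = L, n_slots
    while i > 0:
        take = M[i - 1, c - 1] + weights[i - 1, c - 1]
        skip = M[i, c - 1] if c - 1 >= i else NEG
        here = M[i, c]
        prefer_take = False
        if take == here and skip == here:
            prefer_take = (
                scaffold_slots is not None and scaffold_slots[i - 1] == c - 1
            )
        elif take == here:
            prefer_take = True
        if prefer_take:
            assignment[i - 1] = c - 1
            i -= 1
            c -= 1
        else:
            c -= 1
    return tuple(assignment), float(M[L, n_slots])


@dataclass
class RealignmentResult:
    msa: Msa
    scores: dict
    assignments: dict  # seq_id -> slot per residue (pre column drop)
    moved_residue_count: int
    dropped_columns: int
    slot_columns: tuple


def realign_all(scaffold: Msa, votes: VoteMatrix) -> RealignmentResult:
    """Realign every sequence to the vote array independently.

    Residues are written into their assigned slots, all-empty slots are
    dropped, and the move count against the scaffold is reported.  Every
    output row's ungapped sequence equals its scaffold counterpart by
    construction.
    """
    n_slots = votes.n_slots
    grid = np.full((len(scaffold.ids), n_slots), GAP, dtype="U1")
    scores: dict[str, float] = {}
    assignments: dict[str, tuple[int, ...]] = {}
    moved = 0
    for si, sid in enumerate(scaffold.ids):
        residues = scaffold.ungapped(sid)
        scaffold_slots = tuple(
            votes.axis.col_to_slot[c] for c in scaffold.residue_columns(sid)
        )
        w = dense_weights(votes, sid, len(residues))
        try:
            assignment, score = realign_sequence(w, scaffold_slots)
        except ValidationError as exc:
            raise ValidationError(f"sequence {sid!r}: {exc}") from exc
        scores[sid] = score
        assignments[sid] = assignment
        moved += sum(
            1 for a, b in zip(assignment, scaffold_slots) if a != b
        )
        for ch, slot in zip(residues, assignment):
            grid[si, slot] = ch
    occupied = (grid != GAP).any(axis=0)
    dropped = int((~occupied).sum())
    rows = tuple("".join(r) for r in grid[:, occupied])
    out = Msa(scaffold.ids, rows)
    return RealignmentResult(
        msa=out,
        scores=scores,
        assignments=assignments,
        moved_residue_count=moved,
        dropped_columns=dropped,
        slot_columns=votes.axis.slot_columns,
    )
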