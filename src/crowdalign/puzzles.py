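"""Puzzle construction, scoring and the greedy budget-setting player.

A puzzle is a rectangular region of the scaffold alignment rendered the
way the game shows it: each sequence's residues in the region are
collapsed ("gravity" removes all gaps), a per-column guide profile shows
the region's consensus, and the player re-inserts a limited number of
gap tokens to match residues to guides.  A naive greedy player solves
each fresh puzzle to fix the token budget and the par score that human
(or simulated) players must reach.

Coordinates are 0-based and half-open throughout.  Local puzzle columns
map to global scaffold columns through the region bounds, the guide
offset and the orientation; :func:`local_to_global` is the single place
that mapping lives.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from .io import GAP, RNA_BASES, Msa, ValidationError

#: Tie-break order for guide symbols (modal-count ties).
GUIDE_ORDER = {b: i for i, b in enumerate(RNA_BASES)}

FORWARD = "forward"
MIRRORED = "mirrored"


@dataclass(frozen=True)
class Region:
    """A window of scaffold columns over an ordered subset of sequences."""

    col_start: int
    col_end: int
    row_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "row_ids", tuple(self.row_ids))
        if not 0 <= self.col_start < self.col_end:
            raise ValidationError(
                f"invalid region columns [{self.col_start}, {self.col_end})"
            )
        if not self.row_ids:
            raise ValidationError("region has no rows")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValidationError("region row_ids are not unique")

    @property
    def width(self) -> int:
        return self.col_end - self.col_start

    def validate_for(self, msa: Msa) -> None:
        if self.col_end > msa.width:
            raise ValidationError(
                f"region [{self.col_start}, {self.col_end}) out of bounds "
                f"for width-{msa.width} alignment"
            )
        for sid in self.row_ids:
            msa.index(sid)


@dataclass(frozen=True)
class Guide:
    symbol: str | None  # one of ACGU, or None for no guide
    freq: float


@dataclass(frozen=True)
class PuzzleRow:
    seq_id: str
    residues: str  # gap-free fragment, in on-screen order
    source_cols: tuple[int, ...]  # scaffold column of each residue


@dataclass(frozen=True)
class Puzzle:
    id: str
    region: Region
    rows: tuple[PuzzleRow, ...]
    guides: tuple[Guide, ...]
    width: int
    token_budget: int
    par_score: int
    orientation: str = FORWARD
    offset: int = 0
    variant: int = 0

    def __post_init__(self) -> None:
        if self.orientation not in (FORWARD, MIRRORED):
            raise ValidationError(f"bad orientation {self.orientation!r}")
        if len(self.guides) != self.width:
            raise ValidationError("guide count != puzzle width")
        if self.token_budget < 0:
            raise ValidationError("negative token budget")
        for row in self.rows:
            if len(row.residues) != len(row.source_cols):
                raise ValidationError(
                    f"row {row.seq_id!r}: residues/source_cols length mismatch"
                )
            if len(row.residues) > self.width:
                raise ValidationError(
                    f"row {row.seq_id!r} longer than puzzle width"
                )
            if GAP in row.residues:
                raise ValidationError(f"row {row.seq_id!r} contains a gap")


@dataclass(frozen=True)
class Solution:
    """One player's placement of every row, with its score bookkeeping."""

    puzzle_id: str
    player_id: str
    placement: tuple[tuple[int, ...], ...]
    score: int
    gaps_used: int


#: A placement assigns each row's residues to strictly increasing local
#: columns; tokens used per row = last column + 1 - residue count.
Placement = tuple[tuple[int, ...], ...]


@dataclass(frozen=True)
class PuzzleParams:
    """Generation-time knobs; defaults follow the original game protocol."""

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


def compute_guides(msa: Msa, region: Region, offset: int = 0) -> tuple[Guide, ...]:
    """Per-column modal non-gap symbol over the region rows.

    With a nonzero ``offset`` guides come from columns shifted left by
    ``offset``; columns outside the alignment yield no guide.  Ties are
    broken in fixed order A < C < G < U; ambiguity codes never guide.
    """
    region.validate_for(msa)
    rows = [msa.row(sid) for sid in region.row_ids]
    guides = []
    for local in range(region.width):
        g = region.col_start - offset + local
        if g < 0 or g >= msa.width:
            guides.append(Guide(None, 0.0))
            continue
        column = [row[g] for row in rows]
        non_gap = [ch for ch in column if ch != GAP]
        counts = {b: 0 for b in RNA_BASES}
        for ch in non_gap:
            if ch in counts:
                counts[ch] += 1
        best = max(counts.values()) if counts else 0
        if not non_gap or best == 0:
            guides.append(Guide(None, 0.0))
            continue
        symbol = min(
            (b for b, c in counts.items() if c == best), key=GUIDE_ORDER.get
        )
        guides.append(Guide(symbol, best / len(non_gap)))
    return tuple(guides)


def collapse_rows(
    msa: Msa,
    region: Region,
    elong_prob: float,
    rng: np.random.Generator,
) -> tuple[tuple[PuzzleRow, ...], tuple[str, ...]]:
    """Collapse region rows to gap-free fragments with source bookkeeping.

    Independently per row, with probability ``elong_prob`` the fragment is
    perturbed: a fair coin picks between dropping the last residue and
    appending the sequence's next residue beyond the region (when one
    exists and the fragment is not already full width).  Rows that end up
    empty are dropped and reported.
    """
    region.validate_for(msa)
    if not 0.0 <= elong_prob <= 1.0:
        raise ValidationError("elong_prob must be in [0, 1]")
    rows: list[PuzzleRow] = []
    dropped: list[str] = []
    for sid in region.row_ids:
        full = msa.row(sid)
        cols = [
            c
            for c in range(region.col_start, region.col_end)
            if full[c] != GAP
        ]
        # draw both randoms unconditionally so the stream per row is fixed
        perturb = rng.random() < elong_prob
        coin = rng.random() < 0.5
        if perturb:
            if coin and cols:  # shorten
                cols = cols[:-1]
            elif not coin and len(cols) < region.width:  # elongate
                nxt = next(
                    (
                        c
                        for c in range(region.col_end, msa.width)
                        if full[c] != GAP
                    ),
                    None,
                )
                if nxt is not None:
                    cols = cols + [nxt]
        if not cols:
            dropped.append(sid)
            continue
        rows.append(
            PuzzleRow(
                seq_id=sid,
                residues="".join(full[c] for c in cols),
                source_cols=tuple(cols),
            )
        )
    return tuple(rows), tuple(dropped)


def gaps_used(placement: Placement) -> int:
    """Total gap tokens a placement consumes (suffix-shift accounting)."""
    return sum(cols[-1] + 1 - len(cols) for cols in placement if cols)


def validate_placement(puzzle: Puzzle, placement: Placement,
                       check_budget: bool = True) -> None:
    if len(placement) != len(puzzle.rows):
        raise ValidationError(
            f"placement has {len(placement)} rows, puzzle has {len(puzzle.rows)}"
        )
    for row, cols in zip(puzzle.rows, placement):
        if len(cols) != len(row.residues):
            raise ValidationError(
                f"row {row.seq_id!r}: {len(cols)} columns for "
                f"{len(row.residues)} residues"
            )
        for prev, cur in zip(cols, cols[1:]):
            if cur <= prev:
                raise ValidationError(
                    f"row {row.seq_id!r}: columns not strictly increasing"
                )
        if cols and (cols[0] < 0 or cols[-1] >= puzzle.width):
            raise ValidationError(
                f"row {row.seq_id!r}: column out of [0, {puzzle.width})"
            )
    if check_budget and gaps_used(placement) > puzzle.token_budget:
        raise ValidationError(
            f"placement uses {gaps_used(placement)} tokens, budget is "
            f"{puzzle.token_budget}"
        )


def score_row(residues: str, cols, guides, full_row_bonus: int) -> int:
    matches = sum(
        1
        for ch, c in zip(residues, cols)
        if guides[c].symbol is not None and guides[c].symbol == ch
    )
    if residues and matches == len(residues):
        return matches + full_row_bonus
    return matches


def score_placement(
    puzzle: Puzzle,
    placement: Placement,
    full_row_bonus: int = 2,
    check_budget: bool = True,
) -> int:
    """Guide-match score plus the full-row bonus; deterministic."""
    validate_placement(puzzle, placement, check_budget=check_budget)
    return sum(
        score_row(row.residues, cols, puzzle.guides, full_row_bonus)
        for row, cols in zip(puzzle.rows, placement)
    )


def gravity_placement(puzzle: Puzzle) -> Placement:
    """The start state: every row fully collapsed to the leftmost columns."""
    return tuple(tuple(range(len(r.residues))) for r in puzzle.rows)


@dataclass(frozen=True)
class GreedyResult:
    placement: Placement
    tokens_used: int
    score: int


def greedy_solve(
    puzzle: Puzzle, max_tokens: int, full_row_bonus: int = 2
) -> GreedyResult:
    """Hill-climb from gravity by single-gap insertions.

    Each step evaluates every legal insertion (row r, gap position g:
    shift the residues at and after g one column right, if room remains)
    and applies the one with the largest strict score increase, ties
    broken by lowest row then lowest gap position.  Deterministic; stops
    at a local optimum or when the token allowance is spent.
    """
    if max_tokens < 0:
        raise ValidationError("max_tokens must be >= 0")
    state = [list(range(len(r.residues))) for r in puzzle.rows]
    row_scores = [
        score_row(r.residues, cols, puzzle.guides, full_row_bonus)
        for r, cols in zip(puzzle.rows, state)
    ]
    tokens = 0
    while tokens < max_tokens:
        best_gain = 0
        best_move = None
        for ri, (row, cols) in enumerate(zip(puzzle.rows, state)):
            if not cols or cols[-1] >= puzzle.width - 1:
                continue
            for g in range(len(cols)):
                new_cols = cols[:g] + [c + 1 for c in cols[g:]]
                gain = (
                    score_row(row.residues, new_cols, puzzle.guides, full_row_bonus)
                    - row_scores[ri]
                )
                if gain > best_gain:
                    best_gain = gain
                    best_move = (ri, g)
        if best_move is None:
            break
        ri, g = best_move
        state[ri] = state[ri][:g] + [c + 1 for c in state[ri][g:]]
        row_scores[ri] += best_gain
        tokens += 1
    return GreedyResult(
        placement=tuple(tuple(c) for c in state),
        tokens_used=tokens,
        score=sum(row_scores),
    )


def local_to_global(puzzle: Puzzle, local_col: int) -> int:
    """Global scaffold column a local puzzle column votes for.

    This is the guide frame: with offset ``k`` the guides were drawn from
    columns shifted left by ``k``, so a residue aligned at local column c
    claims scaffold column ``col_start - k + c`` (mirror-reflected for
    mirrored puzzles).  May fall outside the alignment near edges.
    """
    frame_start = puzzle.region.col_start - puzzle.offset
    if puzzle.orientation == FORWARD:
        return frame_start + local_col
    return frame_start + puzzle.width - 1 - local_col


def mirror_rows(rows: tuple[PuzzleRow, ...]) -> tuple[PuzzleRow, ...]:
    return tuple(
        PuzzleRow(r.seq_id, r.residues[::-1], tuple(reversed(r.source_cols)))
        for r in rows
    )


def mirror_puzzle(puzzle: Puzzle) -> Puzzle:
    """Column-reverse a puzzle (involution up to the id suffix)."""
    flipped = MIRRORED if puzzle.orientation == FORWARD else FORWARD
    return replace(
        puzzle,
        id=puzzle.id + "~m",
        rows=mirror_rows(puzzle.rows),
        guides=tuple(reversed(puzzle.guides)),
        orientation=flipped,
    )


def _region_fingerprint(region: Region) -> str:
    digest = hashlib.md5(
        ("|".join(region.row_ids)).encode()
    ).hexdigest()
    return digest[:6]


@dataclass(frozen=True)
class BuildResult:
    puzzles: tuple[Puzzle, ...]
    dropped_rows: tuple[str, ...]
    rejection: str | None = None


def build_puzzles(
    msa: Msa,
    region: Region,
    params: PuzzleParams,
    rng: np.random.Generator,
    id_prefix: str | None = None,
) -> BuildResult:
    """Build up to 3 budget variants x 2 orientations for one region.

    Row perturbation (shorten/elongate) is re-rolled independently for
    every emitted puzzle — each sequence has the elongation chance "in
    each puzzle".  Per puzzle, the base budget B is what the greedy
    player spends under the token cap (floored by ``budget_floor``,
    itself capped at the total empty-cell count, beyond which tokens are
    unspendable); the three variants offset it by {0, +1, -1} and par is
    re-computed by greedy under each budget.  With probability
    ``offset_prob`` the region's guides are shifted left by an offset
    drawn from {1, .., max_offset}.
    """
    region.validate_for(msa)
    base_rows, base_dropped = collapse_rows(msa, region, 0.0, rng)
    if len(base_rows) < params.min_rows:
        return BuildResult(
            (), base_dropped,
            rejection=f"only {len(base_rows)} nonempty rows, "
                      f"need {params.min_rows}",
        )
    offset = 0
    if params.offset_prob > 0 and rng.random() < params.offset_prob:
        offset = int(rng.integers(1, params.max_offset + 1))
    guides = compute_guides(msa, region, offset)
    prefix = id_prefix or (
        f"pz{region.col_start}-{region.col_end}-{_region_fingerprint(region)}"
    )

    orientations = [FORWARD]
    if params.mirror:
        orientations.append(MIRRORED)

    puzzles: list[Puzzle] = []
    dropped: set[str] = set(base_dropped)
    seen: set[tuple] = set()
    for orientation in orientations:
        oguides = guides if orientation == FORWARD else tuple(reversed(guides))
        for variant, delta in enumerate((0, 1, -1)):
            rows, roll_dropped = collapse_rows(
                msa, region, params.elong_prob, rng
            )
            dropped.update(roll_dropped)
            if len(rows) < params.min_rows:
                continue
            if orientation == MIRRORED:
                rows = mirror_rows(rows)
            core = Puzzle(
                id=f"{prefix}:{orientation[0]}:v{variant}",
                region=region,
                rows=rows,
                guides=oguides,
                width=region.width,
                token_budget=params.token_cap,
                par_score=0,
                orientation=orientation,
                offset=offset,
                variant=variant,
            )
            base = greedy_solve(core, params.token_cap, params.full_row_bonus)
            max_useful = sum(region.width - len(r.residues) for r in rows)
            b = max(base.tokens_used, min(params.budget_floor, max_useful))
            budget = max(b + delta, 1)
            key = (rows, budget)
            if key in seen:
                continue
            seen.add(key)
            par = greedy_solve(
                replace(core, token_budget=budget),
                budget,
                params.full_row_bonus,
            ).score
            puzzles.append(
                replace(core, token_budget=budget, par_score=par)
            )
    return BuildResult(tuple(puzzles), tuple(sorted(dropped)))


def accept_puzzle(
    puzzle: Puzzle, params: PuzzleParams
) -> tuple[bool, str | None]:
    """Keep only puzzles with room for improvement over the gravity start."""
    gravity = score_placement(
        puzzle, gravity_placement(puzzle), params.full_row_bonus,
        check_budget=False,
    )
    if puzzle.token_budget < 1:
        return False, "no gap tokens available"
    if puzzle.par_score - gravity < params.min_improvement:
        return False, (
            f"par {puzzle.par_score} within {params.min_improvement} of "
            f"gravity {gravity} (local optimum at start)"
        )
    return True, None
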