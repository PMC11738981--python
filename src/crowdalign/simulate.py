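"""Synthetic benchmarks and simulated player cohorts.

The study's raw inputs — a scaffold alignment of real 16S V4 fragments
and tens of millions of human puzzle solutions — are stood in for by two
generators:

* :func:`simulate_benchmark` evolves sequences down a random Yule tree
  (per-branch substitutions, single-column deletions), yielding a true
  alignment whose column history is known exactly, then corrupts a copy
  by sliding gaps within rows.  The corrupted copy plays the scaffold;
  the pipeline's job is to recover the truth.
* :func:`simulate_cohort` emits per-puzzle player solutions under a
  three-component skill model (optimal / truthful / noisy), gated by the
  game's "reach par" rule.

Both are first-class, tested components: every number they produce flows
from a single seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .io import GAP, RNA_BASES, Msa, ValidationError
from .puzzles import (
    FORWARD,
    Placement,
    Puzzle,
    Solution,
    gaps_used,
    score_placement,
    score_row,
)

_BASES = np.array(list(RNA_BASES))


@dataclass(frozen=True)
class SkillProfile:
    """Mixture weights for the three simulated player behaviours.

    ``p_optimal``: submits a maximum-score placement within budget;
    ``p_truth``: reproduces the true local alignment when it is reachable
    within budget; the rest of the mass plays "noisy": placements sampled
    with probability proportional to exp(score / noise_temperature).
    """

    p_optimal: float = 0.0
    p_truth: float = 0.0
    noise_temperature: float = 1.0

    def __post_init__(self) -> None:
        for name in ("p_optimal", "p_truth"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.p_optimal + self.p_truth > 1.0 + 1e-12:
            raise ValidationError("p_optimal + p_truth must be <= 1")
        if self.noise_temperature <= 0:
            raise ValidationError("noise_temperature must be > 0")


@dataclass(frozen=True)
class SyntheticBenchmark:
    true_msa: Msa
    scaffold_msa: Msa
    tree: TreeNode
    corruption_log: tuple[dict, ...]


def _yule_tree(n_seqs: int, rng: np.random.Generator) -> TreeNode:
    """Pure-birth tree: exponential waiting times, uniform lineage splits."""
    root = TreeNode()
    birth = {id(root): 0.0}
    active = [root]
    t = 0.0
    while len(active) < n_seqs:
        t += float(rng.exponential(1.0 / len(active)))
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        parent.length = t - birth[id(parent)] if parent.parent else None
        kids = [TreeNode(), TreeNode()]
        parent.extend(kids)
        for k in kids:
            birth[id(k)] = t
        active.extend(kids)
    t_end = t + float(rng.exponential(1.0 / n_seqs))
    for tip in active:
        tip.length = t_end - birth[id(tip)]
    for i, tip in enumerate(root.tips()):
        tip.name = f"s{i:03d}"
    return root


def _evolve(
    tree: TreeNode,
    n_cols: int,
    sub_rate: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> dict[str, str]:
    root_seq = rng.choice(_BASES, size=n_cols)
    seqs: dict[int, np.ndarray] = {id(tree): root_seq}
    rows: dict[str, str] = {}
    for node in tree.preorder(include_self=False):
        seq = seqs[id(node.parent)].copy()
        alive = seq != GAP
        # substitutions, then single-column deletions, per branch
        sub = alive & (rng.random(n_cols) < sub_rate)
        if sub.any():
            for i in np.nonzero(sub)[0]:
                choices = [b for b in RNA_BASES if b != seq[i]]
                seq[i] = choices[int(rng.integers(3))]
        dele = (seq != GAP) & (rng.random(n_cols) < indel_rate)
        seq[dele] = GAP
        seqs[id(node)] = seq
        if node.is_tip():
            rows[node.name] = "".join(seq)
    return rows


def _corrupt(
    msa: Msa, corruption_rate: float, rng: np.random.Generator
) -> tuple[Msa, tuple[dict, ...]]:
    rows = []
    log: list[dict] = []
    for sid, row in zip(msa.ids, msa.rows):
        chars = list(row)
        hit = rng.random() < corruption_rate
        if hit:
            gap_positions = [i for i, ch in enumerate(chars) if ch == GAP]
            if not gap_positions:
                log.append({"seq_id": sid, "event": "skipped_no_gap"})
            else:
                g = gap_positions[int(rng.integers(len(gap_positions)))]
                dist = int(rng.integers(1, 3))
                sign = 1 if rng.random() < 0.5 else -1
                target = min(max(g + sign * dist, 0), len(chars) - 1)
                if target != g:
                    chars.pop(g)
                    chars.insert(target, GAP)
                    log.append(
                        {"seq_id": sid, "event": "slide", "from": g, "to": target}
                    )
                else:
                    log.append({"seq_id": sid, "event": "skipped_at_edge"})
        rows.append("".join(chars))
    return Msa(msa.ids, tuple(rows)), tuple(log)


def simulate_benchmark(
    n_seqs: int = 30,
    n_cols: int = 60,
    sub_rate: float = 0.05,
    indel_rate: float = 0.02,
    corruption_rate: float = 0.3,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SyntheticBenchmark:
    """Generate a (truth, corrupted scaffold, tree) benchmark triple.

    The corrupted copy differs from the truth only by within-row gap
    slides of 1-2 columns, so every row's ungapped sequence is identical
    between the two alignments.
    """
    if n_seqs < 2:
        raise ValidationError("n_seqs must be >= 2")
    for name, v in (
        ("sub_rate", sub_rate),
        ("indel_rate", indel_rate),
        ("corruption_rate", corruption_rate),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    tree = _yule_tree(n_seqs, rng)
    rows = _evolve(tree, n_cols, sub_rate, indel_rate, rng)
    ids = tuple(sorted(rows))
    true_msa = Msa(ids, tuple(rows[i] for i in ids))
    scaffold, log = _corrupt(true_msa, corruption_rate, rng)
    return SyntheticBenchmark(true_msa, scaffold, tree, log)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _row_placements(length: int, width: int, budget: int):
    """All monotone placements of ``length`` residues with cost <= budget."""
    if length == 0:
        return [()]
    max_last = min(width - 1, length - 1 + budget)
    return [
        cols
        for cols in itertools.combinations(range(max_last + 1), length)
        if cols[-1] - (length - 1) <= budget
    ]


class _PuzzleSampler:
    """Exact samplers over the placement space of one puzzle.

    Scores are separable per row and the token budget couples rows only
    through the sum of per-row costs, so both the uniform-over-maxima
    sampler and the Boltzmann sampler reduce to dynamic programs over
    (row, remaining tokens).
    """

    def __init__(self, puzzle: Puzzle, full_row_bonus: int = 2):
        self.puzzle = puzzle
        self.bonus = full_row_bonus
        self.budget = puzzle.token_budget
        B = self.budget
        self.row_opts: list[list[tuple[int, int, tuple[int, ...]]]] = []
        for row in puzzle.rows:
            opts = []
            for cols in _row_placements(len(row.residues), puzzle.width, B):
                cost = cols[-1] + 1 - len(cols) if cols else 0
                s = score_row(row.residues, cols, puzzle.guides, self.bonus)
                opts.append((cost, s, cols))
            self.row_opts.append(opts)
        self._noisy_cache: dict = {}
        self._build_optimal()

    def _build_optimal(self) -> None:
        B = self.budget
        R = len(self.row_opts)
        NEG = -(10**9)
        # per row: best score and maximizer placements for each exact cost
        self.best_at = []  # [row][cost] -> (score, [placements])
        for opts in self.row_opts:
            per = [(NEG, []) for _ in range(B + 1)]
            for cost, s, cols in opts:
                cur, lst = per[cost]
                if s > cur:
                    per[cost] = (s, [cols])
                elif s == cur:
                    lst.append(cols)
            self.best_at.append(per)
        # M[i][t]: best score rows i.. with <= t tokens; N: maximizer counts
        self.M = [[NEG] * (B + 1) for _ in range(R + 1)]
        self.N = [[0] * (B + 1) for _ in range(R + 1)]
        for t in range(B + 1):
            self.M[R][t] = 0
            self.N[R][t] = 1
        for i in range(R - 1, -1, -1):
            for t in range(B + 1):
                best = NEG
                for cost in range(t + 1):
                    s, lst = self.best_at[i][cost]
                    if not lst:
                        continue
                    cand = s + self.M[i + 1][t - cost]
                    if cand > best:
                        best = cand
                self.M[i][t] = best
                cnt = 0
                for cost in range(t + 1):
                    s, lst = self.best_at[i][cost]
                    if lst and s + self.M[i + 1][t - cost] == best:
                        cnt += len(lst) * self.N[i + 1][t - cost]
                self.N[i][t] = cnt

    @property
    def optimum(self) -> int:
        return self.M[0][self.budget]

    def sample_optimal(self, rng: np.random.Generator) -> Placement:
        """Uniform draw over all maximum-score placements within budget."""
        out = []
        t = self.budget
        for i in range(len(self.row_opts)):
            options = []
            weights = []
            for cost in range(t + 1):
                s, lst = self.best_at[i][cost]
                if lst and s + self.M[i + 1][t - cost] == self.M[i][t]:
                    options.append((cost, lst))
                    weights.append(len(lst) * self.N[i + 1][t - cost])
            total = sum(weights)
            pick = int(rng.integers(total))
            for (cost, lst), w in zip(options, weights):
                if pick < w:
                    out.append(lst[pick % len(lst)])
                    t -= cost
                    break
                pick -= w
        return tuple(out)

    def _noisy_tables(self, temperature: float):
        cached = self._noisy_cache.get(temperature)
        if cached is not None:
            return cached
        B = self.budget
        R = len(self.row_opts)
        # per-row weights shifted by the row maximum for numerical safety
        row_w = []
        cost_w = []  # [row][cost] -> summed weight
        for opts in self.row_opts:
            m = max(s for _, s, _ in opts)
            w = [(cost, math.exp((s - m) / temperature), cols)
                 for cost, s, cols in opts]
            row_w.append(w)
            per = [0.0] * (B + 1)
            for cost, wt, _ in w:
                per[cost] += wt
            cost_w.append(per)
        Z = [[0.0] * (B + 1) for _ in range(R + 1)]
        for t in range(B + 1):
            Z[R][t] = 1.0
        for i in range(R - 1, -1, -1):
            for t in range(B + 1):
                Z[i][t] = sum(
                    cost_w[i][c] * Z[i + 1][t - c] for c in range(t + 1)
                )
        self._noisy_cache[temperature] = (row_w, cost_w, Z)
        return self._noisy_cache[temperature]

    def sample_noisy(
        self, temperature: float, rng: np.random.Generator
    ) -> Placement:
        """Boltzmann draw: P(placement) ∝ exp(total score / temperature)."""
        B = self.budget
        R = len(self.row_opts)
        row_w, cost_w, Z = self._noisy_tables(temperature)
        if Z[0][B] <= 0.0:
            return self.sample_optimal(rng)  # complete underflow
        out = []
        t = B
        for i in range(R):
            weights = [cost_w[i][c] * Z[i + 1][t - c] for c in range(t + 1)]
            total = sum(weights)
            u = float(rng.random()) * total
            cost = 0
            for c, w in enumerate(weights):
                if u < w:
                    cost = c
                    break
                u -= w
            inner = [(wt, cols) for cc, wt, cols in row_w[i] if cc == cost]
            itotal = sum(wt for wt, _ in inner)
            v = float(rng.random()) * itotal
            chosen = inner[-1][1]
            for wt, cols in inner:
                if v < wt:
                    chosen = cols
                    break
                v -= wt
            out.append(chosen)
            t -= cost
        return tuple(out)


def _frame_locals(puzzle: Puzzle, global_cols: list[int]) -> tuple[int, ...]:
    """Monotone projection of target global columns into the puzzle frame.

    Residues whose target sits inside the frame keep it exactly (when
    that is compatible with monotonicity); targets outside the frame —
    e.g. an elongated row's extra residue, or a pattern crossing the
    region boundary — are clamped to the nearest feasible column.
    """
    frame_start = puzzle.region.col_start - puzzle.offset
    width = puzzle.width
    if puzzle.orientation == FORWARD:
        targets = [c - frame_start for c in global_cols]
    else:
        # mirrored rows store residues and source columns reversed, so the
        # reflection alone restores on-screen monotone order
        targets = [frame_start + width - 1 - c for c in global_cols]
    L = len(targets)
    locals_: list[int] = []
    for j, t in enumerate(targets):
        lo = locals_[-1] + 1 if locals_ else 0
        hi = width - L + j  # leave room for the residues still to place
        locals_.append(min(max(t, lo), hi))
    return tuple(locals_)


def truth_placement(
    puzzle: Puzzle, truth: Msa, scaffold: Msa
) -> Placement | None:
    """The placement reproducing the true local alignment, frame-clamped.

    Per row, the true column pattern is projected monotonically into the
    puzzle frame (see :func:`_frame_locals`).  Returns None only when
    the assembled placement needs more tokens than the budget allows
    (the caller then treats the player as noisy).
    """
    out = []
    for row in puzzle.rows:
        scols = scaffold.residue_columns(row.seq_id)
        tcols = truth.residue_columns(row.seq_id)
        col_to_res = {c: i for i, c in enumerate(scols)}
        res_idx = [col_to_res[src] for src in row.source_cols]
        out.append(_frame_locals(puzzle, [tcols[r] for r in res_idx]))
    placement = tuple(out)
    if gaps_used(placement) > puzzle.token_budget:
        return None
    return placement


def simulate_cohort(
    puzzle: Puzzle,
    n_players: int,
    skill: SkillProfile,
    truth: Msa | None = None,
    scaffold: Msa | None = None,
    rng: np.random.Generator | None = None,
    full_row_bonus: int = 2,
    par_redraw_cap: int = 50,
    player_prefix: str = "p",
) -> list[Solution]:
    """Emit ``n_players`` solutions for one puzzle under a skill profile.

    Every emitted solution reaches at least the par score, or the draw is
    repeated (category re-drawn each time) up to ``par_redraw_cap`` times
    after which the best candidate seen is emitted — the simulated
    counterpart of the game's "must reach par" gate.
    """
    if n_players < 1:
        raise ValidationError("n_players must be >= 1")
    if skill.p_truth > 0 and (truth is None or scaffold is None):
        raise ValidationError(
            "p_truth > 0 requires the truth and scaffold alignments"
        )
    if rng is None:
        rng = np.random.default_rng()
    sampler = _PuzzleSampler(puzzle, full_row_bonus)
    if sampler.optimum < puzzle.par_score:
        raise ValidationError(
            f"puzzle {puzzle.id!r}: par {puzzle.par_score} unreachable "
            f"(optimum {sampler.optimum}) — buggy puzzle"
        )
    tplacement = (
        truth_placement(puzzle, truth, scaffold)
        if skill.p_truth > 0 and truth is not None and scaffold is not None
        else None
    )

    solutions: list[Solution] = []
    for pi in range(n_players):
        # one category per player: a truthful player stays truthful
        u = float(rng.random())
        if u < skill.p_optimal:
            category = "optimal"
        elif u < skill.p_optimal + skill.p_truth and tplacement is not None:
            category = "truth"
        else:
            category = "noisy"
        best: Placement | None = None
        best_score = -(10**9)
        for _ in range(par_redraw_cap):
            if category == "optimal":
                placement = sampler.sample_optimal(rng)
            elif category == "truth":
                placement = tplacement
            else:
                placement = sampler.sample_noisy(skill.noise_temperature, rng)
            s = score_placement(
                puzzle, placement, full_row_bonus, check_budget=True
            )
            if s > best_score:
                best, best_score = placement, s
            if s >= puzzle.par_score or category == "truth":
                # a truthful redraw is deterministic; emitting immediately
                # equals redrawing it to the cap and keeping best-so-far
                break
        solutions.append(
            Solution(
                puzzle_id=puzzle.id,
                player_id=f"{player_prefix}{pi:03d}",
                placement=best,
                score=best_score,
                gaps_used=gaps_used(best),
            )
        )
    return solutions
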