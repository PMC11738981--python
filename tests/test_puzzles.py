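"""Puzzle construction, scoring, greedy solving and acceptance rules."""

import numpy as np
import pytest

from crowdalign.io import Msa, ValidationError
from crowdalign.puzzles import (
    Guide,
    Puzzle,
    PuzzleParams,
    PuzzleRow,
    Region,
    accept_puzzle,
    build_puzzles,
    collapse_rows,
    compute_guides,
    gaps_used,
    gravity_placement,
    greedy_solve,
    local_to_global,
    mirror_puzzle,
    score_placement,
)
from conftest import brute_force_optimum, make_random_puzzle


@pytest.fixture
def msa6() -> Msa:
    return Msa(
        ids=tuple("abcdef"),
        rows=(
            "ACGU-ACGU-AC",
            "ACGUAACG--AC",
            "AC-UAACGUUAC",
            "CCGU-ACGU-AC",
            "ACGUAAC-UUAC",
            "AAGU-ACGUAAC",
        ),
    )


class TestGuides:
    def test_modal_symbol_and_frequency(self, msa6):
        guides = compute_guides(msa6, Region(0, 3, tuple("abcdef")))
        assert guides[0] == Guide("A", 5 / 6)
        assert guides[1].symbol == "C"
        # column 2: G,G,-,G,G,G -> five non-gap, all G
        assert guides[2] == Guide("G", 1.0)

    def test_gap_only_column_has_no_guide(self):
        msa = Msa(("a", "b"), ("A-", "C-"))
        guides = compute_guides(msa, Region(0, 2, ("a", "b")))
        assert guides[1].symbol is None

    def test_tie_broken_in_fixed_base_order(self):
        # {A, C} and {U, G} ties; enumerating both orders shows the rule
        msa = Msa(("a", "b"), ("AU", "CG"))
        guides = compute_guides(msa, Region(0, 2, ("a", "b")))
        assert guides[0].symbol == "A"
        assert guides[1].symbol == "G"

    def test_out_of_bounds_region_rejected(self, msa6):
        with pytest.raises(ValidationError):
            compute_guides(msa6, Region(8, 20, tuple("abc")))

    def test_offset_pulls_guides_from_shifted_columns(self, msa6):
        plain = compute_guides(msa6, Region(9, 11, tuple("abcdef")))
        shifted = compute_guides(msa6, Region(10, 12, tuple("abcdef")), offset=1)
        assert shifted == plain


class TestCollapse:
    def test_gap_removal_and_source_columns(self, msa6):
        rows, dropped = collapse_rows(
            msa6, Region(0, 4, ("c",)), 0.0, np.random.default_rng(0)
        )
        assert dropped == ()
        assert rows[0].residues == "ACU"
        assert rows[0].source_cols == (0, 1, 3)

    def test_no_perturbation_at_zero_probability(self, msa6):
        region = Region(2, 8, tuple("abcdef"))
        rows, _ = collapse_rows(msa6, region, 0.0, np.random.default_rng(1))
        for row in rows:
            assert all(2 <= c < 8 for c in row.source_cols)

    def test_forced_perturbation_changes_length_by_one(self, msa6):
        region = Region(2, 8, tuple("abcdef"))
        base, _ = collapse_rows(msa6, region, 0.0, np.random.default_rng(1))
        base_len = {r.seq_id: len(r.residues) for r in base}
        rows, _ = collapse_rows(msa6, region, 1.0, np.random.default_rng(7))
        for row in rows:
            diff = abs(len(row.residues) - base_len[row.seq_id])
            assert diff <= 1  # elongation may be impossible at full width

    def test_empty_rows_dropped(self):
        msa = Msa(("a", "b"), ("A---", "ACGU"))
        rows, dropped = collapse_rows(
            msa, Region(1, 4, ("a", "b")), 0.0, np.random.default_rng(0)
        )
        assert dropped == ("a",)
        assert [r.seq_id for r in rows] == ["b"]


def _guides(symbols: str):
    return tuple(
        Guide(s, 1.0) if s != "." else Guide(None, 0.0) for s in symbols
    )


def _puzzle(guide_str: str, residue_rows, budget: int = 4) -> Puzzle:
    rows = tuple(
        PuzzleRow(f"s{i}", res, tuple(range(len(res))))
        for i, res in enumerate(residue_rows)
    )
    return Puzzle(
        id="t",
        region=Region(0, len(guide_str), tuple(r.seq_id for r in rows)),
        rows=rows,
        guides=_guides(guide_str),
        width=len(guide_str),
        token_budget=budget,
        par_score=0,
    )


class TestScoring:
    def test_hand_scored_full_row_bonus(self):
        p = _puzzle("ACGU", ["ACU"])
        assert score_placement(p, ((0, 1, 3),)) == 5  # 3 matches + bonus 2
        assert score_placement(p, ((0, 1, 2),)) == 2  # gravity, U under G
        assert score_placement(p, gravity_placement(p)) == 2

    def test_empty_row_scores_zero_and_earns_no_bonus(self):
        rows = (PuzzleRow("s0", "A", (0,)), PuzzleRow("s1", "", ()))
        p = Puzzle(
            id="t", region=Region(0, 4, ("s0", "s1")), rows=rows,
            guides=_guides("ACGU"), width=4, token_budget=2, par_score=0,
        )
        # the full "A" row earns 1 + bonus 2; the empty row contributes
        # nothing, not even a full-row bonus
        assert score_placement(p, ((0,), ())) == 3

    def test_invalid_placements_rejected(self):
        p = _puzzle("ACGU", ["ACU"])
        with pytest.raises(ValidationError):
            score_placement(p, ((0, 0, 1),))  # not strictly increasing
        with pytest.raises(ValidationError):
            score_placement(p, ((0, 1, 4),))  # out of bounds
        with pytest.raises(ValidationError):
            score_placement(p, ((2, 3),))  # wrong residue count

    def test_budget_accounting_is_suffix_shift_tokens(self):
        assert gaps_used(((0, 1, 3),)) == 1  # one inserted gap before U
        assert gaps_used(((0, 1, 2),)) == 0  # gravity
        assert gaps_used(((1, 3, 3 + 1),)) == 2
        p = _puzzle("ACGU", ["ACU"], budget=0)
        with pytest.raises(ValidationError):
            score_placement(p, ((0, 1, 3),))  # costs 1 > budget 0

    def test_mirror_invariance_of_scores(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            p = make_random_puzzle(rng)
            g = gravity_placement(p)
            m = mirror_puzzle(p)
            reflected = tuple(
                tuple(sorted(p.width - 1 - c for c in cols)) for cols in g
            )
            assert score_placement(
                p, g, check_budget=False
            ) == score_placement(m, reflected, check_budget=False)


class TestGreedy:
    def test_single_insertion_example(self):
        p = _puzzle("ACGU", ["ACU"])
        result = greedy_solve(p, 4)
        assert result.placement == ((0, 1, 3),)
        assert result.tokens_used == 1
        assert result.score == 5

    def test_no_improving_move_spends_nothing(self):
        p = _puzzle("AC", ["AC"])
        result = greedy_solve(p, 4)
        assert result.tokens_used == 0
        assert result.score == score_placement(p, gravity_placement(p))

    def test_sandwich_gravity_greedy_optimum(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            p = make_random_puzzle(rng)
            gravity = score_placement(
                p, gravity_placement(p), check_budget=False
            )
            greedy = greedy_solve(p, p.token_budget)
            optimum = brute_force_optimum(p)
            assert gravity <= greedy.score <= optimum

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        p = make_random_puzzle(rng)
        r1 = greedy_solve(p, p.token_budget)
        r2 = greedy_solve(p, p.token_budget)
        assert r1 == r2


class TestBuild:
    def test_offset_worked_example(self, msa6):
        # guides of a [10, 14)-style region with offset 1 come from the
        # columns one to the left
        msa = Msa(
            tuple("ab"),
            ("ACGUACGUACGUAC", "ACGUACGUACGUAC"),
        )
        region = Region(10, 14, ("a", "b"))
        shifted = compute_guides(msa, region, offset=1)
        direct = compute_guides(msa, Region(9, 13, ("a", "b")))
        assert shifted == direct

    def test_variants_and_mirrors(self, msa6):
        params = PuzzleParams(min_rows=2, elong_prob=0.0, mirror=True,
                              offset_prob=0.0)
        region = Region(2, 10, tuple("abcdef"))
        built = build_puzzles(msa6, region, params, np.random.default_rng(0))
        assert built.rejection is None
        orientations = {p.orientation for p in built.puzzles}
        assert orientations == {"forward", "mirrored"}
        for orientation in orientations:
            budgets = sorted(
                p.token_budget
                for p in built.puzzles
                if p.orientation == orientation
            )
            assert budgets and budgets[-1] - budgets[0] <= 2

    def test_region_with_too_few_rows_rejected(self, msa6):
        params = PuzzleParams(min_rows=7)
        built = build_puzzles(
            msa6, Region(0, 4, tuple("abc")), params, np.random.default_rng(0)
        )
        assert built.puzzles == ()
        assert "need 7" in built.rejection

    def test_mirror_involution(self):
        rng = np.random.default_rng(2)
        p = make_random_puzzle(rng)
        back = mirror_puzzle(mirror_puzzle(p))
        assert back.rows == p.rows
        assert back.guides == p.guides
        assert back.orientation == p.orientation

    def test_local_to_global_mirror_consistency(self):
        rng = np.random.default_rng(4)
        p = make_random_puzzle(rng)
        m = mirror_puzzle(p)
        for c in range(p.width):
            assert local_to_global(p, c) == local_to_global(m, p.width - 1 - c)


class TestAcceptance:
    def test_local_optimum_at_start_rejected(self):
        import dataclasses
        p = _puzzle("AC", ["AC"], budget=2)
        par = greedy_solve(p, 2).score
        p = dataclasses.replace(p, par_score=par)
        ok, reason = accept_puzzle(p, PuzzleParams())
        assert not ok and "local optimum" in reason

    def test_improvable_puzzle_accepted(self):
        import dataclasses
        p = _puzzle("ACGU", ["ACU"], budget=3)
        p = dataclasses.replace(p, par_score=5)
        ok, reason = accept_puzzle(p, PuzzleParams())
        assert ok and reason is None

    def test_zero_budget_rejected(self):
        import dataclasses
        p = _puzzle("ACGU", ["ACU"], budget=0)
        p = dataclasses.replace(p, par_score=5)
        ok, reason = accept_puzzle(p, PuzzleParams())
        assert not ok
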