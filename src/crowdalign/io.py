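"""Alignment and puzzle-set input/output.

The pipeline's central container is :class:`Msa`, an immutable gapped
alignment over the RNA alphabet ``{A, C, G, U, -}``.  Sequences are read
with biopython (aligned FASTA or Stockholm) and normalized on input:
``T`` is mapped to ``U`` (16S data are DNA reads of an RNA gene),
lowercase is uppercased and ``.`` gaps become ``-``.  IUPAC ambiguity
codes are preserved but never match a guide and score zero in all
pairwise column scores.

Puzzle/solution sets travel as a versioned JSON document; see
:func:`write_puzzle_set` / :func:`read_puzzle_set`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"
RNA_BASES = "ACGU"
AMBIGUITY_CODES = frozenset("RYSWKMBDHVN")
ALPHABET = frozenset(RNA_BASES) | AMBIGUITY_CODES | {GAP}

SCHEMA_VERSION = 1

_FORMATS = ("fasta", "stockholm")


class FormatError(ValueError):
    """A file could not be parsed as the requested format."""


class ValidationError(ValueError):
    """An in-memory object violates a structural invariant."""


def normalize_sequence(seq: str) -> str:
    """Canonicalize one gapped row: uppercase, T->U, '.'->'-'.

    Idempotent by construction.
    """
    return seq.upper().replace("T", "U").replace(".", GAP)


@dataclass(frozen=True)
class Msa:
    """An ordered, identified gapped alignment of equal-width rows."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "rows", tuple(self.rows))
        if len(self.ids) != len(self.rows):
            raise ValidationError(
                f"{len(self.ids)} ids but {len(self.rows)} rows"
            )
        if not self.ids:
            raise ValidationError("alignment must contain at least one sequence")
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            dup = next(i for i in self.ids if i in seen or seen.add(i))
            raise ValidationError(f"duplicate sequence id {dup!r}")
        width = len(self.rows[0])
        for sid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise ValidationError(
                    f"ragged alignment: sequence {sid!r} has length "
                    f"{len(row)}, expected {width}"
                )
            bad = set(row) - ALPHABET
            if bad:
                raise ValidationError(
                    f"sequence {sid!r} contains invalid symbols {sorted(bad)}"
                )
            if set(row) == {GAP}:
                raise ValidationError(f"sequence {sid!r} is all-gap")
        if width == 0:
            raise ValidationError("alignment has zero columns")

    @property
    def width(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, seq_id: str) -> str:
        return self.rows[self.index(seq_id)]

    def index(self, seq_id: str) -> int:
        try:
            return self.ids.index(seq_id)
        except ValueError:
            raise KeyError(f"unknown sequence id {seq_id!r}") from None

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def residue_columns(self, seq_id: str) -> tuple[int, ...]:
        """Global column index of each residue, in sequence order."""
        return tuple(
            c for c, ch in enumerate(self.row(seq_id)) if ch != GAP
        )

    def column(self, col: int) -> str:
        return "".join(row[col] for row in self.rows)


def read_alignment(path: str | Path, format: str = "fasta") -> Msa:
    """Read an aligned FASTA or Stockholm file into an :class:`Msa`."""
    fmt = format.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported alignment format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        records = list(SeqIO.parse(str(path), fmt))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no sequences found ({fmt})")
    ids = [r.id for r in records]
    rows = [normalize_sequence(str(r.seq)) for r in records]
    width = len(rows[0])
    for sid, row in zip(ids, rows):
        if len(row) != width:
            raise FormatError(
                f"{path}: ragged alignment at sequence {sid!r} "
                f"(length {len(row)}, expected {width})"
            )
    try:
        return Msa(tuple(ids), tuple(rows))
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_alignment(msa: Msa, path: str | Path, format: str = "fasta") -> None:
    """Write an :class:`Msa`; round-trips exactly through read_alignment."""
    fmt = format.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported alignment format {format!r}")
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(msa.ids, msa.rows)
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, fmt)


# ---------------------------------------------------------------------------
# Puzzle / solution JSON document
# ---------------------------------------------------------------------------

def _require(obj: dict, key: str, types, path: str):
    if key not in obj:
        raise ValidationError(f"{path}.{key}: missing required field")
    val = obj[key]
    if not isinstance(val, types):
        raise ValidationError(
            f"{path}.{key}: expected {types}, got {type(val).__name__}"
        )
    return val


def puzzle_to_dict(puzzle) -> dict:
    return {
        "id": puzzle.id,
        "region": {
            "col_start": puzzle.region.col_start,
            "col_end": puzzle.region.col_end,
            "row_ids": list(puzzle.region.row_ids),
        },
        "rows": [
            {
                "seq_id": r.seq_id,
                "residues": r.residues,
                "source_cols": list(r.source_cols),
            }
            for r in puzzle.rows
        ],
        "guides": [{"symbol": g.symbol, "freq": g.freq} for g in puzzle.guides],
        "width": puzzle.width,
        "token_budget": puzzle.token_budget,
        "par_score": puzzle.par_score,
        "orientation": puzzle.orientation,
        "offset": puzzle.offset,
        "variant": puzzle.variant,
    }


def dict_to_puzzle(d: dict, path: str = "puzzle"):
    from .puzzles import Guide, Puzzle, PuzzleRow, Region

    region = _require(d, "region", dict, path)
    rows = _require(d, "rows", list, path)
    guides = _require(d, "guides", list, path)
    reg = Region(
        col_start=_require(region, "col_start", int, f"{path}.region"),
        col_end=_require(region, "col_end", int, f"{path}.region"),
        row_ids=tuple(_require(region, "row_ids", list, f"{path}.region")),
    )
    prows = []
    for i, r in enumerate(rows):
        rp = f"{path}.rows[{i}]"
        if not isinstance(r, dict):
            raise ValidationError(f"{rp}: expected object")
        prows.append(
            PuzzleRow(
                seq_id=_require(r, "seq_id", str, rp),
                residues=_require(r, "residues", str, rp),
                source_cols=tuple(_require(r, "source_cols", list, rp)),
            )
        )
    pguides = []
    for i, g in enumerate(guides):
        gp = f"{path}.guides[{i}]"
        if not isinstance(g, dict):
            raise ValidationError(f"{gp}: expected object")
        sym = _require(g, "symbol", (str, type(None)), gp)
        pguides.append(Guide(symbol=sym, freq=_require(g, "freq", (int, float), gp)))
    return Puzzle(
        id=_require(d, "id", str, path),
        region=reg,
        rows=tuple(prows),
        guides=tuple(pguides),
        width=_require(d, "width", int, path),
        token_budget=_require(d, "token_budget", int, path),
        par_score=_require(d, "par_score", int, path),
        orientation=_require(d, "orientation", str, path),
        offset=_require(d, "offset", int, path),
        variant=_require(d, "variant", int, path),
    )


def solution_to_dict(solution) -> dict:
    return {
        "puzzle_id": solution.puzzle_id,
        "player_id": solution.player_id,
        "placements": [list(cols) for cols in solution.placement],
        "score": solution.score,
        "gaps_used": solution.gaps_used,
    }


def dict_to_solution(d: dict, path: str = "solution"):
    from .puzzles import Solution

    placements = _require(d, "placements", list, path)
    for i, cols in enumerate(placements):
        if not isinstance(cols, list):
            raise ValidationError(f"{path}.placements[{i}]: expected list")
    return Solution(
        puzzle_id=_require(d, "puzzle_id", str, path),
        player_id=_require(d, "player_id", str, path),
        placement=tuple(tuple(cols) for cols in placements),
        score=_require(d, "score", int, path),
        gaps_used=_require(d, "gaps_used", int, path),
    )


def write_puzzle_set(puzzles: Iterable, solutions: Iterable, path: str | Path,
                     extra: dict | None = None) -> None:
    """Write puzzles and solutions to one JSON document (lossless)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "puzzles": [puzzle_to_dict(p) for p in puzzles],
        "solutions": [solution_to_dict(s) for s in solutions],
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as handle:
        json.dump(doc, handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_puzzle_set(path: str | Path):
    """Read a puzzle-set document; returns ``(puzzles, solutions)``."""
    with open(path) as handle:
        try:
            doc = json.load(handle)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise ValidationError("$: expected top-level object")
    version = _require(doc, "schema_version", int, "$")
    if version != SCHEMA_VERSION:
        raise ValidationError(f"$.schema_version: unsupported version {version}")
    puzzles = [
        dict_to_puzzle(d, f"$.puzzles[{i}]")
        for i, d in enumerate(_require(doc, "puzzles", list, "$"))
    ]
    known = {p.id for p in puzzles}
    solutions = []
    for i, d in enumerate(_require(doc, "solutions", list, "$")):
        sol = dict_to_solution(d, f"$.solutions[{i}]")
        if sol.puzzle_id not in known:
            raise ValidationError(
                f"$.solutions[{i}].puzzle_id: unknown puzzle {sol.puzzle_id!r}"
            )
        solutions.append(sol)
    return puzzles, solutions
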