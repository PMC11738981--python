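# Methods

## Overview

`crowdalign` implements a crowd-computation pipeline for correcting a
scaffold multiple sequence alignment.  The scaffold is cut into small
rectangular puzzles; each puzzle is solved many times (here, by a
simulated player crowd); solutions are filtered by consensus; the
survivors become per-residue positional votes; and each sequence is
realigned to its vote array with a Needleman–Wunsch-style dynamic
program.  An evaluation layer scores alignments (sum-of-pairs, gap
statistics) and compares phylogenies estimated from them
(Kendall–Colijn and triplet distances under a sampled-subtree
protocol).

All sequences live on the RNA alphabet {A, C, G, U, -}; T is mapped to
U on input, '.' gaps to '-', and IUPAC ambiguity codes are carried
through but never match a guide and score zero in pairwise column
scores.  All coordinates are 0-based and half-open.

## The puzzle model

A **region** is a window of `col_start..col_end` scaffold columns
(width 4–10 by default) over 7–20 sequences.  Each row is collapsed:
gaps removed, residues packed left ("gravity"), with per-residue
source-column bookkeeping retained.  Per puzzle, each row is perturbed
with probability `elong_prob` (default 0.15): a fair coin chooses
between dropping the last residue and appending the sequence's next
residue beyond the window (when one exists and the fragment is not
already window-wide).  Perturbation is re-rolled independently for
every emitted puzzle of a region, so a single unlucky roll cannot bias
all of a region's cohorts at once.

**Guides** are the modal non-gap base of each column over the region's
rows (ties broken A < C < G < U; gap-only columns have no guide).  A
**placement** assigns every row's residues to strictly increasing local
columns.  Its score is the number of residues matching their guide plus
`full_row_bonus` (default 2; the bonus size is a free parameter of the
game design) for each fully matching nonempty row.  A **gap token** is
one insertion that shifts a row suffix right by one column; a
placement's token cost is Σ_rows (last column + 1 − residue count), and
must not exceed the puzzle's budget.

A deterministic **greedy player** hill-climbs from gravity by applying
the single insertion with the largest strict score gain (ties: lowest
row, then lowest gap position).  Its token consumption B under the
token cap sets the puzzle's budget; the three variants use budgets
{B, B+1, max(B−1, 1)} with par re-computed by greedy under each budget.
Mirrored (column-reversed) puzzles are built with their own budgets,
and with probability `offset_prob` the guides are drawn from columns
shifted `offset` to the left (out-of-range columns get no guide).
Puzzles whose par exceeds the gravity score by less than
`min_improvement` (default 2), or with no tokens, are rejected — the
gravity state is already a local optimum and players would have nothing
to do.

The budget floor used by the synthetic benchmarks is capped per puzzle
at the total number of empty cells, Σ_rows (width − residue count),
beyond which tokens are physically unspendable; this keeps the
placement-space dynamic programs small without changing what players
can express.

## The synthetic benchmark

`simulate_benchmark` emulates the statistical structure the pipeline
assumes — strong columnar conservation, a low indel rate, and a
scaffold that is nearly correct:

* a Yule (pure-birth) tree on `n_seqs` tips (default 30), exponential
  waiting times, uniform lineage splits;
* a root sequence of `n_cols` (default 60) uniform bases evolved down
  the tree; per branch, each live site substitutes with probability
  `sub_rate` (default 0.05, to a uniformly chosen different base) and
  is deleted with probability `indel_rate` (default 0.02).  Deletions
  are single-column and permanent, so the true column history — and
  hence the true alignment, of width exactly `n_cols` — is trivially
  well defined.  The defaults were chosen once so that a 30-tip tree
  yields moderate divergence and roughly 4–6 gaps per row, i.e. most
  rows are corruptible;
* a corrupted copy: each row, with probability `corruption_rate`
  (default 0.3), has one randomly chosen gap slid 1–2 columns (clamped
  at the edges), preserving the row's ungapped sequence.  The corrupted
  copy is the scaffold the pipeline must repair.

What this generator does **not** model: insertions (no new columns in
the truth), rate heterogeneity across sites or lineages, secondary
structure, sequencing error, or alignment errors other than local gap
slides.  Passing tests therefore demonstrate that the machinery
recovers *this* class of error under *this* model of player behaviour,
not that it improves arbitrary real alignments.

## The simulated crowd

Each player draws one behaviour category from a `SkillProfile`:

* **optimal** (`p_optimal`): a uniformly random maximum-score placement
  within budget.  Scores are separable per row and couple only through
  the token budget, so an exact (row × remaining-tokens) dynamic
  program enumerates the maxima and samples uniformly among them;
* **truthful** (`p_truth`): the placement reproducing the true local
  alignment, obtained by monotonically projecting each row's true
  columns into the puzzle frame (residues whose true column falls
  outside the frame — elongated bricks, patterns crossing the window
  boundary — are clamped to the nearest feasible column).  If the
  projected placement needs more tokens than the budget allows, the
  player falls back to noisy;
* **noisy** (rest): a placement drawn with probability proportional to
  exp(score / temperature), sampled exactly by the same
  budget-coupled DP (per-row weights are shifted by the row maximum,
  so the zero-temperature limit degenerates to the optimum).

Every emitted solution must reach the puzzle's par score; failing draws
are redrawn within the player's category up to 50 times, after which
the best candidate seen is emitted.  A truthful redraw is
deterministic, so truthful players effectively always submit the truth,
beating par or not — mirroring a player who plays their best and moves
on.  A par that the brute-force optimum cannot reach raises an error
(it signals a buggy puzzle).

## Consensus filtering

Per puzzle, each solution gets two anomaly scores: `d_opt`, the score
deficit against the best submitted solution using the same number of
gap tokens, and `d_cons`, the Euclidean distance between its binary
(row, column)-occupancy vector and the cohort centroid (the mean of
those vectors).  Both are standardized within the puzzle (zero variance
maps to zero) and combined with weights `w_opt = w_cons = 1`.  The
⌈keep_fraction · n⌉ solutions with smallest combined badness are kept
(default 1/3, i.e. about two-thirds excluded); ties break by lower
`d_opt`, then input order.  A deterministic per-puzzle quantile makes the
exclusion fraction exact and reproducible, rather than relying on a
hand-tuned threshold.

## Votes and realignment

Each kept residue placement casts one vote: the residue (identified
through the row's source column) votes for the global column
`col_start − offset + local` (mirror-reflected for mirrored puzzles, so
a mirrored solution votes identically to its forward twin).  Votes
outside the alignment are clipped to the boundary and logged.  Raw
counts are normalized per residue to sum to one — a residue covered by
40 solutions weighs no more than one covered by 10 — and residues with
no votes receive a single pseudo-vote of `prior_weight` (default 0.5,
dominated by any unanimous real vote) at their scaffold column.

Realignment solves, independently per sequence, the maximum-weight
strictly monotone assignment of residues to column slots:

    M[i][c] = max(M[i][c−1], M[i−1][c−1] + W[i][c−1]),  M[0][·] = 0,

with traceback ties preferring the residue's scaffold slot and then the
leftmost slot; this is the minimal Needleman–Wunsch variant that aligns
a sequence to an array of votes, with no separate gap penalty (absent
vote mass is the penalty).  Residues are written into their assigned
slots, slots empty across all sequences are dropped, and the output
row's ungapped sequence always equals the scaffold's.  With zero player
signal the scaffold is reproduced exactly (identity fixed point).

The slot axis is the scaffold columns; `slack > 0` optionally
interleaves unlabelled insertion slots after region-boundary columns,
allowing opt-in width growth (default 0, logged when used).

## Benchmark experiments

`tile_regions` covers the scaffold with windows of `region_width`
(default 8) advancing by `region_stride`, plus tapering edge windows of
width `min_width..region_width−1` at both ends; rows are partitioned
into blocks of 7–20.  Two preconfigured experiments:

* `benchmark_config()` — study defaults plus two adaptations to the
  synthetic benchmark: the token budget is floored so the truthful
  category is expressible (game-style budgets assume a much tighter
  scaffold), and guide offsets are disabled, since a row
  filling its window cannot be shifted at all and offset solutions are
  therefore structurally biased toward the guides; they need a
  dedicated aggregation scheme and are left out of the corrected
  alignment here.
* `recovery_config()` — the sufficient-information regime for exact
  recovery: stride-1 tiling (each cell covered by many frames, so the
  few frames that truncate a boundary-crossing pattern are outvoted),
  no row perturbation, no mirroring, no puzzle rejection.

Agreement with the truth is measured as the fraction of residues
assigned to their true columns (the scaffold's agreement uses its own
columns).  Tree-level evaluation builds neighbor-joining trees from
Jukes–Cantor distances (gap-excluded pairwise sites, capped where the
correction diverges, negative branch lengths clamped to zero, midpoint
rooted) for the scaffold and realigned alignments and compares both to
the generating tree with the sampled Kendall–Colijn protocol, using the
same tip samples for both sides of each comparison.  At benchmark
scale the protocol is scaled to 20 tips × 20 replicates (the full
404-taxon protocol defaults, 400 × 100 and 100 × 5, remain the module
defaults).

## Evaluation metrics

* **Sum-of-pairs**: Σ over retained columns of Σ_b C(count_b, 2) over
  the four bases; the two column filters are a gap-fraction ceiling
  (default 0.5) and the k most populated columns (default 150, ties to
  the lower index).
* **Gap statistics**: per-column gap fractions, and mean gaps per
  sequence over row subsamples of fixed size (default 50) so
  alignments of different depths compare fairly.
* **Kendall–Colijn**: for the sorted tip set, the vector of
  (1−λ)·edge-depth + λ·path-length of root→MRCA for every tip pair,
  followed by per-tip entries (1−λ) + λ·pendant length; the distance is
  the Euclidean norm of the vector difference.  λ defaults to 0
  (topology only).  Sampling the protocol's "nodes" is interpreted as
  sampling tips, since the metric is defined on tip sets.
* **Triplet distance**: direct enumeration over all C(n,3) tip triples
  of the induced rooted topology (the pair with the strictly deepest
  MRCA is the cherry; all-equal depths mean unresolved), counting
  triples that differ; unresolved counts as differing from every
  resolved topology.  n is capped (default 200) to bound the O(n³)
  cost; callers sample first.
* **Compound score**: each metric's per-method means are divided by
  their maximum across methods, then averaged per method — an
  order-preserving summary in [0, 1].

## Numerical and degenerate-input choices

* Guide ties: fixed order A < C < G < U; all puzzle generation is
  deterministic given one seed (`numpy` Generators throughout, one
  `SeedSequence` spawned per pipeline stage).
* The optimal-placement sampler counts maximizers in exact integer
  arithmetic, so the uniform draw is exact even for astronomically
  many maxima; the Boltzmann sampler shifts scores by the per-row
  maximum before exponentiating and falls back to the optimal sampler
  on complete underflow.
* Realign DP ties are resolved on exact float equality (ties arise
  from identical sums, e.g. uniform priors), preferring scaffold slots
  and then leftmost.
* Empty puzzle rows are dropped with a log record; all-gap region rows
  never enter a puzzle; an empty vote row is impossible after
  `fill_unvoted` (every residue gets at least the prior).
* JC distances: sites where either sequence is gapped are excluded;
  observed divergence ≥ 0.749 (or no shared sites) maps to a capped
  distance of 5.0 substitutions/site.

## Known limitations

* Offset-puzzle votes are mapped like normal votes but, per the above,
  are biased where rows fill their window; they are generated and
  unit-tested but excluded from the benchmark experiments.
* The player model has no learning, fatigue or per-player reliability;
  filtering is per-solution, not per-player.
* The benchmark's deletion-only indel model cannot create new columns,
  so output width growth (the `slack` mechanism) is effectively
  unexercised end to end.
* Neighbor joining on short (60-column) alignments yields noisy trees;
  the tree-level comparison is therefore the weakest signal in the
  benchmark summary, and is reported as a paired no-worse fraction
  rather than a margin.
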