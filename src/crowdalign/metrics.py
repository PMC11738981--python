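"""Alignment- and phylogeny-quality metrics.

Alignment side: sum-of-pairs with optional heavy-gap column exclusion
(either a gap-fraction ceiling or the k most populated columns),
per-column gap frequencies, and gap statistics over sampled fixed-size
sub-alignments so alignments of different depths compare fairly.

Phylogeny side: the Kendall-Colijn metric (Euclidean distance between
vectors of root-to-MRCA depths over all tip pairs, plus per-tip entries;
lambda blends topology with branch lengths) and the rooted triplet
distance (number of 3-tip subsets whose induced topology differs).  Both
are evaluated under a sampled-subtree protocol for large trees, and a
per-method compound score rescales and averages the two.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .io import GAP, RNA_BASES, Msa, ValidationError


# ---------------------------------------------------------------------------
# Alignment metrics
# ---------------------------------------------------------------------------

def _column_mask(
    arr: np.ndarray,
    gap_fraction_max: float | None,
    top_k_populated: int | None,
) -> np.ndarray:
    n_rows, width = arr.shape
    if gap_fraction_max is not None and top_k_populated is not None:
        raise ValidationError("choose at most one column filter mode")
    mask = np.ones(width, dtype=bool)
    if gap_fraction_max is not None:
        gap_frac = (arr == GAP).mean(axis=0)
        mask = gap_frac <= gap_fraction_max
    elif top_k_populated is not None:
        populated = (arr != GAP).sum(axis=0)
        k = min(top_k_populated, width)
        # stable: ties go to the lower column index
        keep = np.argsort(-populated, kind="stable")[:k]
        mask = np.zeros(width, dtype=bool)
        mask[keep] = True
    return mask


def sum_of_pairs(
    msa: Msa,
    gap_fraction_max: float | None = None,
    top_k_populated: int | None = None,
) -> int:
    """Identical-non-gap pair count summed over the retained columns.

    Each column contributes sum_b C(count_b, 2) over the four bases;
    ambiguity codes and gaps score zero with everything.
    """
    arr = np.array([list(r) for r in msa.rows])
    mask = _column_mask(arr, gap_fraction_max, top_k_populated)
    total = 0
    sub = arr[:, mask]
    for base in RNA_BASES:
        counts = (sub == base).sum(axis=0)
        total += int((counts * (counts - 1) // 2).sum())
    return total


def gap_frequencies(msa: Msa) -> np.ndarray:
    """Per-column gap fraction; length equals the alignment width."""
    arr = np.array([list(r) for r in msa.rows])
    return (arr == GAP).mean(axis=0)


@dataclass(frozen=True)
class GapStats:
    samples: np.ndarray  # mean gaps per sequence, one entry per sub-alignment
    quartiles: tuple[float, float, float]
    subsample_size: int
    n_samples: int


def sampled_gap_stats(
    msa: Msa,
    subsample_size: int = 50,
    n_samples: int = 100,
    rng: np.random.Generator | None = None,
) -> GapStats:
    """Mean gaps per sequence over row subsamples of fixed size."""
    if subsample_size > msa.n_rows:
        raise ValidationError(
            f"subsample_size {subsample_size} exceeds {msa.n_rows} rows"
        )
    if rng is None:
        rng = np.random.default_rng()
    gap_counts = np.array([row.count(GAP) for row in msa.rows], float)
    samples = np.array(
        [
            gap_counts[
                rng.choice(msa.n_rows, size=subsample_size, replace=False)
            ].mean()
            for _ in range(n_samples)
        ]
    )
    q1, q2, q3 = np.percentile(samples, [25, 50, 75])
    return GapStats(
        samples=samples,
        quartiles=(float(q1), float(q2), float(q3)),
        subsample_size=subsample_size,
        n_samples=n_samples,
    )


# ---------------------------------------------------------------------------
# Tree metrics
# ---------------------------------------------------------------------------

def _mrca_depth_matrices(
    tree: TreeNode, tips: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Root-to-MRCA depth for every tip pair: (edge counts, path lengths)."""
    index = {name: i for i, name in enumerate(tips)}
    n = len(tips)
    topo = np.zeros((n, n))
    blen = np.zeros((n, n))
    depths: dict[int, tuple[int, float]] = {id(tree): (0, 0.0)}
    below: dict[int, list[int]] = {}
    found = 0
    for node in tree.preorder(include_self=False):
        d, dl = depths[id(node.parent)]
        depths[id(node)] = (d + 1, dl + (node.length or 0.0))
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            i = index.get(node.name)
            below[id(node)] = [i] if i is not None else []
            if i is not None:
                found += 1
            continue
        kid_sets = [below.pop(id(ch)) for ch in node.children]
        d, dl = depths[id(node)]
        for a, b in itertools.combinations(range(len(kid_sets)), 2):
            ia = np.array(kid_sets[a], dtype=int)
            ib = np.array(kid_sets[b], dtype=int)
            if len(ia) and len(ib):
                topo[np.ix_(ia, ib)] = d
                topo[np.ix_(ib, ia)] = d
                blen[np.ix_(ia, ib)] = dl
                blen[np.ix_(ib, ia)] = dl
        below[id(node)] = [i for s in kid_sets for i in s]
    if found != n:
        missing = set(tips) - {t.name for t in tree.tips()}
        raise ValidationError(f"tips not in tree: {sorted(missing)[:5]}")
    return topo, blen


def _pendant_lengths(tree: TreeNode, tips: list[str]) -> np.ndarray:
    by_name = {t.name: (t.length or 0.0) for t in tree.tips()}
    return np.array([by_name[name] for name in tips])


def kc_vector(
    tree: TreeNode, tips: list[str] | tuple[str, ...], lam: float = 0.0
) -> np.ndarray:
    """Kendall-Colijn vector over the given tips (sorted lexicographically).

    Pair entries blend root->MRCA edge counts and path lengths by lambda;
    tip entries are (1-lambda)*1 + lambda*pendant_length.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValidationError("lambda must be in [0, 1]")
    tips = sorted(tips)
    topo, blen = _mrca_depth_matrices(tree, tips)
    iu = np.triu_indices(len(tips), k=1)
    pairs = (1.0 - lam) * topo[iu] + lam * blen[iu]
    tip_entries = (1.0 - lam) * np.ones(len(tips)) + lam * _pendant_lengths(
        tree, tips
    )
    return np.concatenate([pairs, tip_entries])


def kc_distance(
    t1: TreeNode,
    t2: TreeNode,
    tips: list[str] | None = None,
    lam: float = 0.0,
) -> float:
    """Euclidean Kendall-Colijn distance on the shared tip set."""
    if tips is None:
        shared = {t.name for t in t1.tips()} & {t.name for t in t2.tips()}
        tips = sorted(shared)
    if not tips:
        raise ValidationError("no shared tips")
    v1 = kc_vector(t1, tips, lam)
    v2 = kc_vector(t2, tips, lam)
    return float(np.linalg.norm(v1 - v2))


def _triple_categories(topo: np.ndarray, triples: np.ndarray) -> np.ndarray:
    """0 = unresolved, 1/2/3 = cherry (ij)/(ik)/(jk) per triple."""
    i, j, k = triples[:, 0], triples[:, 1], triples[:, 2]
    dij = topo[i, j]
    dik = topo[i, k]
    djk = topo[j, k]
    cats = np.zeros(len(triples), dtype=np.int8)
    cats[(dij > dik) & (dij > djk)] = 1
    cats[(dik > dij) & (dik > djk)] = 2
    cats[(djk > dij) & (djk > dik)] = 3
    return cats


def triplet_distance(
    t1: TreeNode,
    t2: TreeNode,
    tips: list[str] | None = None,
    cap: int = 200,
) -> int:
    """Count of 3-tip subsets whose induced rooted topology differs.

    Direct O(n^3) enumeration over MRCA-depth matrices; a polytomy triple
    ("unresolved") differs from every resolved topology.
    """
    if tips is None:
        shared = {t.name for t in t1.tips()} & {t.name for t in t2.tips()}
        tips = sorted(shared)
    else:
        tips = sorted(tips)
    if len(tips) < 3:
        raise ValidationError("need at least 3 shared tips")
    if len(tips) > cap:
        raise ValidationError(
            f"{len(tips)} tips exceeds the O(n^3) cap of {cap}; sample first"
        )
    topo1, _ = _mrca_depth_matrices(t1, tips)
    topo2, _ = _mrca_depth_matrices(t2, tips)
    triples = np.array(
        list(itertools.combinations(range(len(tips)), 3)), dtype=int
    )
    c1 = _triple_categories(topo1, triples)
    c2 = _triple_categories(topo2, triples)
    return int((c1 != c2).sum())


@dataclass(frozen=True)
class DistanceReport:
    metric: str
    distances: tuple[float, ...]
    mean: float
    n_tips_sampled: int
    n_replicates: int


_METRICS = {
    "kendall_colijn": lambda a, b, tips: kc_distance(a, b, tips),
    "triplet": lambda a, b, tips: float(triplet_distance(a, b, tips)),
}

#: Sampling protocol defaults for large-tree comparison.
KC_SAMPLE_TIPS = 400
KC_REPLICATES = 100
TRIPLET_SAMPLE_TIPS = 100
TRIPLET_REPLICATES = 5


def sampled_tree_distance(
    t1: TreeNode,
    t2: TreeNode,
    metric: str = "kendall_colijn",
    n_tips: int | None = None,
    n_reps: int | None = None,
    rng: np.random.Generator | None = None,
) -> DistanceReport:
    """Mean metric over random same-tip shearings of both trees.

    Defaults: 400 tips x 100 replicates for Kendall-Colijn, 100 tips x 5
    replicates for the triplet distance.
    """
    if metric not in _METRICS:
        raise ValidationError(f"unknown metric {metric!r}")
    if n_tips is None:
        n_tips = KC_SAMPLE_TIPS if metric == "kendall_colijn" else TRIPLET_SAMPLE_TIPS
    if n_reps is None:
        n_reps = KC_REPLICATES if metric == "kendall_colijn" else TRIPLET_REPLICATES
    if rng is None:
        rng = np.random.default_rng()
    shared = sorted(
        {t.name for t in t1.tips()} & {t.name for t in t2.tips()}
    )
    if len(shared) < n_tips:
        raise ValidationError(
            f"only {len(shared)} shared tips, need {n_tips}"
        )
    fn = _METRICS[metric]
    distances = []
    for _ in range(n_reps):
        sample = sorted(
            np.array(shared)[
                rng.choice(len(shared), size=n_tips, replace=False)
            ].tolist()
        )
        s1 = t1.shear(sample)
        s2 = t2.shear(sample)
        distances.append(float(fn(s1, s2, sample)))
    return DistanceReport(
        metric=metric,
        distances=tuple(distances),
        mean=float(np.mean(distances)),
        n_tips_sampled=n_tips,
        n_replicates=n_reps,
    )


def compound_distance(
    kc_means: dict, triplet_means: dict
) -> dict:
    """Per-method average of max-scaled KC and triplet means (in [0, 1])."""
    if set(kc_means) != set(triplet_means):
        raise ValidationError("method sets differ between the two metrics")
    if not kc_means:
        raise ValidationError("no methods given")
    kc_max = max(kc_means.values())
    tr_max = max(triplet_means.values())
    if kc_max <= 0 or tr_max <= 0:
        raise ValidationError("at least one method must have positive distances")
    return {
        m: (kc_means[m] / kc_max + triplet_means[m] / tr_max) / 2.0
        for m in kc_means
    }
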