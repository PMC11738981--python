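"""Rooted-tree I/O and baseline tree estimation.

Trees are scikit-bio :class:`~skbio.TreeNode` objects throughout: rooted,
uniquely tip-labeled, with optional nonnegative branch lengths.  Besides
newick reading/writing this module provides a small neighbor-joining
builder on Jukes-Cantor distances so benchmark alignments can be turned
into trees without external tree software.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .io import GAP, Msa, FormatError, ValidationError

#: JC69 correction diverges as the observed mismatch fraction approaches
#: 3/4; distances beyond this point are capped at this value.
MAX_JC_DISTANCE = 5.0


def validate_tree(tree: TreeNode) -> TreeNode:
    names = [t.name for t in tree.tips()]
    if any(n is None for n in names):
        raise ValidationError("tree has unlabeled tips")
    if len(set(names)) != len(names):
        seen: set[str] = set()
        dup = next(n for n in names if n in seen or seen.add(n))
        raise ValidationError(f"duplicate tip label {dup!r}")
    for node in tree.non_tips(include_self=True):
        if len(node.children) < 2:
            raise ValidationError(
                "internal node with a single child (tree is not properly rooted)"
            )
    return tree


def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted newick tree, preserving branch lengths if present."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises format-specific subclasses
        raise FormatError(f"{path}: invalid newick: {exc}") from exc
    return validate_tree(tree)


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def jukes_cantor_distances(msa: Msa) -> DistanceMatrix:
    """Pairwise JC69 distances, ignoring sites where either row is gapped."""
    arr = np.array([list(r) for r in msa.rows])
    n = len(msa.ids)
    gaps = arr == GAP
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~(gaps[i] | gaps[j])
            total = int(shared.sum())
            if total == 0:
                d = MAX_JC_DISTANCE
            else:
                p = float((arr[i, shared] != arr[j, shared]).mean())
                if p >= 0.749:
                    d = MAX_JC_DISTANCE
                else:
                    d = -0.75 * np.log1p(-4.0 * p / 3.0)
            dm[i, j] = dm[j, i] = d
    return DistanceMatrix(dm, ids=list(msa.ids))


def nj_jukes_cantor(msa: Msa, midpoint_root: bool = True) -> TreeNode:
    """Neighbor-joining tree from JC distances; midpoint-rooted by default.

    A convenience baseline for benchmark evaluation, not a substitute for
    a maximum-likelihood tree on real data.  Negative NJ branch lengths
    are clamped to zero.
    """
    tree = nj(jukes_cantor_distances(msa))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    if midpoint_root:
        tree = tree.root_at_midpoint()
        for node in tree.traverse():
            if node.length is not None and node.length < 0:
                node.length = 0.0
    return tree
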