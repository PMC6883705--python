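"""Distance-based gene trees and synteny-pairing support bookkeeping.

Homologous protein alignments are summarised by Kimura-corrected distances,
clustered by UPGMA into ultrametric gene trees, and the fraction of
*informative* trees containing the expected (basal, core) chromosome
pairings as clades is reported.  Tree building is deliberately simple --
the contribution here is the support-fraction bookkeeping, not phylogenetic
sophistication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from skbio import TreeNode

from .model import SaturationError, ValidationError

__all__ = [
    "DistanceMatrix",
    "kimura_protein_distance",
    "upgma",
    "leaf_chromosomes",
    "pairing_support_fraction",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        if (self.d < -1e-12).any():
            raise ValidationError("distances must be non-negative")


def kimura_protein_distance(seq_a: str, seq_b: str) -> float:
    """Kimura-corrected protein distance: with p the mismatch fraction over
    pairwise-ungapped columns, d = -ln(1 - p - 0.2 p^2).

    Raises :class:`SaturationError` when the correction is undefined.
    """
    if len(seq_a) != len(seq_b):
        raise ValidationError("aligned sequences must have equal length")
    valid = mism = 0
    for a, b in zip(seq_a, seq_b):
        if a == "-" or b == "-":
            continue
        valid += 1
        if a != b:
            mism += 1
    if valid == 0:
        raise ValidationError("no ungapped columns shared by the two sequences")
    p = mism / valid
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0:
        raise SaturationError(f"p={p:.3f} saturates the Kimura correction")
    return -math.log(arg)


def upgma(labels: Sequence[str], d) -> TreeNode:
    """Average-linkage (UPGMA) agglomeration into a rooted ultrametric tree.

    Branch lengths are half the merge-height differences; ties in minimum
    distance are broken deterministically toward the cluster pair whose
    smallest leaf labels sort first.
    """
    dm = DistanceMatrix(list(labels), d)
    n = len(dm.labels)
    if n < 2:
        raise ValidationError("UPGMA needs at least 2 leaves")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=dm.labels[i]) for i in range(n)
    }
    heights = {i: 0.0 for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    minleaf = {i: dm.labels[i] for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(dm.d[i, j])
    active = set(range(n))
    next_id = n
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if i >= j:
                    continue
                key = (
                    dist[(i, j)],
                    min(minleaf[i], minleaf[j]),
                    max(minleaf[i], minleaf[j]),
                )
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        h = dist[(i, j)] / 2.0
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = h - heights[i]
        nodes[j].length = h - heights[j]
        new = next_id
        next_id += 1
        for k in sorted(active - {i, j}):
            dij_k = (
                dist[tuple(sorted((i, k)))] * sizes[i]
                + dist[tuple(sorted((j, k)))] * sizes[j]
            ) / (sizes[i] + sizes[j])
            dist[(min(new, k), max(new, k))] = dij_k
        nodes[new] = parent
        heights[new] = h
        sizes[new] = sizes[i] + sizes[j]
        minleaf[new] = min(minleaf[i], minleaf[j])
        active -= {i, j}
        active.add(new)
    root = nodes[next_id - 1]
    root.length = None
    return root


def leaf_chromosomes(tree: TreeNode, tags: dict[str, str]) -> dict[str, str]:
    """Map each leaf name to its chromosome tag (``tags``: gene id -> chrom)."""
    out = {}
    for tip in tree.tips():
        if tip.name not in tags:
            raise ValidationError(f"leaf {tip.name!r} has no chromosome tag")
        out[tip.name] = tags[tip.name]
    return out


def _is_informative(tree: TreeNode, tags: dict[str, str], required: set) -> bool:
    present = {tags[t.name] for t in tree.tips()}
    return required <= present


def _has_pair_clade(tree: TreeNode, tags: dict[str, str], pair: tuple[str, str]) -> bool:
    """True when the tree contains an internal node whose leaves come only
    from the two expected chromosomes, with at least one from each."""
    want = set(pair)
    for node in tree.non_tips(include_self=True):
        chroms = {tags[t.name] for t in node.tips()}
        if chroms == want:
            return True
    return False


def pairing_support_fraction(
    trees: Iterable[TreeNode],
    expected_pairs: Sequence[tuple[str, str]],
    tags: dict[str, str],
    required_chroms: Optional[set] = None,
) -> dict:
    """Fraction of informative gene trees supporting the synteny pairing.

    A tree is *informative* when it has at least one leaf from each required
    chromosome (by default the union of the expected pairs); it is
    *supporting* when every expected (basal, core) pair forms a clade
    containing leaves of only those two chromosomes.
    """
    trees = list(trees)
    if not trees:
        raise ValidationError("empty tree set")
    required = set(required_chroms) if required_chroms is not None else {
        c for pair in expected_pairs for c in pair
    }
    informative = supporting = 0
    for tree in trees:
        if not _is_informative(tree, tags, required):
            continue
        informative += 1
        if all(_has_pair_clade(tree, tags, pair) for pair in expected_pairs):
            supporting += 1
    fraction = supporting / informative if informative else float("nan")
    return {"informative": informative, "supporting": supporting, "fraction": fraction}
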