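"""Band-profile diversity: similarities, averaged distances, UPGMA trees.

Pairwise variety similarity at a marker is the Jaccard index
``n_xy / (n_x + n_y - n_xy)`` or the Sørensen–Dice index
``2 n_xy / (n_x + n_y)`` on the band sets; distance is one minus the
similarity. Per-marker distance matrices are averaged element-wise over
all markers (monomorphic markers contribute zeros) and clustered with
UPGMA, yielding an ultrametric rooted dendrogram.

Two varieties in which a marker amplified nothing are indistinguishable
there: the both-empty similarity is defined as 1 (distance 0), while an
empty against a non-empty profile scores 0 — this keeps distances defined
for markers that amplify in only part of the panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, AbstractSet, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from clovermark.formats import BandMatrix

INDICES = ("jaccard", "dice")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative pairwise distances with a zero diagonal.

    Distances derived from band-profile similarities lie in [0, 1] by
    construction; the container itself accepts any non-negative scale so
    that general dissimilarities can be clustered too.
    """

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} does not match {n} labels")
        if np.isnan(d).any():
            raise ValueError("NaN distance")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if d.min() < -1e-12:
            raise ValueError("distances must be non-negative")


@dataclass(frozen=True)
class TreeNode:
    """Rooted binary dendrogram node with an ultrametric height.

    Leaves have a label and height 0; internal nodes have exactly two
    children and a height equal to half the merge distance. Branch lengths
    (parent height minus child height) are derived at serialization.
    """

    height: float
    label: str = ""
    children: tuple["TreeNode", "TreeNode"] | tuple = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for child in self.children for leaf in child.leaves()]

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(leaf.label for leaf in self.leaves())

    def cophenetic(self) -> dict[frozenset[str], float]:
        """Pairwise leaf distances implied by the tree (2x merge height)."""
        out: dict[frozenset[str], float] = {}

        def _walk(node: "TreeNode") -> list[str]:
            if node.is_leaf:
                return [node.label]
            left = _walk(node.children[0])
            right = _walk(node.children[1])
            for a in left:
                for b in right:
                    out[frozenset((a, b))] = 2.0 * node.height
            return left + right

        _walk(self)
        return out


def pair_similarity(
    x: AbstractSet[str], y: AbstractSet[str], index: str = "jaccard"
) -> float:
    """Jaccard or Sørensen–Dice similarity of two band sets."""
    if index not in INDICES:
        raise ValueError(f"unknown similarity index {index!r}")
    if not x and not y:
        return 1.0
    n_xy = len(x & y)
    n_x, n_y = len(x), len(y)
    if index == "jaccard":
        return n_xy / (n_x + n_y - n_xy)
    return 2.0 * n_xy / (n_x + n_y)


def marker_distance_matrix(
    bands: "BandMatrix", marker: str, index: str = "jaccard"
) -> DistanceMatrix:
    """Distance matrix (1 - similarity) among all varieties for one marker."""
    profiles = [bands.profile(marker, v) for v in bands.varieties]
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - pair_similarity(profiles[i], profiles[j], index)
    return DistanceMatrix(labels=tuple(bands.varieties), d=d)


def average_distance(matrices: Sequence[DistanceMatrix]) -> DistanceMatrix:
    """Element-wise mean of distance matrices sharing one label order."""
    if not matrices:
        raise ValueError("average_distance needs at least one matrix")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels:
            raise ValueError("distance matrices have mismatched labels")
    mean = np.mean([m.d for m in matrices], axis=0)
    return DistanceMatrix(labels=labels, d=mean)


def upgma(dm: DistanceMatrix) -> TreeNode:
    """UPGMA clustering of a distance matrix into an ultrametric tree.

    Repeatedly merges the closest pair of clusters at half their distance;
    the merged cluster's distance to every other cluster is the
    size-weighted average of its members' distances. Ties are broken by the
    lexicographically smallest pair of cluster labels (a cluster is
    labelled by its smallest leaf label), making the tree invariant to
    input order.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("UPGMA needs at least two labels")
    clusters: dict[str, dict] = {
        label: {"node": TreeNode(height=0.0, label=label), "size": 1}
        for label in dm.labels
    }
    dist: dict[frozenset[str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((dm.labels[i], dm.labels[j]))] = float(dm.d[i, j])

    while len(clusters) > 1:
        best_pair: tuple[str, str] | None = None
        best_d = np.inf
        for key, value in dist.items():
            a, b = sorted(key)
            if value < best_d or (value == best_d and (a, b) < best_pair):
                best_d = value
                best_pair = (a, b)
        a, b = best_pair
        size_a, size_b = clusters[a]["size"], clusters[b]["size"]
        node = TreeNode(
            height=best_d / 2.0,
            children=(clusters[a]["node"], clusters[b]["node"]),
        )
        merged = min(a, b)
        others = [c for c in clusters if c not in (a, b)]
        for c in others:
            d_ac = dist.pop(frozenset((a, c)))
            d_bc = dist.pop(frozenset((b, c)))
            dist[frozenset((merged, c))] = (size_a * d_ac + size_b * d_bc) / (
                size_a + size_b
            )
        del dist[frozenset((a, b))]
        del clusters[a], clusters[b]
        clusters[merged] = {"node": node, "size": size_a + size_b}

    return next(iter(clusters.values()))["node"]


def diversity_tree(
    bands: "BandMatrix", index: str = "jaccard"
) -> tuple[DistanceMatrix, TreeNode]:
    """Averaged distance matrix over all markers and its UPGMA tree."""
    matrices = [marker_distance_matrix(bands, m, index) for m in bands.markers]
    avg = average_distance(matrices)
    return avg, upgma(avg)
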