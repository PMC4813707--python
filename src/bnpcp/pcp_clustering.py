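"""Protein correlation profiling: Manhattan distances, average-linkage
(UPGMA) hierarchical clustering, heatmap ordering and bait co-cluster
extraction.

The agglomeration is implemented here rather than delegated so that
tie-breaking is fully specified and platform-independent: at every step the
pair of clusters with minimal mean inter-cluster distance is merged, ties
broken lexicographically on the (creation-order) cluster index pair. Leaves
are numbered 0..n-1 in input order; the cluster created by merge step k gets
index n+k; the left child of a merge is the earlier-created cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import MigrationProfile

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "manhattan_matrix",
    "average_linkage",
    "co_cluster",
    "default_cut_height",
    "heatmap_order",
    "to_newick",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix over an ordered protein list."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal not zero")
        if np.any(self.d < 0):
            raise ValueError("negative distance")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class Dendrogram:
    """Merge history of an agglomerative clustering.

    ``merges[k] = (a, b, height)`` joins cluster indices ``a < b`` (leaves are
    0..n-1 in ``ids`` order; merge k creates cluster ``n + k``) at the given
    linkage height. Average-linkage heights are recorded as produced and are
    not guaranteed monotone in pathological cases.
    """

    ids: list[str]
    merges: list[tuple[int, int, float]]

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def members(self, cluster: int) -> list[int]:
        """Leaf indices under *cluster*, in creation order."""
        n = self.n_leaves
        if cluster < n:
            return [cluster]
        a, b, _ = self.merges[cluster - n]
        return self.members(a) + self.members(b)

    def leaf_order(self) -> list[int]:
        """Display order: left subtree (earlier-created cluster) first."""
        if not self.merges:
            return list(range(self.n_leaves))
        return self.members(self.n_leaves + len(self.merges) - 1)


def manhattan_matrix(profiles: list[MigrationProfile]) -> DistanceMatrix:
    """Pairwise Manhattan (L1) distances between migration profiles."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    lengths = {p.n_fractions for p in profiles}
    if len(lengths) != 1:
        raise ValueError(f"profiles have mismatched lengths: {sorted(lengths)}")
    mat = np.stack([p.values for p in profiles])
    d = np.abs(mat[:, None, :] - mat[None, :, :]).sum(axis=2)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=[p.protein_id for p in profiles], d=d)


def average_linkage(dist: DistanceMatrix) -> Dendrogram:
    """UPGMA agglomeration with deterministic lexicographic tie-breaking.

    Inter-cluster distances are the unweighted mean of all cross pairs,
    maintained with the Lance-Williams update
    ``d(a+b, c) = (|a| d(a,c) + |b| d(b,c)) / (|a| + |b|)``.
    """
    n = dist.n
    if n == 1:
        return Dendrogram(ids=list(dist.ids), merges=[])
    # active: cluster index -> size; pairwise dict keyed on (i, j) with i < j
    sizes = {i: 1 for i in range(n)}
    pair_d = {(i, j): float(dist.d[i, j]) for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[int, int, float]] = []
    next_idx = n
    while len(sizes) > 1:
        (a, b), height = min(pair_d.items(), key=lambda kv: (kv[1], kv[0]))
        new = next_idx
        next_idx += 1
        for c in sizes:
            if c in (a, b):
                continue
            dac = pair_d.pop((min(a, c), max(a, c)))
            dbc = pair_d.pop((min(b, c), max(b, c)))
            pair_d[(c, new)] = (sizes[a] * dac + sizes[b] * dbc) / (sizes[a] + sizes[b])
        pair_d.pop((a, b))
        sizes[new] = sizes.pop(a) + sizes.pop(b)
        merges.append((a, b, height))
    return Dendrogram(ids=list(dist.ids), merges=merges)


def co_cluster(tree: Dendrogram, bait_id: str, height: float) -> set[str]:
    """Members of the cluster containing the bait when cutting at *height*.

    Merges are applied in order; a merge applies when its height is <= the
    cut and both of its children have themselves been formed. Membership is
    therefore monotone in the cut height.
    """
    if bait_id not in tree.ids:
        raise ValueError(f"unknown bait {bait_id!r}")
    if height < 0:
        raise ValueError("height must be >= 0")
    n = tree.n_leaves
    formed = {i: {i} for i in range(n)}
    for k, (a, b, h) in enumerate(tree.merges):
        if h <= height and a in formed and b in formed:
            formed[n + k] = formed.pop(a) | formed.pop(b)
    bait_leaf = tree.ids.index(bait_id)
    for members in formed.values():
        if bait_leaf in members:
            return {tree.ids[i] for i in members}
    raise AssertionError("bait leaf lost during cut")  # unreachable


def default_cut_height(tree: Dendrogram, bait_id: str, min_members: int = 12) -> float:
    """Smallest merge height at which the bait's cluster has >= *min_members*.

    Falls back to the maximal height (whole tree) when no cut reaches the
    requested size.
    """
    heights = sorted({h for _, _, h in tree.merges})
    for h in heights:
        if len(co_cluster(tree, bait_id, h)) >= min_members:
            return h
    return heights[-1] if heights else 0.0


def heatmap_order(tree: Dendrogram, dist: DistanceMatrix) -> tuple[list[str], np.ndarray]:
    """Dendrogram leaf order and the distance matrix reordered to match."""
    if tree.ids != dist.ids:
        raise ValueError("dendrogram and distance matrix cover different ids")
    order = tree.leaf_order()
    ids = [tree.ids[i] for i in order]
    return ids, dist.d[np.ix_(order, order)]


def to_newick(tree: Dendrogram) -> str:
    """Newick serialization of the dendrogram (branch lengths from heights)."""
    n = tree.n_leaves
    height_of = {i: 0.0 for i in range(n)}
    for k, (_, _, h) in enumerate(tree.merges):
        height_of[n + k] = h

    def fmt(cluster: int, parent_height: float) -> str:
        length = max(parent_height - height_of[cluster], 0.0)
        if cluster < n:
            return f"{tree.ids[cluster]}:{length:g}"
        a, b, h = tree.merges[cluster - n]
        return f"({fmt(a, h)},{fmt(b, h)}):{length:g}"

    if not tree.merges:
        return f"{tree.ids[0]};" if tree.ids else ";"
    root = n + len(tree.merges) - 1
    a, b, h = tree.merges[root - n]
    return f"({fmt(a, h)},{fmt(b, h)});"
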