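"""Hierarchical clustering of samples or features with missing-value handling.

Profiles are compared with a rescaled pairwise-complete Euclidean distance
(missing coordinates are skipped and the sum of squares is scaled up by
m / m_obs so distances stay comparable across pairs with different amounts of
missingness), then clustered agglomeratively with complete linkage.  Leaves
are sorted lexicographically before clustering so ties in minimum distance
break identically regardless of input order, and the tree exports to Newick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .matrix import ExpressionMatrix

__all__ = ["Dendrogram", "euclidean_distance_masked", "hcluster", "to_newick",
           "cut_tree"]


@dataclass
class Dendrogram:
    """Binary merge tree over labelled leaves.

    ``merges[k] = (left, right, height)`` where left/right index either a leaf
    (0..n-1) or an earlier merge (n+j for merges[j]); heights are the
    complete-linkage distances, non-decreasing along any root path.
    """

    labels: list[str]
    merges: list[tuple[int, int, float]]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def members(self, node: int) -> frozenset[str]:
        """Leaf labels under a node index (leaf or internal)."""
        n = self.n_leaves
        if node < n:
            return frozenset([self.labels[node]])
        left, right, _ = self.merges[node - n]
        return self.members(left) | self.members(right)

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of every internal node, in merge order."""
        return [self.members(self.n_leaves + j) for j in range(len(self.merges))]

    def smallest_clade_containing(self, labels: set[str]) -> frozenset[str]:
        want = set(labels)
        for clade in self.clades():
            if want <= clade:
                return clade
        raise ValueError("labels not all present in the tree")


def euclidean_distance_masked(
    x: np.ndarray, y: np.ndarray,
    x_mask: np.ndarray | None = None, y_mask: np.ndarray | None = None,
) -> float:
    """Rescaled pairwise-complete Euclidean distance.

    d = sqrt((m / m_obs) * sum over jointly observed coordinates of (x-y)^2),
    with m the total number of coordinates and m_obs the jointly observed
    count.  With no missing data this is the ordinary Euclidean distance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    x_mask = np.isnan(x) if x_mask is None else np.asarray(x_mask, dtype=bool)
    y_mask = np.isnan(y) if y_mask is None else np.asarray(y_mask, dtype=bool)
    obs = ~x_mask & ~y_mask
    m, m_obs = x.size, int(obs.sum())
    if m_obs == 0:
        raise ValueError("profiles share no unmasked coordinate")
    ss = float(np.sum((x[obs] - y[obs]) ** 2))
    return float(np.sqrt(ss * m / m_obs))


def hcluster(
    matrix: ExpressionMatrix, axis: str = "samples", linkage_method: str = "complete"
) -> Dendrogram:
    """Agglomerative clustering of samples (columns) or features (rows).

    Items are sorted by label first, so the result is invariant to input
    order and minimum-distance ties break by the lexicographically smallest
    member label.
    """
    if axis == "samples":
        labels = list(matrix.sample_ids)
        data = matrix.values.T
        mask = matrix.mask.T
    elif axis == "features":
        labels = list(matrix.feature_ids)
        data = matrix.values
        mask = matrix.mask
    else:
        raise ValueError("axis must be 'samples' or 'features'")
    n = len(labels)
    if n < 2:
        raise ValueError("clustering needs >= 2 items")
    order = sorted(range(n), key=lambda i: labels[i])
    labels = [labels[i] for i in order]
    data, mask = data[order], mask[order]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = euclidean_distance_masked(
                data[i], data[j], mask[i], mask[j]
            )
    Z = linkage(squareform(D, checks=False), method=linkage_method)
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in Z]
    return Dendrogram(labels=labels, merges=merges)


def _newick_node(tree: Dendrogram, node: int, parent_height: float, precision: int) -> str:
    n = tree.n_leaves
    if node < n:
        height = 0.0
        label = tree.labels[node]
        inner = label
    else:
        left, right, height = tree.merges[node - n]
        inner = "(%s,%s)" % (
            _newick_node(tree, left, height, precision),
            _newick_node(tree, right, height, precision),
        )
    branch = parent_height - height
    return f"{inner}:{branch:.{precision}g}"


def to_newick(tree: Dendrogram, precision: int = 10) -> str:
    """Newick string with branch lengths = merge-height differences."""
    n = tree.n_leaves
    if not tree.merges:  # single leaf
        return f"{tree.labels[0]};"
    root = n + len(tree.merges) - 1
    left, right, height = tree.merges[-1]
    body = "(%s,%s)" % (
        _newick_node(tree, left, height, precision),
        _newick_node(tree, right, height, precision),
    )
    del root
    return body + ";"


def cut_tree(tree: Dendrogram, height: float) -> dict[str, int]:
    """Flat clusters from cutting all merges strictly above ``height``."""
    n = tree.n_leaves
    parent = list(range(n + len(tree.merges)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for k, (a, b, h) in enumerate(tree.merges):
        if h <= height:
            node = n + k
            parent[find(a)] = node
            parent[find(b)] = node
    roots: dict[int, int] = {}
    out: dict[str, int] = {}
    for i, lab in enumerate(tree.labels):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots)
        out[lab] = roots[r]
    return out
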