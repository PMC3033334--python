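"""Hierarchical clustering for heat-map ordering.

Distance is 1 - Pearson correlation of log2 expression profiles; linkage
is average (UPGMA), the combination used for the published gene trees.
The agglomeration is written out explicitly (Lance-Williams update) so the
tie-break is fully deterministic: among equally distant pairs the one
containing the lowest original item index merges first, and leaf ordering
places the lower-indexed subtree on the left.  Average linkage admits no
inversions, so merge heights are non-decreasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ClusterTree", "cluster", "heatmap_order", "to_newick"]


@dataclass(frozen=True)
class ClusterTree:
    """Merge history of an agglomerative clustering.

    merges[i] = (id_a, id_b, height, size) creates node n_leaves + i; ids
    below n_leaves are leaves (indices into ``labels``).  leaf_order is the
    left-to-right dendrogram order.
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]
    leaf_order: tuple[int, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]

    def linkage_matrix(self) -> np.ndarray:
        """scipy-compatible (n-1, 4) linkage array."""
        return np.asarray(self.merges, dtype=float)


def _correlation_distance(profiles: np.ndarray) -> np.ndarray:
    c = np.corrcoef(profiles)
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def cluster(
    signals: pd.DataFrame, axis: str = "genes", standardize: bool = True
) -> ClusterTree:
    """Average-linkage tree over genes (rows) or samples (columns).

    Profiles are log2-transformed; gene-axis profiles are additionally
    row-standardized when ``standardize`` (the heat-map convention; Pearson
    distance is invariant to it, the exported matrix is not).  Items with
    zero variance have undefined correlation and are dropped with a
    warning.
    """
    if axis not in ("genes", "samples"):
        raise ValueError(f"axis must be 'genes' or 'samples', got {axis!r}")
    mat = np.log2(np.maximum(signals.to_numpy(dtype=float), 1.0))
    labels = list(signals.index.astype(str)) if axis == "genes" else list(signals.columns)
    if axis == "samples":
        mat = mat.T
    keep = mat.std(axis=1) > 0.0
    if not keep.all():
        dropped = [l for l, k in zip(labels, keep) if not k]
        logger.warning("dropping %d zero-variance items: %s ...", len(dropped), dropped[:5])
        mat = mat[keep]
        labels = [l for l, k in zip(labels, keep) if k]
    if len(labels) < 2:
        raise ValueError("fewer than 2 items remain after zero-variance filtering")
    if axis == "genes" and standardize:
        mat = (mat - mat.mean(axis=1, keepdims=True)) / mat.std(axis=1, keepdims=True)
    dist = _correlation_distance(mat)
    merges, order = _average_linkage(dist)
    return ClusterTree(labels=tuple(labels), merges=tuple(merges), leaf_order=tuple(order))


def _average_linkage(dist: np.ndarray):
    """Explicit UPGMA agglomeration with deterministic tie-breaking."""
    n = dist.shape[0]
    d = dist.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    active = list(range(n))  # current cluster ids, index = matrix slot
    size = {i: 1 for i in range(n)}
    min_orig = {i: i for i in range(n)}  # lowest original leaf in cluster
    leaves = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    for step in range(n - 1):
        m = np.min(d)
        ti, tj = np.nonzero(d == m)
        # candidate pairs (slot_i < slot_j); pick the one whose clusters
        # contain the lowest original index, then the lowest partner
        best = None
        for a, b in zip(ti, tj):
            if a == b:
                continue
            if a > b:
                a, b = b, a
            ca, cb = active[a], active[b]
            key = tuple(sorted((min_orig[ca], min_orig[cb])))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        ca, cb = active[a], active[b]
        height = float(d[a, b])
        merges.append((min(ca, cb), max(ca, cb), height, size[ca] + size[cb]))
        # Lance-Williams average-linkage update into slot a
        wa, wb = size[ca], size[cb]
        new_row = (wa * d[a, :] + wb * d[b, :]) / (wa + wb)
        d[a, :] = new_row
        d[:, a] = new_row
        d[a, a] = np.inf
        d[b, :] = np.inf
        d[:, b] = np.inf
        # lower-min_orig subtree goes left in the dendrogram
        la, lb = leaves[ca], leaves[cb]
        left, right = (la, lb) if min_orig[ca] <= min_orig[cb] else (lb, la)
        size[next_id] = wa + wb
        min_orig[next_id] = min(min_orig[ca], min_orig[cb])
        leaves[next_id] = left + right
        active[a] = next_id
        active[b] = -1
        next_id += 1
    order = leaves[next_id - 1]
    return merges, order


def heatmap_order(tree: ClusterTree) -> list[str]:
    """Leaf labels in dendrogram order, for row/column ordering."""
    return tree.ordered_labels()


def to_newick(tree: ClusterTree) -> str:
    """Newick string with branch lengths = parent height - child height."""
    heights = {i: 0.0 for i in range(tree.n_leaves)}
    children: dict[int, tuple[int, int]] = {}
    for i, (a, b, h, _) in enumerate(tree.merges):
        node = tree.n_leaves + i
        heights[node] = h
        children[node] = (a, b)

    def render(node: int, parent_h: float) -> str:
        bl = parent_h - heights[node]
        if node < tree.n_leaves:
            return f"{tree.labels[node]}:{bl:.6g}"
        a, b = children[node]
        return f"({render(a, heights[node])},{render(b, heights[node])}):{bl:.6g}"

    root = tree.n_leaves + len(tree.merges) - 1
    a, b = children[root]
    h = heights[root]
    return f"({render(a, h)},{render(b, h)});"
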