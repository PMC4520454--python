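"""Unsupervised hierarchical clustering of samples and dendrogram export.

Mirrors the genome-wide clustering readout of the transition time course:
samples are clustered on their expression or methylation profiles and the
tree is cut to ask which timepoints co-cluster with the endpoint reference
state.  Expression defaults to 1 - Pearson correlation distance with
average linkage; methylation to Euclidean distance over beta values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

METRICS = ("correlation", "euclidean")
LINKAGES = ("average", "complete", "ward")


@dataclass(frozen=True)
class ClusterTree:
    """Agglomerative sample tree.

    ``linkage_matrix`` is in scipy form: row i merges nodes ``Z[i,0]`` and
    ``Z[i,1]`` at height ``Z[i,2]`` into node ``n + i``.  Invariants: n
    leaves imply n-1 merges, heights non-decreasing in merge order.
    """

    labels: tuple
    linkage_matrix: np.ndarray
    method: str
    metric: str

    def __post_init__(self):
        Z = np.asarray(self.linkage_matrix, dtype=float)
        n = len(self.labels)
        if Z.shape != (n - 1, 4):
            raise ValueError(f"linkage matrix shape {Z.shape} inconsistent with {n} leaves")
        heights = Z[:, 2]
        if np.any(np.diff(heights) < -1e-10):
            raise ValueError("merge heights must be non-decreasing")
        object.__setattr__(self, "linkage_matrix", Z)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)


def hierarchical_cluster(
    matrix: pd.DataFrame,
    metric: str = "correlation",
    method: str = "average",
    top_n: int | None = 5000,
) -> ClusterTree:
    """Cluster the samples (columns) of a features x samples matrix.

    ``metric='correlation'`` uses distance ``1 - Pearson`` between sample
    profiles; a constant sample profile is rejected because its correlation
    is undefined.  ``top_n`` keeps only the most variable features before
    clustering (pass ``None`` for all); this is the usual desk-scale stand-in
    for "genome-wide" clustering.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if method not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    if matrix.isna().all(axis=0).any():
        raise ValueError("all-missing sample profile")
    data = matrix.dropna(axis=0)
    if top_n is not None and data.shape[0] > top_n:
        keep = data.var(axis=1).nlargest(top_n).index
        data = data.loc[keep]
    X = data.to_numpy(dtype=float).T  # samples x features
    if metric == "correlation":
        if np.any(X.std(axis=1) == 0):
            const = matrix.columns[int(np.argmax(X.std(axis=1) == 0))]
            raise ValueError(f"sample {const!r} has a constant profile; "
                             "correlation distance undefined")
        dist = pdist(X, metric="correlation")
    else:
        dist = pdist(X, metric="euclidean")
    Z = hierarchy.linkage(dist, method=method)
    return ClusterTree(tuple(matrix.columns), Z, method, metric)


def clusters_at_k(tree: ClusterTree, k: int) -> pd.Series:
    """Cut the tree into ``k`` flat clusters; returns sample -> cluster id."""
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    assign = hierarchy.fcluster(tree.linkage_matrix, t=k, criterion="maxclust")
    return pd.Series(assign, index=list(tree.labels), name="cluster")


def to_newick(tree: ClusterTree, fmt: str = "%.6g") -> str:
    """Newick string with branch lengths equal to merge-height differences
    (leaves at height 0)."""
    root = hierarchy.to_tree(tree.linkage_matrix)
    labels = tree.labels

    def render(node, parent_height):
        length = fmt % (parent_height - node.dist if not node.is_leaf() else parent_height)
        if node.is_leaf():
            return f"{labels[node.id]}:{length}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length}"

    left = render(root.left, root.dist)
    right = render(root.right, root.dist)
    return f"({left},{right});"
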