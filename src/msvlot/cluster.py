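"""Ward hierarchical clustering of component scores, dendrogram cuts,
and singleton-outlier handling.

Ward's minimum-variance criterion is applied to Euclidean distances via
the Lance-Williams update on squared distances, with merge heights
stored as square roots of the updated squared distances (so two
singletons merge at their Euclidean distance). This is the dialect that
genuinely minimizes within-cluster variance on coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

#: Label given to patients excluded as outliers (undersized clusters).
OUTLIER = 0


@dataclass
class Dendrogram:
    """Ward merge tree: a scipy linkage matrix plus the leaf ids."""

    linkage: np.ndarray
    leaf_ids: list

    @property
    def n(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def merges(self) -> pd.DataFrame:
        """Merge table: node_a, node_b, height, merged cluster size.

        Nodes 0..n-1 are leaves; node n+i is the cluster created by
        merge i.
        """
        return pd.DataFrame({
            "node_a": self.linkage[:, 0].astype(int),
            "node_b": self.linkage[:, 1].astype(int),
            "height": self.linkage[:, 2],
            "size": self.linkage[:, 3].astype(int),
        })


@dataclass
class Partition:
    """Group labels per patient; label 0 flags an excluded outlier."""

    labels: pd.Series  # int labels indexed by patient_id; 0 = outlier

    @property
    def k_effective(self) -> int:
        non_outlier = self.labels[self.labels != OUTLIER]
        return int(non_outlier.nunique())

    @property
    def outlier_ids(self) -> list:
        return list(self.labels.index[self.labels == OUTLIER])

    @property
    def non_outlier_ids(self) -> list:
        return list(self.labels.index[self.labels != OUTLIER])

    def sizes(self) -> pd.Series:
        """Cluster sizes, outliers excluded, indexed by label."""
        non = self.labels[self.labels != OUTLIER]
        return non.value_counts().sort_index()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "patient_id": self.labels.index,
            "group": self.labels.to_numpy(),
            "outlier_flag": (self.labels == OUTLIER).to_numpy(),
        })


def ward_linkage(scores, leaf_ids=None) -> Dendrogram:
    """Agglomerate with Ward's criterion on Euclidean coordinates.

    ``scores`` is a patients x components matrix (DataFrame index is
    used for leaf ids when present).
    """
    if isinstance(scores, pd.DataFrame):
        if leaf_ids is None:
            leaf_ids = list(scores.index)
        X = scores.to_numpy(float)
    else:
        X = np.asarray(scores, float)
        if X.ndim == 1:
            X = X[:, None]
    n = X.shape[0]
    if leaf_ids is None:
        leaf_ids = list(range(n))
    if n < 2:
        raise ValueError("ward_linkage needs >= 2 patients")
    if not np.isfinite(X).all():
        bad = [leaf_ids[i] for i in np.flatnonzero(~np.isfinite(X).all(axis=1))]
        raise ValueError(f"non-finite scores for patients: {bad}")
    Z = hierarchy.linkage(X, method="ward")
    return Dendrogram(linkage=Z, leaf_ids=list(leaf_ids))


def _relabel_by_size(assignments: np.ndarray, leaf_ids: list) -> pd.Series:
    # largest cluster -> label 1; equal sizes broken by smallest member id
    ids = pd.Index(leaf_ids)
    groups: dict[int, list] = {}
    for i, a in enumerate(assignments):
        groups.setdefault(int(a), []).append(ids[i])
    ordered = sorted(groups.values(), key=lambda m: (-len(m), min(map(str, m))))
    labels = pd.Series(0, index=ids, dtype=int)
    labels.index.name = "patient_id"
    for new, members in enumerate(ordered, start=1):
        labels.loc[members] = new
    return labels


def cut_dendrogram(dendro: Dendrogram, k: int) -> Partition:
    """Undo the last k-1 merges and label clusters by decreasing size
    (largest = 1; ties broken by smallest patient id)."""
    if not (1 <= k <= dendro.n):
        raise ValueError(f"k must be in [1, {dendro.n}], got {k}")
    flat = hierarchy.cut_tree(dendro.linkage, n_clusters=k).ravel()
    return Partition(labels=_relabel_by_size(flat, dendro.leaf_ids))


def choose_k(dendro: Dendrogram, k_range=None) -> int:
    """Pick k by the largest gap between successive merge heights.

    A reproducible stand-in for the visual dendrogram cut: the gap for a
    k-cluster solution is the height of the merge that would reduce k
    clusters to k-1, minus the height of the last merge performed at k
    clusters. Ties resolve to the smallest k; always overridable by an
    explicit k in the pipeline config.
    """
    n = dendro.n
    if k_range is None:
        k_range = range(2, min(10, n - 1) + 1)
    ks = [int(k) for k in k_range]
    if not ks or min(ks) < 2 or max(ks) > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    h = dendro.heights
    best_k, best_gap = None, -np.inf
    for k in sorted(ks):
        gap = h[n - k] - h[n - k - 1]
        if gap > best_gap + 1e-12:
            best_k, best_gap = k, gap
    return best_k


def flag_outliers(partition: Partition, min_size: int = 2) -> Partition:
    """Flag clusters smaller than min_size as outliers and relabel the
    remaining groups contiguously by decreasing size."""
    sizes = partition.labels[partition.labels != OUTLIER].value_counts()
    keep = set(sizes[sizes >= min_size].index)
    if not keep:
        raise ValueError(f"all clusters smaller than min_size={min_size}")
    ids = partition.labels.index
    kept_mask = partition.labels.isin(keep)
    labels = pd.Series(OUTLIER, index=ids, dtype=int)
    labels.index.name = "patient_id"
    if kept_mask.any():
        sub = _relabel_by_size(
            partition.labels[kept_mask].to_numpy(), list(ids[kept_mask])
        )
        labels.loc[sub.index] = sub
    return Partition(labels=labels)


def to_newick(dendro: Dendrogram) -> str:
    """Newick export with branch lengths from merge heights.

    Each node's branch length is the height difference to its parent
    merge (leaves sit at height 0).
    """
    tree = hierarchy.to_tree(dendro.linkage)
    ids = dendro.leaf_ids

    def fmt(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.6g}"
        left = fmt(node.left, node.dist)
        right = fmt(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = fmt(tree.left, tree.dist)
    right = fmt(tree.right, tree.dist)
    return f"({left},{right});"
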