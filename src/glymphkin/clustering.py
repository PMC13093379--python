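"""Hierarchical k-means clustering of voxel time-signal curves.

Voxels are clustered on the first derivative of their time-signal curve
(TSC), which captures similarity of tracer kinetics independent of static
offsets.  Starting from one root cluster, any cluster whose voxel count
exceeds ``size_threshold`` AND whose within-cluster inconsistency (WCI)
exceeds ``wci_threshold`` is split by seeded 2-means, recursively.  The
WCI of a cluster is the mean Euclidean distance of member feature vectors
to the cluster centroid, divided by sqrt(feature length), so the threshold
acts on a per-coordinate RMS scale and is independent of the number of
timepoints.  Each terminal leaf yields a representative TSC (the mean of
its members' original curves) for kinetic modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "DerivativeFeatures",
    "ClusterNode",
    "ClusterTree",
    "tsc_derivative_features",
    "within_cluster_inconsistency",
    "hierarchical_kmeans",
    "representative_tscs",
]

DEFAULT_SIZE_THRESHOLD = 100
DEFAULT_WCI_THRESHOLD = 0.125


@dataclass
class DerivativeFeatures:
    """First-derivative feature matrix, (voxels x (timepoints - 1))."""

    matrix: np.ndarray
    normalization_constant: float
    times_min: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.shape[-1] != self.times_min.size - 1:
            raise ValueError("feature length must be timepoints - 1")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("features must be finite")


def tsc_derivative_features(tsc_matrix, times_min, normalize: bool = True) -> DerivativeFeatures:
    """Finite-difference derivative features of each voxel's TSC.

    Entry j is (x[j+1] - x[j]) / (t[j+1] - t[j]).  With ``normalize`` the
    whole matrix is divided by the global max |derivative| so the features
    are dimensionless in [-1, 1] and the WCI threshold acts on the scale of
    the fastest signal change in the data (a per-minute derivative of
    curves sampled tens of minutes apart would otherwise sit orders of
    magnitude below any fixed threshold).  The constant is stored for
    invertibility.
    """
    x = np.atleast_2d(np.asarray(tsc_matrix, dtype=float))
    t = np.asarray(times_min, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 timepoints")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("duplicate or non-increasing timepoints")
    feats = np.diff(x, axis=-1) / dt
    const = 1.0
    if normalize:
        const = float(np.max(np.abs(feats)))
        if const == 0:
            const = 1.0
        feats = feats / const
    return DerivativeFeatures(matrix=feats, normalization_constant=const, times_min=t)


def within_cluster_inconsistency(features, member_ids) -> float:
    """Relative dispersion of member derivative signals around their centroid.

    ``wci = mean_i ||f_i - centroid|| / ||centroid||`` — the mean Euclidean
    distance to the cluster centroid expressed as a fraction of the
    centroid's own norm.  This makes the statistic dimensionless,
    independent of both the sampling grid and the signal amplitude, so one
    fixed threshold separates "one kinetic family plus noise" (small
    relative dispersion) from "mixture of kinetic families" (large) across
    brain regions with very different enhancement levels.  A singleton, or
    a cluster of identical members, has WCI 0; a cluster whose centroid is
    exactly zero but whose members disagree is maximally inconsistent
    (infinity).
    """
    f = features.matrix if isinstance(features, DerivativeFeatures) else np.asarray(features, float)
    ids = np.asarray(member_ids)
    if ids.size == 0:
        raise ValueError("empty member set")
    sub = f[ids]
    centroid = sub.mean(axis=0)
    mean_dist = float(np.linalg.norm(sub - centroid, axis=1).mean())
    norm_c = float(np.linalg.norm(centroid))
    if mean_dist == 0.0:
        return 0.0
    if norm_c == 0.0:
        return float("inf")
    return mean_dist / norm_c


@dataclass
class ClusterNode:
    node_id: int
    member_ids: np.ndarray
    wci: float
    depth: int
    parent_id: int | None = None
    children: tuple[int, int] | None = None
    split_failed: bool = False
    depth_capped: bool = False

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    @property
    def count(self) -> int:
        return int(self.member_ids.size)


@dataclass
class ClusterTree:
    nodes: dict = field(default_factory=dict)
    root_id: int = 0
    size_threshold: int = DEFAULT_SIZE_THRESHOLD
    wci_threshold: float = DEFAULT_WCI_THRESHOLD
    seed: int = 0

    def leaves(self) -> list[ClusterNode]:
        return [n for n in self.nodes.values() if n.is_leaf]

    def leaf_labels(self, n_voxels: int) -> np.ndarray:
        """Leaf node id per voxel; every voxel belongs to exactly one leaf."""
        labels = np.full(n_voxels, -1, dtype=int)
        for leaf in self.leaves():
            labels[leaf.member_ids] = leaf.node_id
        return labels


def hierarchical_kmeans(
    features,
    size_threshold: int = DEFAULT_SIZE_THRESHOLD,
    wci_threshold: float = DEFAULT_WCI_THRESHOLD,
    seed: int = 0,
    max_depth: int = 12,
    n_init: int = 10,
) -> ClusterTree:
    """Recursive seeded 2-means subdivision with the size/WCI stopping rule.

    A cluster is split only while ``count > size_threshold`` and
    ``wci > wci_threshold``; a degenerate split (an empty child, or 2-means
    unable to separate) makes the node a flagged leaf.  Deterministic for a
    fixed seed: each node's k-means restarts are seeded from the tree seed
    and the node id.
    """
    f = features.matrix if isinstance(features, DerivativeFeatures) else np.asarray(features, float)
    n = f.shape[0]
    if n < 1:
        raise ValueError("need at least one voxel")
    tree = ClusterTree(
        size_threshold=size_threshold, wci_threshold=wci_threshold, seed=seed
    )
    all_ids = np.arange(n)
    next_id = [0]

    def new_node(ids, depth, parent):
        node = ClusterNode(
            node_id=next_id[0],
            member_ids=ids,
            wci=within_cluster_inconsistency(f, ids),
            depth=depth,
            parent_id=parent,
        )
        tree.nodes[node.node_id] = node
        next_id[0] += 1
        return node

    stack = [new_node(all_ids, 0, None)]
    tree.root_id = 0
    while stack:
        node = stack.pop()
        if not (node.count > size_threshold and node.wci > wci_threshold):
            continue
        if node.depth >= max_depth:
            node.depth_capped = True
            continue
        node_seed = (seed * 1_000_003 + node.node_id) % (2**31 - 1)
        km = KMeans(n_clusters=2, n_init=n_init, random_state=node_seed)
        labels = km.fit_predict(f[node.member_ids])
        left = node.member_ids[labels == 0]
        right = node.member_ids[labels == 1]
        if left.size == 0 or right.size == 0:
            node.split_failed = True
            continue
        # deterministic child order: lexicographically smaller centroid first
        c0, c1 = km.cluster_centers_
        if tuple(c1) < tuple(c0):
            left, right = right, left
        a = new_node(left, node.depth + 1, node.node_id)
        b = new_node(right, node.depth + 1, node.node_id)
        node.children = (a.node_id, b.node_id)
        stack.extend([b, a])
    return tree


def representative_tscs(tree: ClusterTree, tsc_matrix) -> list[tuple[int, int, np.ndarray]]:
    """Per-leaf (leaf id, member count, mean original TSC).

    Means are taken over the original curves, not the derivative features;
    counts sum to the total voxel number (leaves partition the voxel set).
    """
    x = np.atleast_2d(np.asarray(tsc_matrix, dtype=float))
    leaves = sorted(tree.leaves(), key=lambda n: n.node_id)
    total = sum(leaf.count for leaf in leaves)
    if total != x.shape[0]:
        raise ValueError(
            f"tree covers {total} voxels but TSC matrix has {x.shape[0]} rows"
        )
    return [(leaf.node_id, leaf.count, x[leaf.member_ids].mean(axis=0)) for leaf in leaves]
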