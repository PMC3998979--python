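"""Expression-profile clustering: a from-scratch self-organizing tree
algorithm (SOTA) and agglomerative hierarchical clustering with k-group cuts.

SOTA grows a binary tree of cells. Growth starts from a single root cell at
the data mean; each growth cycle runs adaptation epochs (every profile is
presented, the closest leaf cell and — while its sister is a leaf — its
parent and sister are moved toward the profile), then the leaf with the
highest resource (mean member-to-centroid distance) splits into two
daughters. Growth stops when every leaf's resource falls at or below the
threshold, the leaf count reaches `max_clusters`, or cycles are exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform


@dataclass
class SotaNode:
    node_id: int
    centroid: np.ndarray
    parent: Optional[int] = None
    children: Tuple[int, int] | None = None
    member_genes: List[str] = field(default_factory=list)
    resource: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class ClusterAssignment:
    """Gene -> 1..k cluster labels produced by one clustering method."""

    labels: Dict[str, int]
    k: int
    method: str

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as handle:
            handle.write("gene_id\tcluster\n")
            for gene in sorted(self.labels):
                handle.write(f"{gene}\t{self.labels[gene]}\n")


def _profile_distances(x: np.ndarray, centroid: np.ndarray, distance: str) -> np.ndarray:
    """Distances from each row of x to a single centroid."""
    if distance == "euclidean":
        return np.linalg.norm(x - centroid, axis=1)
    # pearson: 1 - r, with constant profiles pinned (0 to constant, 1 otherwise)
    xc = x - x.mean(axis=1, keepdims=True)
    cc = centroid - centroid.mean()
    x_norm = np.linalg.norm(xc, axis=1)
    c_norm = np.linalg.norm(cc)
    out = np.empty(len(x))
    if c_norm == 0:
        out[:] = np.where(x_norm == 0, 0.0, 1.0)
        return out
    flat = x_norm == 0
    out[flat] = 1.0
    if (~flat).any():
        r = (xc[~flat] @ cc) / (x_norm[~flat] * c_norm)
        out[~flat] = 1.0 - np.clip(r, -1.0, 1.0)
    return out


def _pairwise_distances(x: np.ndarray, distance: str) -> np.ndarray:
    n = len(x)
    out = np.zeros((n, n))
    if distance == "euclidean":
        for i in range(n):
            out[i] = np.linalg.norm(x - x[i], axis=1)
        return out
    for i in range(n):
        out[i] = _profile_distances(x, x[i], "pearson")
        out[i, i] = 0.0
    return np.maximum(out, out.T)  # symmetrize against fp noise


class _SotaTree:
    def __init__(self, data: np.ndarray, gene_ids: Sequence[str], distance: str, rng: np.random.Generator):
        self.data = data
        self.gene_ids = list(gene_ids)
        self.distance = distance
        self.rng = rng
        self.nodes: Dict[int, SotaNode] = {}
        self._next_id = 0
        root = self._new_node(data.mean(axis=0))
        self.leaf_ids: List[int] = [root.node_id]
        self.assignment = np.zeros(len(data), dtype=int)  # leaf id per gene

    def _new_node(self, centroid: np.ndarray, parent: Optional[int] = None) -> SotaNode:
        node = SotaNode(node_id=self._next_id, centroid=centroid.copy(), parent=parent)
        self.nodes[self._next_id] = node
        self._next_id += 1
        return node

    def assign_all(self) -> None:
        """Map every profile to its closest leaf (ties -> lowest node id)."""
        dists = np.column_stack(
            [_profile_distances(self.data, self.nodes[l].centroid, self.distance) for l in self.leaf_ids]
        )
        winners = np.argmin(dists, axis=1)  # argmin takes first minimum; leaf_ids ascend
        self.assignment = np.array([self.leaf_ids[w] for w in winners])
        for leaf_id in self.leaf_ids:
            node = self.nodes[leaf_id]
            members = np.flatnonzero(self.assignment == leaf_id)
            node.member_genes = [self.gene_ids[i] for i in members]
            if len(members) == 0:
                node.resource = 0.0
            else:
                node.resource = float(
                    _profile_distances(self.data[members], node.centroid, self.distance).mean()
                )

    def adapt(self, epochs: int, alphas: Tuple[float, float, float]) -> None:
        a_win, a_parent, a_sister = alphas
        for _ in range(epochs):
            for i in range(len(self.data)):
                profile = self.data[i]
                centroids = np.vstack([self.nodes[l].centroid for l in self.leaf_ids])
                dists = _profile_distances(centroids, profile, self.distance)
                winner = self.nodes[self.leaf_ids[int(np.argmin(dists))]]
                winner.centroid += a_win * (profile - winner.centroid)
                if winner.parent is not None:
                    parent = self.nodes[winner.parent]
                    c1, c2 = parent.children  # type: ignore[misc]
                    sister = self.nodes[c2 if winner.node_id == c1 else c1]
                    if sister.is_leaf:
                        parent.centroid += a_parent * (profile - parent.centroid)
                        sister.centroid += a_sister * (profile - sister.centroid)

    def split(self, leaf_id: int, jitter: float = 1e-6) -> None:
        node = self.nodes[leaf_id]
        scale = max(float(np.abs(node.centroid).max()), 1.0) * jitter
        left = self._new_node(node.centroid + self.rng.normal(0, scale, node.centroid.shape), parent=leaf_id)
        right = self._new_node(node.centroid + self.rng.normal(0, scale, node.centroid.shape), parent=leaf_id)
        node.children = (left.node_id, right.node_id)
        node.member_genes = []
        self.leaf_ids = sorted(set(self.leaf_ids) - {leaf_id} | {left.node_id, right.node_id})


def sota_cluster(
    matrix: pd.DataFrame,
    distance: str = "pearson",
    max_cycles: int = 1000,
    resource_threshold: float = 0.0,
    max_clusters: int = 6,
    learning: Tuple[float, float, float] = (0.01, 0.005, 0.001),
    adaptation_epochs: int = 30,
    seed: int = 0,
) -> Tuple[Dict[int, SotaNode], ClusterAssignment]:
    """Cluster gene profiles (rows of `matrix`, e.g. log2 TPM) with SOTA.

    Returns the grown node tree plus a ClusterAssignment whose labels number
    the leaves 1..k in node-id order.
    """
    if max_clusters < 1:
        raise ValueError("max_clusters must be >= 1")
    if distance not in ("pearson", "euclidean"):
        raise ValueError(f"unknown distance {distance!r}")
    if len(matrix) < 1:
        raise ValueError("at least one gene profile is required")
    data = matrix.to_numpy(dtype=float)
    if not np.isfinite(data).all():
        raise ValueError("profiles must be finite")

    tree = _SotaTree(data, list(matrix.index), distance, np.random.default_rng(seed))
    tree.assign_all()
    for _ in range(max_cycles):
        if len(tree.leaf_ids) >= max_clusters:
            break
        worst = max(
            (tree.nodes[l] for l in tree.leaf_ids), key=lambda node: (node.resource, -node.node_id)
        )
        if worst.resource <= resource_threshold:
            break
        tree.split(worst.node_id)
        tree.adapt(adaptation_epochs, learning)
        tree.assign_all()

    labels: Dict[str, int] = {}
    for cluster, leaf_id in enumerate(sorted(tree.leaf_ids), start=1):
        for gene in tree.nodes[leaf_id].member_genes:
            labels[gene] = cluster
    # drop empty leaves from the label range
    used = sorted(set(labels.values()))
    remap = {old: new for new, old in enumerate(used, start=1)}
    labels = {g: remap[c] for g, c in labels.items()}
    assignment = ClusterAssignment(labels=labels, k=len(used), method="sota")
    return tree.nodes, assignment


def hier_cluster(
    matrix: pd.DataFrame,
    distance: str = "pearson",
    linkage_method: str = "average",
    k: int = 6,
) -> Tuple[ClusterAssignment, np.ndarray]:
    """Agglomerative clustering of gene profiles; cut the merge tree at k.

    Returns the assignment and the scipy linkage matrix. Cutting uses
    `scipy.cluster.hierarchy.cut_tree`, so the k-cut refines the (k-1)-cut.
    """
    if linkage_method not in ("average", "complete"):
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    n = len(matrix)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    data = matrix.to_numpy(dtype=float)
    dist = _pairwise_distances(data, distance)
    merge_tree = linkage(squareform(dist, checks=False), method=linkage_method)
    flat = cut_tree(merge_tree, n_clusters=k).ravel()
    # relabel in order of first appearance for determinism
    remap: Dict[int, int] = {}
    labels: Dict[str, int] = {}
    for gene, raw in zip(matrix.index, flat):
        if raw not in remap:
            remap[raw] = len(remap) + 1
        labels[gene] = remap[raw]
    return ClusterAssignment(labels=labels, k=k, method="hierarchical"), merge_tree


def linkage_to_newick(merge_tree: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string for inspection."""
    n = len(leaf_names)
    subtrees: Dict[int, str] = {i: str(leaf_names[i]) for i in range(n)}
    heights: Dict[int, float] = {i: 0.0 for i in range(n)}
    for step, (a, b, height, _) in enumerate(merge_tree):
        a, b = int(a), int(b)
        la = max(height - heights[a], 0.0)
        lb = max(height - heights[b], 0.0)
        node = n + step
        subtrees[node] = f"({subtrees[a]}:{la:.6g},{subtrees[b]}:{lb:.6g})"
        heights[node] = float(height)
    return subtrees[n + len(merge_tree) - 1] + ";"


def cluster_profile_summary(
    assignment: ClusterAssignment, matrix: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster mean profile, size, and above/below grand-mean direction.

    Rows are cluster labels; columns are the matrix columns (mean profile),
    `size`, and one `dir_<col>` tag per column ("above"/"below" the grand
    mean of gene-wise profile means).
    """
    missing = set(matrix.index) - set(assignment.labels)
    if missing:
        raise ValueError(f"assignment does not cover genes: {sorted(missing)[:5]}")
    grand = matrix.to_numpy(dtype=float).mean()
    rows = []
    for cluster in range(1, assignment.k + 1):
        genes = [g for g in matrix.index if assignment.labels[g] == cluster]
        mean_profile = matrix.loc[genes].mean(axis=0)
        row = dict(mean_profile)
        row["size"] = len(genes)
        for col in matrix.columns:
            row[f"dir_{col}"] = "above" if mean_profile[col] >= grand else "below"
        rows.append(row)
    return pd.DataFrame(rows, index=pd.RangeIndex(1, assignment.k + 1, name="cluster"))
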