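"""Tree-landscape analysis: Robinson-Foulds and Kendall-Colijn pairwise
distances, classical principal-coordinate ordination, and grove
detection by Ward hierarchical clustering of the leading axes.

RF operates on trees read as unrooted (symmetric difference of the
non-trivial bipartition sets); KC requires rooted trees and compares,
for every tip pair, the depth of their most recent common ancestor
(topological, branch-length, or a lambda-mixture of both).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .io_core import PhyloTree, bipartitions, leaf_labels

__all__ = [
    "TreeDistanceMatrix",
    "Ordination",
    "rf_distance",
    "rf_distance_matrix",
    "kc_vector",
    "kc_distance",
    "kc_distance_matrix",
    "pcoa",
    "find_groves",
    "plot_landscape",
]


class LeafsetMismatchError(ValueError):
    """Trees being compared do not share one leaf set."""


@dataclass
class TreeDistanceMatrix:
    """Pairwise tree distances with their metric tag."""

    tree_ids: list[str]
    matrix: np.ndarray
    metric: str                      # "RF" or "KC"
    kc_lambda: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        n = len(self.tree_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("id / matrix shape mismatch")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.matrix < 0):
            raise ValueError("distances must be nonnegative")

    def to_csv(self, path: str) -> None:
        pd.DataFrame(self.matrix, index=self.tree_ids,
                     columns=self.tree_ids).to_csv(path)


@dataclass
class Ordination:
    """Classical-scaling coordinates of a tree set."""

    tree_ids: list[str]
    coordinates: np.ndarray          # (n_trees, n_axes)
    eigenvalues: np.ndarray          # retained (positive), non-increasing
    variance_explained: np.ndarray
    dropped_negative: int = 0
    grove_labels: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Robinson-Foulds


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric-difference (RF) distance between two unrooted trees."""
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    if l1 != l2:
        raise LeafsetMismatchError(
            "trees have different leaf sets; harmonize first")
    s1, s2 = bipartitions(t1), bipartitions(t2)
    return len(s1 ^ s2)


def rf_distance_matrix(trees: list[PhyloTree], tree_ids: list[str],
                       normalized: bool = False) -> TreeDistanceMatrix:
    """All pairwise RF distances; optionally divided by 2(n-3)."""
    splits = [bipartitions(t) for t in trees]
    leafsets = {leaf_labels(t) for t in trees}
    if len(leafsets) != 1:
        raise LeafsetMismatchError("trees do not share one leaf set")
    n_leaves = len(next(iter(leafsets)))
    denom = 2.0 * (n_leaves - 3) if normalized else 1.0
    n = len(trees)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = len(splits[i] ^ splits[j]) / denom
    return TreeDistanceMatrix(list(tree_ids), D, "RF")


# ---------------------------------------------------------------------------
# Kendall-Colijn


def kc_vector(tree: PhyloTree, lam: float = 0.0) -> np.ndarray:
    """Kendall-Colijn characterization vector of a rooted tree.

    For each unordered tip pair (lexicographic order): (1-lambda) times
    the edge count from the root to the pair's MRCA plus lambda times
    the branch-length sum on that path; followed by per-tip pendant
    entries (1-lambda) * 1 + lambda * pendant length.
    """
    if not tree.is_rooted:
        raise ValueError("KC vector requires a rooted tree")
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must be in [0, 1]")
    taxa = sorted(leaf_labels(tree))
    pos = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)

    # root-to-node topological depth and length depth
    depth_e = {tree.seed_node: 0}
    depth_l = {tree.seed_node: 0.0}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            depth_e[nd] = depth_e[nd.parent_node] + 1
            depth_l[nd] = depth_l[nd.parent_node] + (nd.edge.length or 0.0)

    # MRCA depth per tip pair via postorder leaf-set accumulation
    pair_e = np.zeros((n, n))
    pair_l = np.zeros((n, n))
    below: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[nd] = [pos[nd.taxon.label]]
            continue
        child_sets = [below[c] for c in nd.child_nodes()]
        for s1, s2 in itertools.combinations(child_sets, 2):
            for a in s1:
                for b in s2:
                    pair_e[a, b] = pair_e[b, a] = depth_e[nd]
                    pair_l[a, b] = pair_l[b, a] = depth_l[nd]
        below[nd] = [x for s in child_sets for x in s]

    pend_e = np.ones(n)
    pend_l = np.zeros(n)
    for l in tree.leaf_node_iter():
        pend_l[pos[l.taxon.label]] = l.edge.length or 0.0

    iu = np.triu_indices(n, k=1)
    pair_part = (1.0 - lam) * pair_e[iu] + lam * pair_l[iu]
    tip_part = (1.0 - lam) * pend_e + lam * pend_l
    return np.concatenate([pair_part, tip_part])


def kc_distance(t1: PhyloTree, t2: PhyloTree, lam: float = 0.0) -> float:
    """Euclidean distance between Kendall-Colijn vectors."""
    if leaf_labels(t1) != leaf_labels(t2):
        raise LeafsetMismatchError(
            "trees have different leaf sets; harmonize first")
    return float(np.linalg.norm(kc_vector(t1, lam) - kc_vector(t2, lam)))


def kc_distance_matrix(trees: list[PhyloTree], tree_ids: list[str],
                       lam: float = 0.0) -> TreeDistanceMatrix:
    vecs = [kc_vector(t, lam) for t in trees]
    leafsets = {leaf_labels(t) for t in trees}
    if len(leafsets) != 1:
        raise LeafsetMismatchError("trees do not share one leaf set")
    V = np.stack(vecs)
    sq = ((V[:, None, :] - V[None, :, :]) ** 2).sum(axis=2)
    D = np.sqrt(np.maximum(sq, 0.0))
    np.fill_diagonal(D, 0.0)
    return TreeDistanceMatrix(list(tree_ids), D, "KC", kc_lambda=lam)


# ---------------------------------------------------------------------------
# ordination and groves


def pcoa(D: TreeDistanceMatrix, k: int = 3) -> Ordination:
    """Classical scaling (principal coordinate analysis).

    Double-centers -D^2/2, eigendecomposes, and keeps the top-k axes
    with positive eigenvalues (coordinates scaled by sqrt(eigenvalue)).
    Negative eigenvalues (non-Euclidean part) are dropped and counted.
    """
    if k < 1:
        raise ValueError("k must be positive")
    M = D.matrix
    n = M.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (M ** 2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = 1e-10 * max(1.0, abs(vals[0])) if n else 0.0
    positive = vals > tol
    n_pos = int(positive.sum())
    n_neg = int((vals < -tol).sum())
    kept = min(k, n_pos)
    coords = vecs[:, :kept] * np.sqrt(vals[:kept])[None, :]
    total = vals[positive].sum()
    var = vals[:kept] / total if total > 0 else np.zeros(kept)
    return Ordination(list(D.tree_ids), coords, vals[:kept], var,
                      dropped_negative=n_neg)


def find_groves(ordination: Ordination, n_axes: int = 3,
                k_groups: int = 2) -> np.ndarray:
    """Groves: Ward clustering on the first ``n_axes`` coordinates.

    Returns integer labels (1..k_groups), stored on the ordination; the
    labels are canonicalized by first appearance so they are stable
    under tree reordering of equivalent configurations.
    """
    n_trees = ordination.coordinates.shape[0]
    if k_groups < 1 or k_groups > n_trees:
        raise ValueError("k_groups must be in [1, n_trees]")
    if k_groups == 1:
        labels = np.ones(n_trees, dtype=int)
    else:
        axes = min(n_axes, ordination.coordinates.shape[1])
        X = ordination.coordinates[:, :axes]
        Z = linkage(X, method="ward")
        labels = fcluster(Z, t=k_groups, criterion="maxclust")
    # canonicalize by order of first appearance
    remap: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out[i] = remap[lab]
    ordination.grove_labels = out
    return out


def plot_landscape(ordination: Ordination, path: str,
                   title: str = "tree landscape") -> None:
    """Scatter plots of axes 1-2 and 1-3, colored by grove."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = ordination.coordinates
    labels = ordination.grove_labels
    fig, axes = plt.subplots(1, 2, figsize=(11, 5))
    pairs = [(0, 1), (0, 2)]
    for ax, (i, j) in zip(axes, pairs):
        if coords.shape[1] <= j:
            ax.set_visible(False)
            continue
        c = labels if labels is not None else "k"
        ax.scatter(coords[:, i], coords[:, j], c=c, cmap="tab10", s=60)
        for tid, x, y in zip(ordination.tree_ids, coords[:, i],
                             coords[:, j]):
            ax.annotate(tid, (x, y), fontsize=7,
                        textcoords="offset points", xytext=(3, 3))
        ax.set_xlabel(f"axis {i + 1}")
        ax.set_ylabel(f"axis {j + 1}")
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
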