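"""Likelihood and distance machinery: maximum-likelihood pairwise
distances, neighbor-joining, Felsenstein pruning per-site
log-likelihoods, and fixed-topology branch-length optimization.

Everything here is desk-scale by design: gene trees are inferred by
neighbor-joining on ML distances, and candidate species trees are scored
by re-optimizing branch lengths on a fixed alignment before the
resampling (RELL) topology tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .io_core import MISSING_CODE, MultipleAlignment, PhyloTree, clone_tree
from .simulate import JC69, SubstitutionModel

__all__ = [
    "SiteLikelihoodMatrix",
    "UndefinedDistanceError",
    "ml_distance",
    "jc_distance_from_p",
    "ml_distance_matrix",
    "nj_tree",
    "site_loglik",
    "optimize_branch_lengths",
    "nj_gene_tree",
]

#: sentinel for saturated distances (mismatch fraction >= 3/4 under JC)
INF_DISTANCE = np.inf

BL_MAX = 10.0  # substitutions/site upper bound for branch optimization


class UndefinedDistanceError(ValueError):
    """Two sequences share no called sites."""


def jc_distance_from_p(p: float) -> float:
    """Jukes-Cantor distance from an observed mismatch proportion."""
    if p >= 0.75:
        return INF_DISTANCE
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def ml_distance(seq_i, seq_j, model: SubstitutionModel = JC69) -> float:
    """Pairwise ML distance over shared called sites.

    JC69 uses the closed form ``d = -(3/4) ln(1 - 4p/3)``; saturation
    (``p >= 3/4``) returns an infinite sentinel.  HKY85 maximizes the
    two-sequence likelihood numerically.
    """
    ci, cj = _codes(seq_i), _codes(seq_j)
    both = (ci != MISSING_CODE) & (cj != MISSING_CODE)
    n = int(both.sum())
    if n == 0:
        raise UndefinedDistanceError("no shared called sites")
    a, b = ci[both], cj[both]
    if model.name == "JC69":
        p = float((a != b).mean())
        return float(jc_distance_from_p(p))
    counts = np.zeros((4, 4))
    np.add.at(counts, (a, b), 1)
    pi = np.asarray(model.freqs)

    def neg_ll(t: float) -> float:
        P = model.transition_matrix(t)
        with np.errstate(divide="ignore"):
            ll = counts * np.log(np.maximum(pi[:, None] * P, 1e-300))
        return -float(ll.sum())

    res = minimize_scalar(neg_ll, bounds=(1e-9, BL_MAX), method="bounded",
                          options={"xatol": 1e-10})
    if neg_ll(1e-12) <= res.fun:
        return 0.0
    return float(res.x)


def _codes(seq) -> np.ndarray:
    arr = np.asarray(seq)
    if arr.dtype == np.uint8:
        return arr
    from .io_core import _CODE
    return _CODE[np.char.upper(arr.astype("S1")).view(np.uint8)]


def ml_distance_matrix(aln: MultipleAlignment,
                       model: SubstitutionModel = JC69,
                       taxa: list[str] | None = None) -> np.ndarray:
    """Symmetric matrix of pairwise ML distances (JC vectorized)."""
    if taxa is None:
        taxa = aln.taxa
    codes = aln.codes()[[aln.taxa.index(t) for t in taxa]]
    n = len(taxa)
    D = np.zeros((n, n))
    called = codes != MISSING_CODE
    if model.name == "JC69":
        for i in range(n):
            for j in range(i + 1, n):
                both = called[i] & called[j]
                m = int(both.sum())
                if m == 0:
                    raise UndefinedDistanceError(
                        f"{taxa[i]} / {taxa[j]}: no shared called sites")
                p = float((codes[i][both] != codes[j][both]).mean())
                D[i, j] = D[j, i] = jc_distance_from_p(p)
    else:
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = ml_distance(codes[i], codes[j], model)
    return D


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(D: np.ndarray, taxa: list[str]) -> PhyloTree:
    """Neighbor-joining tree (unrooted) from a distance matrix.

    Infinite entries (saturated distances) are imputed as the largest
    finite entry plus one; negative branch-length estimates are clamped
    to zero.
    """
    D = np.array(D, dtype=float)
    n = D.shape[0]
    if n != D.shape[1] or n != len(taxa):
        raise ValueError("distance matrix / label mismatch")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.isinf(D).any():
        finite_max = D[np.isfinite(D)].max()
        D[np.isinf(D)] = finite_max + 1.0

    tns = dendropy.TaxonNamespace()
    nodes = [dendropy.Node(taxon=tns.require_taxon(t)) for t in taxa]
    active = list(range(n))
    D = D.copy()

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Qm = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Qm, np.inf)
        i_, j_ = np.unravel_index(np.argmin(Qm), Qm.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        ai, aj = active[i_], active[j_]
        dij = sub[i_, j_]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[ai])
        parent.add_child(nodes[aj])
        nodes[ai].edge.length = li
        nodes[aj].edge.length = lj
        # distances from the new node
        new_d = 0.5 * (D[ai, :] + D[aj, :] - dij)
        D = np.vstack([D, new_d])
        new_col = np.append(new_d, 0.0)
        D = np.column_stack([D, new_col])
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]

    a, b = active
    dab = max(D[a, b], 0.0)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = False
    if nodes[b].is_leaf():
        a, b = b, a
    # attach the remaining pair: use b (internal if any) as the seed
    root = nodes[b]
    root.add_child(nodes[a])
    nodes[a].edge.length = dab
    tree.seed_node = root
    return tree


def nj_gene_tree(aln: MultipleAlignment,
                 model: SubstitutionModel = JC69,
                 min_called: int = 1) -> PhyloTree | None:
    """Per-locus gene tree: NJ on ML distances.

    Taxa with fewer than ``min_called`` called sites are excluded; loci
    with fewer than four usable taxa return ``None`` (uninformative for
    quartet-based species-tree estimation).
    """
    codes = aln.codes()
    ok = (codes != MISSING_CODE).sum(axis=1) >= max(min_called, 1)
    taxa = [t for t, o in zip(aln.taxa, ok) if o]
    if len(taxa) < 4:
        return None
    try:
        D = ml_distance_matrix(aln, model, taxa=taxa)
    except UndefinedDistanceError:
        return None
    return nj_tree(D, taxa)


# ---------------------------------------------------------------------------
# pruning likelihoods


@dataclass
class SiteLikelihoodMatrix:
    """Per-site log-likelihoods of several trees on one fixed alignment."""

    tree_ids: list[str]
    matrix: np.ndarray  # (n_trees, n_sites)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, float))
        if len(self.tree_ids) != self.matrix.shape[0]:
            raise ValueError("tree id / row mismatch")
        if not np.isfinite(self.matrix).all():
            raise ValueError("non-finite per-site log-likelihoods")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def totals(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def to_csv(self, path: str) -> None:
        import pandas as pd
        pd.DataFrame(self.matrix, index=self.tree_ids).to_csv(path)


def _compress_patterns(codes: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique site patterns, their weights, and site -> pattern index."""
    cols = np.ascontiguousarray(codes.T)
    view = cols.view([("", codes.dtype)] * codes.shape[0]).ravel()
    _, first, inverse, counts = np.unique(
        view, return_index=True, return_inverse=True, return_counts=True)
    patterns = codes[:, first]
    return patterns, counts.astype(float), inverse


def _pattern_loglik(tree: PhyloTree, taxa_index: dict[str, int],
                    patterns: np.ndarray,
                    model: SubstitutionModel,
                    scale: float = 1.0) -> np.ndarray:
    """Felsenstein pruning: log-likelihood of each site pattern.

    Gaps/N contribute a flat partial likelihood of 1 over all states;
    the root uses the model's stationary frequencies (the likelihood is
    invariant to root placement for these reversible models).  ``scale``
    multiplies every branch length (per-partition rate scalars).
    """
    pi = np.asarray(model.freqs)
    S = patterns.shape[1]
    rates = model.gamma_rates() * scale
    per_rate = np.zeros((len(rates), S))
    eye = np.eye(4)
    for ri, r in enumerate(rates):
        logscale = np.zeros(S)
        partial: dict = {}
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                row = patterns[taxa_index[nd.taxon.label]]
                L = np.ones((4, S))
                called = row != MISSING_CODE
                L[:, called] = eye[:, row[called]]
                partial[nd] = L
            else:
                L = np.ones((4, S))
                for c in nd.child_nodes():
                    t = (c.edge.length or 0.0) * r
                    P = model.transition_matrix(t)
                    L = L * (P @ partial.pop(c))
                m = L.max(axis=0)
                m = np.where(m > 0, m, 1.0)
                L = L / m
                logscale += np.log(m)
                partial[nd] = L
        root = partial[tree.seed_node]
        per_rate[ri] = np.log(np.maximum(pi @ root, 1e-300)) + logscale
    if len(rates) == 1:
        return per_rate[0]
    # mean over equiprobable rate categories, in log space
    mx = per_rate.max(axis=0)
    return mx + np.log(np.exp(per_rate - mx).mean(axis=0))


def site_loglik(tree: PhyloTree, aln: MultipleAlignment,
                model: SubstitutionModel = JC69) -> np.ndarray:
    """Per-site log-likelihood vector of one tree on one alignment."""
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    missing = labels - set(aln.taxa)
    if missing:
        raise KeyError(f"tree leaves missing from alignment: {sorted(missing)}")
    taxa_index = {t: i for i, t in enumerate(aln.taxa)}
    patterns, _, inverse = _compress_patterns(aln.codes())
    per_pattern = _pattern_loglik(tree, taxa_index, patterns, model)
    return per_pattern[inverse]


def optimize_branch_lengths(topology: PhyloTree, aln: MultipleAlignment,
                            model: SubstitutionModel = JC69,
                            tol: float = 1e-6, max_sweeps: int = 20,
                            ) -> tuple[PhyloTree, np.ndarray, bool]:
    """Cyclic one-branch ML optimization on a fixed topology.

    Each sweep optimizes every branch in turn by bounded scalar search
    on [0, 10] substitutions/site; sweeps stop when the total
    log-likelihood improves by less than ``tol``.  Returns the optimized
    tree, its per-site log-likelihood vector, and a convergence flag
    (``False`` when the sweep cap was hit while still improving).
    """
    tree = clone_tree(topology)
    taxa_index = {t: i for i, t in enumerate(aln.taxa)}
    patterns, weights, inverse = _compress_patterns(aln.codes())

    def total() -> float:
        return float(_pattern_loglik(tree, taxa_index, patterns, model)
                     @ weights)

    edges = [nd for nd in tree.preorder_node_iter()
             if nd.parent_node is not None]
    for nd in edges:
        if nd.edge.length is None or nd.edge.length < 0:
            nd.edge.length = 0.01

    prev = total()
    converged = False
    for _ in range(max_sweeps):
        for nd in edges:
            cur = nd.edge.length

            def neg(t: float, _nd=nd) -> float:
                _nd.edge.length = t
                return -total()

            res = minimize_scalar(neg, bounds=(0.0, BL_MAX),
                                  method="bounded",
                                  options={"xatol": 1e-8})
            if -res.fun >= -neg(cur):
                nd.edge.length = float(res.x)
            else:
                nd.edge.length = cur
        cur_total = total()
        if cur_total - prev < tol:
            converged = True
            prev = cur_total
            break
        prev = cur_total
    per_site = _pattern_loglik(tree, taxa_index, patterns, model)[inverse]
    return tree, per_site, converged
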