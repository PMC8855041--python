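"""Species-tree estimation: concatenation (partitioned / unpartitioned)
and maximum-quartet-support estimation under the multispecies
coalescent, with bootstrap and quartet-based branch supports.

The quartet objective is the one ASTRAL maximizes: the number of induced
four-taxon topologies shared between a candidate species tree and the
gene trees.  At desk scale (<= 8 taxa) the maximizer is found by exact
enumeration over all unrooted binary topologies; above that, by
neighbor-joining on average gene-tree path-count distances followed by
NNI hill-climbing.  Branch support on MSC trees is the normalized
quartet support (share of gene-tree quartets around a branch agreeing
with it), not ASTRAL's local posterior probability.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .io_core import (
    MISSING_CODE,
    MultipleAlignment,
    PhyloTree,
    bipartitions,
    clone_tree,
    leaf_labels,
    to_newick,
    topo_leaf_distances,
)
from .phylo_engine import (
    _pattern_loglik,
    _compress_patterns,
    ml_distance_matrix,
    nj_gene_tree,
    nj_tree,
    optimize_branch_lengths,
)
from .simulate import JC69, LocusSet, SubstitutionModel

__all__ = [
    "MethodSpec",
    "quartet_score",
    "msc_tree",
    "msc_bootstrap",
    "concatenated_tree",
    "build_supermatrix",
    "annotate_supports",
]


@dataclass
class MethodSpec:
    """One of the five species-tree method variants.

    ``Cpa``/``Cun``: concatenated partitioned / unpartitioned with
    site-bootstrap support; ``As``: MSC tree with quartet support;
    ``Abs``: MSC with gene+site bootstrap (default 100 replicates);
    ``AUFbs``: MSC with the fast site-only bootstrap analog (1,000
    replicates at full scale, 200 at desk scale).
    """

    method: str
    replicates: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("Cpa", "Cun", "As", "Abs", "AUFbs"):
            raise ValueError(f"unknown method {self.method}")
        if self.method in ("Abs", "AUFbs", "Cpa", "Cun") \
                and self.replicates == 0:
            self.replicates = {"Abs": 100, "AUFbs": 1000,
                               "Cpa": 100, "Cun": 100}[self.method]
        if self.method != "As" and self.replicates < 1:
            raise ValueError("replicate count must be positive")


# ---------------------------------------------------------------------------
# quartet index


@dataclass
class _QuartetIndex:
    taxa: list[str]                  # sorted global taxon order
    subsets: np.ndarray              # (S, 4) int, global indices, i<j<k<l

    @classmethod
    def for_taxa(cls, taxa) -> "_QuartetIndex":
        taxa = sorted(taxa)
        n = len(taxa)
        subsets = np.array(
            list(itertools.combinations(range(n), 4)), dtype=np.int64)
        return cls(taxa, subsets)

    @property
    def n_subsets(self) -> int:
        return self.subsets.shape[0]


def _resolutions_from_D(D: np.ndarray, subsets: np.ndarray) -> np.ndarray:
    """Induced quartet resolution per subset from a tree metric.

    Returns int8: 0 unresolved, 1 = ij|kl, 2 = ik|jl, 3 = il|jk.  Uses
    the four-point condition: the pairing with the strictly smallest
    distance sum is the induced split; ties mean the quartet is
    unresolved (multifurcation).
    """
    i, j, k, l = (subsets[:, 0], subsets[:, 1], subsets[:, 2], subsets[:, 3])
    sums = np.stack([D[i, j] + D[k, l], D[i, k] + D[j, l], D[i, l] + D[j, k]])
    mn = sums.min(axis=0)
    is_min = np.isclose(sums, mn[None, :], rtol=0.0, atol=1e-9)
    unique = is_min.sum(axis=0) == 1
    res = np.where(unique, sums.argmin(axis=0) + 1, 0).astype(np.int8)
    return res


def _tree_qvec(tree: PhyloTree, qidx: _QuartetIndex) -> np.ndarray:
    """Quartet-resolution vector of one tree over the global subsets.

    Subsets containing taxa absent from the tree are 0 (not comparable).
    """
    present = leaf_labels(tree)
    pos = {t: i for i, t in enumerate(qidx.taxa)}
    loc = np.full(len(qidx.taxa), -1, dtype=np.int64)
    tree_taxa = sorted(present & set(qidx.taxa))
    for li, t in enumerate(tree_taxa):
        loc[pos[t]] = li
    sub_loc = loc[qidx.subsets]
    usable = (sub_loc >= 0).all(axis=1)
    out = np.zeros(qidx.n_subsets, dtype=np.int8)
    if usable.any():
        D = topo_leaf_distances(tree, tree_taxa)
        out[usable] = _resolutions_from_D(D, sub_loc[usable])
    return out


def quartet_score(species_tree: PhyloTree,
                  gene_trees: list[PhyloTree]) -> int:
    """Number of gene-tree quartets whose induced topology matches the
    species tree; unresolved quartets (on either side) contribute 0."""
    qidx = _QuartetIndex.for_taxa(leaf_labels(species_tree))
    s = _tree_qvec(species_tree, qidx)
    total = 0
    for g in gene_trees:
        gv = _tree_qvec(g, qidx)
        total += int(((gv == s) & (s > 0) & (gv > 0)).sum())
    return total


def _gene_counts(gene_trees: list[PhyloTree],
                 qidx: _QuartetIndex) -> np.ndarray:
    """(3, S) counts of gene trees showing each resolution per subset."""
    counts = np.zeros((3, qidx.n_subsets), dtype=np.int64)
    for g in gene_trees:
        gv = _tree_qvec(g, qidx)
        for r in (1, 2, 3):
            counts[r - 1] += gv == r
    return counts


# ---------------------------------------------------------------------------
# topology enumeration (adjacency representation)


def _enumerate_adjacencies(n: int) -> list[dict]:
    """All (2n-5)!! unrooted binary topologies on leaves 0..n-1.

    Trees are adjacency dicts; internal node ids start at ``n``.
    Sequential leaf insertion into every edge.
    """
    base = {0: {n}, 1: {n}, 2: {n}, n: {0, 1, 2}}
    trees = [(base, n + 1)]
    for leaf in range(3, n):
        nxt = []
        for adj, next_id in trees:
            edges = []
            seen = set()
            for u, nbrs in adj.items():
                for v in nbrs:
                    if (v, u) not in seen:
                        seen.add((u, v))
                        edges.append((u, v))
            for (u, v) in edges:
                new = {k: set(s) for k, s in adj.items()}
                w = next_id
                new[u].discard(v)
                new[v].discard(u)
                new[u].add(w)
                new[v].add(w)
                new[w] = {u, v, leaf}
                new[leaf] = {w}
                nxt.append((new, next_id + 1))
        trees = nxt
    return [a for a, _ in trees]


def _adj_leaf_dists(adj: dict, n: int) -> np.ndarray:
    D = np.zeros((n, n))
    for a in range(n):
        dist = {a: 0}
        stack = [a]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    stack.append(v)
        for b in range(n):
            D[a, b] = dist[b]
    return D


def _adj_to_dendropy(adj: dict, taxa: list[str]) -> PhyloTree:
    n = len(taxa)
    tns = dendropy.TaxonNamespace()
    start = next(u for u in adj if u >= n)
    nodes = {start: dendropy.Node()}
    stack = [start]
    seen = {start}
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v in seen:
                continue
            seen.add(v)
            nd = dendropy.Node()
            if v < n:
                nd.taxon = tns.require_taxon(taxa[v])
            nodes[v] = nd
            nodes[u].add_child(nd)
            stack.append(v)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[start]
    tree.is_rooted = False
    return tree


_TOPOLOGY_CACHE: dict[int, tuple[list[dict], np.ndarray]] = {}


def _enumerated_qvecs(n: int, subsets: np.ndarray
                      ) -> tuple[list[dict], np.ndarray]:
    """All topologies on n leaves with their quartet vectors, cached."""
    if n not in _TOPOLOGY_CACHE:
        adjs = _enumerate_adjacencies(n)
        Q = np.zeros((len(adjs), subsets.shape[0]), dtype=np.int8)
        for t, adj in enumerate(adjs):
            D = _adj_leaf_dists(adj, n)
            Q[t] = _resolutions_from_D(D, subsets)
        _TOPOLOGY_CACHE[n] = (adjs, Q)
    return _TOPOLOGY_CACHE[n]


# ---------------------------------------------------------------------------
# MSC species tree


EXACT_MODE_MAX_TAXA = 8


def msc_tree(gene_trees: list[PhyloTree], mode: str = "auto",
             collapse_below: float | None = None,
             ) -> PhyloTree:
    """Maximum-quartet-support species tree from a set of gene trees.

    ``mode='exact'`` (<= 8 taxa) enumerates every unrooted binary
    topology and returns the quartet-score argmax, ties broken by the
    lexicographically smallest Newick string.  ``mode='heuristic'``
    starts from NJ on average gene-tree path-count distances and
    hill-climbs with NNI moves to a local optimum of the same score.
    Internal branches are annotated with normalized quartet support
    (percentage of resolved gene-tree quartets around the branch that
    agree with it); ``collapse_below`` optionally collapses branches
    whose support falls below the given percentage.
    """
    informative = [g for g in gene_trees if len(leaf_labels(g)) >= 4]
    if len(informative) < 2:
        raise ValueError("need at least 2 informative gene trees")
    taxa = sorted(set().union(*(leaf_labels(g) for g in informative)))
    n = len(taxa)
    qidx = _QuartetIndex.for_taxa(taxa)
    counts = _gene_counts(informative, qidx)
    if mode == "auto":
        mode = "exact" if n <= EXACT_MODE_MAX_TAXA else "heuristic"

    if mode == "exact":
        if n > EXACT_MODE_MAX_TAXA:
            raise ValueError("exact mode limited to 8 taxa")
        adjs, Q = _enumerated_qvecs(n, qidx.subsets)
        scores = np.zeros(len(adjs), dtype=np.int64)
        for r in (1, 2, 3):
            scores += (Q == r) @ counts[r - 1]
        best = scores.max()
        tied = np.flatnonzero(scores == best)
        if len(tied) > 1:
            newicks = [
                to_newick(_canonical(_adj_to_dendropy(adjs[t], taxa)),
                          include_lengths=False)
                for t in tied
            ]
            winner = tied[int(np.argmin(newicks))]
        else:
            winner = tied[0]
        tree = _adj_to_dendropy(adjs[winner], taxa)
    elif mode == "heuristic":
        tree = _nni_search(informative, taxa, qidx, counts)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    _annotate_quartet_support(tree, taxa, counts, qidx)
    if collapse_below is not None:
        _collapse_low_support(tree, collapse_below)
    return tree


def _canonical(tree: PhyloTree) -> PhyloTree:
    t = clone_tree(tree)
    # deterministic child order by smallest descendant label
    keys = {}
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            keys[nd] = nd.taxon.label
        else:
            nd._child_nodes.sort(key=lambda c: keys[c])
            keys[nd] = keys[nd.child_nodes()[0]]
    return t


def _avg_path_distances(gene_trees, taxa) -> np.ndarray:
    n = len(taxa)
    tot = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for g in gene_trees:
        present = sorted(leaf_labels(g) & set(taxa))
        if len(present) < 2:
            continue
        idx = [taxa.index(t) for t in present]
        D = topo_leaf_distances(g, present)
        ix = np.ix_(idx, idx)
        tot[ix] += D
        cnt[ix] += 1
    with np.errstate(invalid="ignore"):
        avg = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    if np.isnan(avg).any():
        mx = np.nanmax(avg)
        avg = np.where(np.isnan(avg), mx + 1.0, avg)
    np.fill_diagonal(avg, 0.0)
    return avg


def _dendropy_to_adj(tree: PhyloTree, taxa: list[str]) -> tuple[dict, int]:
    n = len(taxa)
    pos = {t: i for i, t in enumerate(taxa)}
    ids = {}
    next_id = n
    adj: dict[int, set] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            ids[nd] = pos[nd.taxon.label]
        else:
            ids[nd] = next_id
            next_id += 1
        adj.setdefault(ids[nd], set())
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            a, b = ids[nd], ids[nd.parent_node]
            adj[a].add(b)
            adj[b].add(a)
    # suppress degree-2 nodes (rooted input read as unrooted)
    for u in [u for u, s in adj.items() if len(s) == 2 and u >= n]:
        a, b = adj[u]
        adj[a].discard(u)
        adj[b].discard(u)
        adj[a].add(b)
        adj[b].add(a)
        del adj[u]
    return adj, next_id


def _score_adj(adj: dict, n: int, counts: np.ndarray,
               subsets: np.ndarray) -> int:
    D = _adj_leaf_dists(adj, n)
    res = _resolutions_from_D(D, subsets)
    s = 0
    for r in (1, 2, 3):
        s += int(counts[r - 1][res == r].sum())
    return s


def _nni_search(gene_trees, taxa, qidx, counts) -> PhyloTree:
    n = len(taxa)
    start = nj_tree(_avg_path_distances(gene_trees, taxa), list(taxa))
    adj, _ = _dendropy_to_adj(start, list(taxa))
    best_score = _score_adj(adj, n, counts, qidx.subsets)
    improved = True
    while improved:
        improved = False
        internal_edges = [
            (u, v) for u in adj for v in adj[u]
            if u < v and u >= n and v >= n
        ]
        for (u, v) in internal_edges:
            a_side = [w for w in adj[u] if w != v]
            b_side = [w for w in adj[v] if w != u]
            if len(a_side) != 2 or len(b_side) != 2:
                continue
            for swap_b in b_side:
                a1 = a_side[0]
                cand = {k: set(s) for k, s in adj.items()}
                cand[u].discard(a1)
                cand[a1].discard(u)
                cand[v].discard(swap_b)
                cand[swap_b].discard(v)
                cand[u].add(swap_b)
                cand[swap_b].add(u)
                cand[v].add(a1)
                cand[a1].add(v)
                sc = _score_adj(cand, n, counts, qidx.subsets)
                if sc > best_score:
                    adj, best_score = cand, sc
                    improved = True
                    break
            if improved:
                break
    return _adj_to_dendropy(adj, list(taxa))


def _split_sides(tree: PhyloTree) -> list[tuple[object, frozenset, frozenset]]:
    """(node, side_below, side_above) for each internal branch."""
    below = {}
    for nd in tree.postorder_node_iter():
        below[nd] = frozenset([nd.taxon.label]) if nd.is_leaf() else \
            frozenset().union(*(below[c] for c in nd.child_nodes()))
    all_leaves = below[tree.seed_node]
    out = []
    seen = set()
    for nd in tree.postorder_node_iter():
        if nd.is_leaf() or nd is tree.seed_node:
            continue
        side = below[nd]
        other = all_leaves - side
        split = frozenset([side, other])
        # a two-child root presents the same unrooted branch twice
        if len(side) >= 2 and len(other) >= 2 and split not in seen:
            seen.add(split)
            out.append((nd, side, other))
    return out


def _annotate_quartet_support(tree: PhyloTree, taxa, counts, qidx) -> None:
    pos = {t: i for i, t in enumerate(qidx.taxa)}
    for nd, side, other in _split_sides(tree):
        in_a = np.zeros(len(qidx.taxa), dtype=bool)
        for t in side:
            if t in pos:
                in_a[pos[t]] = True
        a_members = in_a[qidx.subsets]
        spanning = a_members.sum(axis=1) == 2
        if not spanning.any():
            continue
        am = a_members[spanning]
        # concordant resolution id given which two of (i,j,k,l) are on side A
        conc = np.where(
            am[:, 0] == am[:, 1], 1,
            np.where(am[:, 0] == am[:, 2], 2, 3))
        sub_counts = counts[:, spanning]
        resolved = sub_counts.sum(axis=0)
        concordant = sub_counts[conc - 1, np.arange(len(conc))]
        tot_res = int(resolved.sum())
        nd.quartet_support = (
            100.0 * float(concordant.sum()) / tot_res if tot_res else None)
        nd.label = (f"{nd.quartet_support:.1f}"
                    if nd.quartet_support is not None else None)


def _collapse_low_support(tree: PhyloTree, threshold: float) -> None:
    doomed = [
        nd for nd, _, _ in _split_sides(tree)
        if getattr(nd, "quartet_support", None) is not None
        and nd.quartet_support < threshold
    ]
    for nd in doomed:
        parent = nd.parent_node
        for c in list(nd.child_nodes()):
            nd.remove_child(c)
            parent.add_child(c)
        parent.remove_child(nd)


# ---------------------------------------------------------------------------
# supermatrix and concatenated trees


def build_supermatrix(loci: list[MultipleAlignment],
                      dataset: str = "supermatrix"
                      ) -> tuple[MultipleAlignment, list[tuple[str, int, int]]]:
    """Concatenate loci over the union taxon set.

    Missing taxa per locus are padded with gaps.  Returns the combined
    alignment and the partition table ``(locus_id, start, end)`` with
    half-open 0-based coordinates.
    """
    if not loci:
        raise ValueError("no loci to concatenate")
    taxa = sorted(set().union(*(set(a.taxa) for a in loci)))
    if any(not (set(a.taxa) & set(taxa)) for a in loci):
        raise ValueError("disjoint taxon sets")
    blocks = []
    parts = []
    pos = 0
    for a in loci:
        block = np.full((len(taxa), a.n_sites), b"-", dtype="S1")
        for ti, t in enumerate(taxa):
            if t in a.taxa:
                block[ti] = a.matrix[a.taxa.index(t)]
        blocks.append(block)
        parts.append((a.locus_id, pos, pos + a.n_sites))
        pos += a.n_sites
    sm = MultipleAlignment(dataset, loci[0].class_tag, taxa,
                           np.concatenate(blocks, axis=1))
    return sm, parts


def _bootstrap_support(main: PhyloTree, replicate_trees) -> None:
    """Annotate internal branches of ``main`` with % of replicate trees
    containing the same bipartition."""
    reps = [bipartitions(t) for t in replicate_trees]
    B = len(reps)
    for nd, side, other in _split_sides(main):
        split = frozenset([side, other])
        nd.bootstrap_support = 100.0 * sum(split in r for r in reps) / B
        nd.label = f"{nd.bootstrap_support:.0f}"


def concatenated_tree(loci: list[MultipleAlignment], partitioned: bool,
                      model: SubstitutionModel = JC69,
                      bootstrap_replicates: int = 100, seed: int = 0,
                      dataset: str = "concat",
                      ) -> tuple[PhyloTree, dict]:
    """Concatenation species tree with site-bootstrap branch support.

    Topology comes from NJ on supermatrix ML distances; branch lengths
    are re-optimized by maximum likelihood.  In the partitioned scheme
    every locus gets its own rate scalar multiplying the shared branch
    lengths (scalars and lengths alternately optimized, scalars
    normalized to mean 1); unpartitioned uses a single model for all
    sites.  Support is the percentage of site-resampling bootstrap
    replicates (sites resampled within loci, partition sizes preserved)
    whose NJ tree contains each branch.
    """
    sm, parts = build_supermatrix(loci, dataset=dataset)
    D = ml_distance_matrix(sm, model)
    main = nj_tree(D, sm.taxa)
    main.is_rooted = False

    info: dict = {"partition_rates": None}
    if not partitioned or len(loci) == 1:
        opt, per_site, _ = optimize_branch_lengths(main, sm, model,
                                                   max_sweeps=8)
        info["per_site_lnL"] = per_site
        if partitioned:
            info["partition_rates"] = {a.locus_id: 1.0 for a in loci}
    else:
        opt, rates = _optimize_partitioned(main, loci, sm.taxa, model)
        info["partition_rates"] = rates

    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(bootstrap_replicates):
        cols = []
        for (_, s, e) in parts:
            cols.append(rng.integers(s, e, size=e - s))
        idx = np.concatenate(cols)
        rep_aln = MultipleAlignment(sm.locus_id, sm.class_tag, sm.taxa,
                                    sm.matrix[:, idx])
        reps.append(nj_tree(ml_distance_matrix(rep_aln, model), sm.taxa))
    _bootstrap_support(opt, reps)
    info["supermatrix"] = sm
    return opt, info


def _optimize_partitioned(topology: PhyloTree,
                          loci: list[MultipleAlignment],
                          taxa: list[str], model: SubstitutionModel,
                          outer_iters: int = 2,
                          ) -> tuple[PhyloTree, dict[str, float]]:
    from scipy.optimize import minimize_scalar
    tree = clone_tree(topology)
    taxa_index = {t: i for i, t in enumerate(taxa)}
    per_locus = []
    for a in loci:
        # pad locus to the shared taxon order
        block = np.full((len(taxa), a.n_sites), MISSING_CODE, dtype=np.uint8)
        codes = a.codes()
        for ti, t in enumerate(a.taxa):
            block[taxa.index(t)] = codes[ti]
        pat, w, _ = _compress_patterns(block)
        per_locus.append((a.locus_id, pat, w))
    rates = {lid: 1.0 for lid, _, _ in per_locus}

    edges = [nd for nd in tree.preorder_node_iter()
             if nd.parent_node is not None]
    for nd in edges:
        if nd.edge.length is None or nd.edge.length <= 0:
            nd.edge.length = 0.01

    def locus_lnL(lid, pat, w, scale) -> float:
        return float(_pattern_loglik(tree, taxa_index, pat, model,
                                     scale=scale) @ w)

    def total() -> float:
        return sum(locus_lnL(lid, pat, w, rates[lid])
                   for lid, pat, w in per_locus)

    for _ in range(outer_iters):
        # shared branch lengths under the current rate scalars
        for _sweep in range(2):
            for nd in edges:
                cur = nd.edge.length

                def neg(t, _nd=nd):
                    _nd.edge.length = t
                    return -total()

                res = minimize_scalar(neg, bounds=(0.0, 10.0),
                                      method="bounded",
                                      options={"xatol": 1e-6})
                if res.fun <= neg(cur):
                    nd.edge.length = float(res.x)
                else:
                    nd.edge.length = cur
        # per-locus rate scalars
        for lid, pat, w in per_locus:
            res = minimize_scalar(
                lambda s: -locus_lnL(lid, pat, w, s),
                bounds=(1e-3, 100.0), method="bounded",
                options={"xatol": 1e-6})
            rates[lid] = float(res.x)
        # identifiability: mean rate 1, absorb into branch lengths
        mean_rate = float(np.mean(list(rates.values())))
        for lid in rates:
            rates[lid] /= mean_rate
        for nd in edges:
            nd.edge.length *= mean_rate
    return tree, rates


# ---------------------------------------------------------------------------
# MSC bootstraps


def _resample_sites(aln: MultipleAlignment, rng) -> MultipleAlignment:
    idx = rng.integers(aln.n_sites, size=aln.n_sites)
    return MultipleAlignment(aln.locus_id, aln.class_tag, list(aln.taxa),
                             aln.matrix[:, idx])


def msc_bootstrap(loci: LocusSet | list[MultipleAlignment],
                  gene_trees: list[PhyloTree], replicates: int,
                  flavor: str = "site_only", seed: int = 0,
                  model: SubstitutionModel = JC69,
                  ) -> tuple[PhyloTree, PhyloTree, list[PhyloTree]]:
    """Bootstrap support for the MSC species tree.

    ``gene_site`` resamples loci with replacement and sites within each
    sampled locus (the classical gene+site scheme); ``site_only`` is the
    fast analog that only resamples sites within each locus.  Per
    replicate the gene trees are re-inferred and the MSC tree re-built;
    support on the main tree is the percentage of replicate trees
    containing each branch.  Also returns the greedy majority-rule
    consensus of the replicate trees.
    """
    if flavor not in ("gene_site", "site_only"):
        raise ValueError(f"unknown flavor {flavor!r}")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    alns = loci.loci if isinstance(loci, LocusSet) else list(loci)
    rng = np.random.default_rng(seed)
    main = msc_tree(gene_trees)
    rep_trees = []
    for _ in range(replicates):
        if flavor == "gene_site":
            chosen = [alns[i] for i in
                      rng.integers(len(alns), size=len(alns))]
        else:
            chosen = alns
        rep_gts = []
        for a in chosen:
            gt = nj_gene_tree(_resample_sites(a, rng), model)
            if gt is not None:
                rep_gts.append(gt)
        if len(rep_gts) < 2:
            continue
        rep_trees.append(msc_tree(rep_gts))
    _bootstrap_support(main, rep_trees)
    consensus = greedy_consensus(rep_trees)
    return main, consensus, rep_trees


def greedy_consensus(trees: list[PhyloTree]) -> PhyloTree:
    """Greedy majority-rule consensus: add splits by decreasing
    frequency, keeping each only if compatible with those already in."""
    if not trees:
        raise ValueError("no trees")
    taxa = sorted(leaf_labels(trees[0]))
    from collections import Counter
    counter: Counter = Counter()
    for t in trees:
        for split in bipartitions(t):
            counter[split] += 1
    accepted: list[frozenset] = []

    def compatible(s1, s2) -> bool:
        a1, b1 = tuple(s1)
        a2, b2 = tuple(s2)
        return any(not (x & y) for x in (a1, b1) for y in (a2, b2))

    for split, _cnt in sorted(counter.items(),
                              key=lambda kv: (-kv[1], sorted(map(sorted, kv[0])))):
        if all(compatible(split, s) for s in accepted):
            accepted.append(split)
    # build from clusters relative to a reference taxon
    ref = taxa[0]
    clusters = sorted(
        (next(side for side in s if ref not in side) for s in accepted),
        key=len, reverse=True)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = False
    root = tree.seed_node
    node_of: dict[frozenset, object] = {frozenset(taxa): root}
    parents = [frozenset(taxa)]
    for cl in clusters:
        parent = min((p for p in parents if cl < p), key=len)
        nd = dendropy.Node()
        node_of[parent].add_child(nd)
        node_of[cl] = nd
        parents.append(cl)
    for t in taxa:
        containing = [c for c in parents if t in c]
        parent = min(containing, key=len)
        leaf = dendropy.Node(taxon=tns.require_taxon(t))
        node_of[parent].add_child(leaf)
    return tree


def annotate_supports(tree: PhyloTree) -> dict[frozenset, float]:
    """Branch support values keyed by bipartition (for reports)."""
    out = {}
    for nd, side, other in _split_sides(tree):
        val = getattr(nd, "bootstrap_support",
                      getattr(nd, "quartet_support", None))
        if val is not None:
            out[frozenset([side, other])] = val
    return out
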