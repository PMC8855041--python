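"""Gene and site concordance factors, score classification, and
clade-recovery tables.

gCF of a reference branch is the percentage of decisive gene trees
(those with at least two taxa on each side of the branch) that contain
the branch's restricted bipartition.  sCF samples quartets around the
branch (one taxon from each of the four adjacent subtrees) and averages,
over quartets with at least one decisive site, the fraction of decisive
alignment sites supporting the branch's pairing; its noise floor is
~33% because a quartet has three resolutions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import (
    MISSING_CODE,
    MultipleAlignment,
    PhyloTree,
    TreeCollection,
    bipartitions,
    leaf_labels,
)
from .species_tree import _split_sides

__all__ = [
    "BranchConcordance",
    "CladeDefinition",
    "gcf",
    "scf",
    "concordant_count",
    "classify_scores",
    "clade_recovery",
    "cf_heatmap_table",
    "read_clades_csv",
    "plot_cf_heatmap",
]


def concordant_count(gcf_pct: float, decisive: int) -> int:
    """Number of concordant gene trees implied by a gCF percentage.

    Inverts ``gCF = 100 * concordant / decisive`` and rounds to the
    nearest whole tree — e.g. a branch with gCF 37.4% over 306 decisive
    gene trees corresponds to 114 concordant single-locus trees.
    """
    if not (0.0 <= gcf_pct <= 100.0):
        raise ValueError("gCF percentage outside [0, 100]")
    if decisive < 0:
        raise ValueError("decisive count must be nonnegative")
    return int(round(gcf_pct / 100.0 * decisive))


@dataclass
class BranchConcordance:
    """Concordance bookkeeping for one reference branch."""

    split: frozenset           # frozenset of the two leaf-label sides
    decisive: int = 0
    concordant: int = 0
    n_quartets: int = 0
    quartet_decisive_sites: list[int] = field(default_factory=list)
    gcf_pct: float | None = None
    scf_pct: float | None = None

    def finalize_gcf(self) -> None:
        if self.concordant > self.decisive:
            raise ValueError("concordant exceeds decisive")
        self.gcf_pct = (100.0 * self.concordant / self.decisive
                        if self.decisive > 0 else None)


@dataclass(frozen=True)
class CladeDefinition:
    """A named set of tips whose monophyly is tracked across trees."""

    name: str
    tips: frozenset

    def __post_init__(self) -> None:
        if len(self.tips) < 2:
            raise ValueError(f"clade {self.name!r} needs at least 2 tips")


def read_clades_csv(path: str) -> list[CladeDefinition]:
    """CSV with columns ``name, tips`` (tips comma-separated)."""
    df = pd.read_csv(path)
    clades = [
        CladeDefinition(row["name"],
                        frozenset(t.strip() for t in
                                  str(row["tips"]).split(",")))
        for _, row in df.iterrows()
    ]
    names = [c.name for c in clades]
    if len(set(names)) != len(names):
        raise ValueError("duplicate clade names")
    return clades


# ---------------------------------------------------------------------------
# gene concordance factor


def gcf(reference: PhyloTree,
        gene_trees: list[PhyloTree]) -> list[BranchConcordance]:
    """Gene concordance factor for every internal branch of ``reference``.

    A gene tree is decisive for branch A|B when its leaf set has >= 2
    taxa on each restricted side, and concordant when it contains the
    restricted bipartition A'|B' exactly.
    """
    if not gene_trees:
        raise ValueError("no gene trees")
    gene_splits = [(leaf_labels(g), bipartitions(g)) for g in gene_trees]
    out = []
    for _nd, side, other in _split_sides(reference):
        bc = BranchConcordance(split=frozenset([side, other]))
        for gl, gs in gene_splits:
            a = side & gl
            b = other & gl
            if len(a) < 2 or len(b) < 2:
                continue
            bc.decisive += 1
            if frozenset([a, b]) in gs:
                bc.concordant += 1
        bc.finalize_gcf()
        out.append(bc)
    return out


# ---------------------------------------------------------------------------
# site concordance factor


def _branch_quartet_groups(reference: PhyloTree):
    """For each internal branch: (node, split, four adjacent tip groups).

    For a binary reference the four groups are the leaf sets of the two
    subtrees on each side of the branch.  At multifurcations a side with
    more than two subtrees contributes its two first groups merged so
    that exactly two groups per side remain; a side that cannot be split
    into two non-empty groups yields ``None`` (branch skipped with NA).
    """
    below = {}
    for nd in reference.postorder_node_iter():
        below[nd] = frozenset([nd.taxon.label]) if nd.is_leaf() else \
            frozenset().union(*(below[c] for c in nd.child_nodes()))
    all_leaves = below[reference.seed_node]

    def side_groups(groups: list[frozenset]) -> tuple | None:
        groups = [g for g in groups if g]
        if len(groups) < 2:
            return None
        if len(groups) == 2:
            return groups[0], groups[1]
        return groups[0], frozenset().union(*groups[1:])

    for nd, side, other in _split_sides(reference):
        lower = [below[c] for c in nd.child_nodes()]
        g12 = side_groups(lower)
        # upper side: sibling subtrees plus everything above the parent
        parent = nd.parent_node
        sib_nodes = [c for c in parent.child_nodes() if c is not nd]
        groups_up = [below[c] for c in sib_nodes]
        rest = all_leaves - side - frozenset().union(*groups_up)
        if rest:
            groups_up.append(rest)
        elif len(groups_up) == 1:
            # branch hangs off a two-child root: decompose the sibling
            sib = sib_nodes[0]
            if not sib.is_leaf():
                groups_up = [below[c] for c in sib.child_nodes()]
        g34 = side_groups(groups_up)
        yield nd, frozenset([side, other]), g12, g34


def scf(reference: PhyloTree, supermatrix: MultipleAlignment,
        q: int = 100, seed: int = 0) -> list[BranchConcordance]:
    """Site concordance factor with ``q`` sampled quartets per branch.

    Per quartet (one taxon from each adjacent group), a site is decisive
    when all four taxa are called and it supports exactly one of the
    three pairings; the quartet's concordance is the fraction of its
    decisive sites supporting the reference pairing.  sCF is 100 x the
    mean over quartets with >= 1 decisive site; when fewer than ``q``
    distinct quartets exist they are enumerated exhaustively.  Branches
    with an empty adjacent group are reported with ``scf_pct = None``.
    """
    if q < 1:
        raise ValueError("q must be positive")
    missing = leaf_labels(reference) - set(supermatrix.taxa)
    if missing:
        raise KeyError(f"reference leaves not in alignment: {sorted(missing)}")
    codes = supermatrix.codes()
    row = {t: i for i, t in enumerate(supermatrix.taxa)}
    rng = np.random.default_rng(seed)
    out = []
    for _nd, split, g12, g34 in _branch_quartet_groups(reference):
        bc = BranchConcordance(split=split)
        if g12 is None or g34 is None:
            out.append(bc)
            continue
        groups = [sorted(g) for g in (g12[0], g12[1], g34[0], g34[1])]
        n_distinct = int(np.prod([len(g) for g in groups]))
        if n_distinct <= q:
            quartets = list(itertools.product(*groups))
        else:
            quartets = [
                tuple(g[rng.integers(len(g))] for g in groups)
                for _ in range(q)
            ]
        cf_vals = []
        for (a, a2, b, b2) in quartets:
            sa, sa2 = codes[row[a]], codes[row[a2]]
            sb, sb2 = codes[row[b]], codes[row[b2]]
            called = ((sa != MISSING_CODE) & (sa2 != MISSING_CODE)
                      & (sb != MISSING_CODE) & (sb2 != MISSING_CODE))
            conc = called & (sa == sa2) & (sb == sb2) & (sa != sb)
            d2 = called & (sa == sb) & (sa2 == sb2) & (sa != sa2)
            d3 = called & (sa == sb2) & (sa2 == sb) & (sa != sa2)
            decisive = int(conc.sum() + d2.sum() + d3.sum())
            bc.n_quartets += 1
            bc.quartet_decisive_sites.append(decisive)
            if decisive > 0:
                cf_vals.append(conc.sum() / decisive)
        bc.scf_pct = 100.0 * float(np.mean(cf_vals)) if cf_vals else None
        out.append(bc)
    return out


# ---------------------------------------------------------------------------
# classification and clade recovery


_BANDS = {
    "gcf": (30.0, 80.0, 0.0, 100.0),
    "support_pp": (0.75, 0.9, 0.0, 1.0),
    "support_bs": (75.0, 90.0, 0.0, 100.0),
}


def classify_scores(value: float, kind: str) -> str:
    """Classify a concordance factor or support value.

    gCF: low < 30 <= moderate < 80 <= high.  Posterior-probability
    support: high >= 0.9, low < 0.75.  Bootstrap support: high >= 90,
    low < 75.
    """
    if kind not in _BANDS:
        raise ValueError(f"unknown kind {kind!r}")
    lo, hi, vmin, vmax = _BANDS[kind]
    if not (vmin <= value <= vmax):
        raise ValueError(f"{kind} value {value} outside [{vmin}, {vmax}]")
    if value < lo:
        return "low"
    if value < hi:
        return "moderate"
    return "high"


def _splits_compatible(split_a: frozenset, splits) -> bool:
    a1, b1 = tuple(split_a)
    for s in splits:
        a2, b2 = tuple(s)
        if not any(not (x & y) for x in (a1, b1) for y in (a2, b2)):
            return False
    return True


def clade_recovery(trees: TreeCollection,
                   clades: list[CladeDefinition]) -> pd.DataFrame:
    """Clade x tree matrix of {recovered, not_recovered, NA}.

    A clade is recovered when its tips present in the tree form a
    bipartition side; NA when fewer than two tips are present or the
    clade's split is compatible with the tree but unresolved.
    """
    rows = {}
    for clade in clades:
        row = {}
        for (dataset, method), tree in trees:
            leaves = leaf_labels(tree)
            present = clade.tips & leaves
            rest = leaves - present
            if len(present) < 2 or not rest:
                row[(dataset, method)] = "NA"
                continue
            split = frozenset([present, rest])
            splits = bipartitions(tree)
            if split in splits:
                row[(dataset, method)] = "recovered"
            elif _splits_compatible(split, splits):
                row[(dataset, method)] = "NA"  # unresolved, no conflict
            else:
                row[(dataset, method)] = "not_recovered"
        rows[clade.name] = row
    df = pd.DataFrame(rows).T
    df.columns = pd.MultiIndex.from_tuples(df.columns,
                                           names=["dataset", "method"])
    return df


def cf_heatmap_table(trees: TreeCollection,
                     clades: list[CladeDefinition],
                     gene_trees_by_dataset: dict[str, list[PhyloTree]],
                     supermatrices_by_dataset: dict[str, MultipleAlignment],
                     q: int = 100, seed: int = 0) -> pd.DataFrame:
    """Long-format (clade, dataset, method, gCF, sCF, recovery) table.

    CF values are evaluated at each clade's branch in each species tree,
    using the tree's own dataset's gene trees (gCF) and supermatrix
    (sCF); cells where the clade is absent or unresolved propagate NA.
    """
    recovery = clade_recovery(trees, clades)
    gcf_cache: dict = {}
    scf_cache: dict = {}
    rows = []
    for (dataset, method), tree in trees:
        key = (dataset, method)
        if key not in gcf_cache:
            gts = gene_trees_by_dataset.get(dataset)
            gcf_cache[key] = {
                bc.split: bc for bc in gcf(tree, gts)
            } if gts else {}
            sm = supermatrices_by_dataset.get(dataset)
            scf_cache[key] = {
                bc.split: bc for bc in scf(tree, sm, q=q, seed=seed)
            } if sm is not None else {}
        leaves = leaf_labels(tree)
        for clade in clades:
            present = clade.tips & leaves
            rest = leaves - present
            rec = recovery.loc[clade.name, key]
            g = s = np.nan
            if rec == "recovered":
                split = frozenset([present, rest])
                bc_g = gcf_cache[key].get(split)
                bc_s = scf_cache[key].get(split)
                if bc_g is not None and bc_g.gcf_pct is not None:
                    g = bc_g.gcf_pct
                if bc_s is not None and bc_s.scf_pct is not None:
                    s = bc_s.scf_pct
            rows.append((clade.name, dataset, method, g, s, rec))
    return pd.DataFrame(
        rows, columns=["clade", "dataset", "method", "gCF", "sCF",
                       "recovery"])


def plot_cf_heatmap(table: pd.DataFrame, value: str, path: str) -> None:
    """Render one CF column of the long table as a clade x tree heatmap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    wide = table.pivot_table(index="clade",
                             columns=["dataset", "method"],
                             values=value, dropna=False)
    fig, ax = plt.subplots(
        figsize=(1 + 0.45 * wide.shape[1], 1 + 0.4 * wide.shape[0]))
    sns.heatmap(wide, annot=True, fmt=".0f", cmap="viridis",
                vmin=0, vmax=100, ax=ax,
                cbar_kws={"label": f"{value} (%)"})
    ax.set_title(f"{value} per clade and species tree")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
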