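"""Synthetic data with the statistical structure of a target-capture
phylogenomic study.

The generator produces a species tree, multispecies-coalescent (MSC)
gene trees with a tunable amount of incomplete lineage sorting (ILS),
and per-locus nucleotide alignments in three locus classes that emulate
a Hyb-Seq design:

* ``CDS``  — exon-like loci: short, slowly evolving, little missing data;
* ``INT``  — intron/flanking loci: long, fast, more missing data;
* ``PL``   — plastid-like loci: one shared genealogy for every locus
  (organellar inheritance), very low variation, heavy missingness.

Class defaults target the study-scale summary statistics of such data:
306/239/44 loci with mean aligned lengths 590/1375/1116 bp, parsimony-
informative fractions near 11.9/26.9/1 %, and missing-data fractions
16.1/34.6/77.5 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import yaml

from .io_core import (
    MultipleAlignment,
    PhyloTree,
    clone_tree,
    to_newick,
    write_alignment,
)

__all__ = [
    "SubstitutionModel",
    "LocusClassConfig",
    "SimulationConfig",
    "LocusSet",
    "JC69",
    "sim_species_tree",
    "scale_internal_branches",
    "sim_gene_trees_msc",
    "sim_alignment",
    "build_study_dataset",
]


# ---------------------------------------------------------------------------
# substitution models


@dataclass(frozen=True)
class SubstitutionModel:
    """JC69 or HKY85, optionally with discrete-Gamma rate heterogeneity.

    The rate matrix is normalized to one expected substitution per site
    per unit branch length.
    """

    name: str = "JC69"
    kappa: float = 1.0
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    gamma_alpha: float | None = None
    gamma_categories: int = 4

    def __post_init__(self) -> None:
        if self.name not in ("JC69", "HKY85"):
            raise ValueError(f"unknown model {self.name}")
        f = np.asarray(self.freqs, float)
        if np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-12:
            raise ValueError("base frequencies must be positive and sum to 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.gamma_alpha is not None and self.gamma_alpha <= 0:
            raise ValueError("gamma shape must be positive")
        if self.name == "JC69":
            object.__setattr__(self, "kappa", 1.0)
            object.__setattr__(self, "freqs", (0.25, 0.25, 0.25, 0.25))

    def rate_matrix(self) -> np.ndarray:
        """Normalized 4x4 generator (order A, C, G, T)."""
        pi = np.asarray(self.freqs, float)
        Q = np.zeros((4, 4))
        # transitions: A<->G (0,2), C<->T (1,3)
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                k = self.kappa if (i, j) in ((0, 2), (2, 0), (1, 3), (3, 1)) \
                    else 1.0
                Q[i, j] = k * pi[j]
        Q[np.diag_indices(4)] = -Q.sum(axis=1)
        mu = -(pi * np.diag(Q)).sum()
        return Q / mu

    def _decomposition(self):
        pi = np.asarray(self.freqs, float)
        Q = self.rate_matrix()
        sq = np.sqrt(pi)
        B = (sq[:, None] * Q) / sq[None, :]
        lam, U = np.linalg.eigh((B + B.T) / 2.0)
        left = U.T * sq[None, :]      # U^T diag(sqrt pi)
        right = (U.T / sq[None, :]).T  # diag(1/sqrt pi) U
        return lam, right, left

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows are parent states, columns child states."""
        if t < 0:
            raise ValueError("negative branch length")
        lam, right, left = self._cached_decomposition()
        P = (right * np.exp(lam * t)[None, :]) @ left
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def _cached_decomposition(self):
        dec = getattr(self, "_dec", None)
        if dec is None:
            dec = self._decomposition()
            object.__setattr__(self, "_dec", dec)
        return dec

    def gamma_rates(self) -> np.ndarray:
        """Mean rates of the discrete-Gamma categories (mean 1)."""
        if self.gamma_alpha is None:
            return np.array([1.0])
        from scipy.stats import gamma as gamma_dist
        a = self.gamma_alpha
        k = self.gamma_categories
        edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a, scale=1.0 / a)
        # mean within each quantile slab
        cdf_inner = gamma_dist.cdf(edges, a + 1, scale=1.0 / a)
        rates = k * np.diff(cdf_inner)
        return rates / rates.mean()


JC69 = SubstitutionModel("JC69")


# ---------------------------------------------------------------------------
# species tree


def sim_species_tree(n_taxa: int, seed: int,
                     labels: list[str] | None = None) -> PhyloTree:
    """Random ultrametric species tree from a Yule (pure-birth) process.

    Branch lengths are in coalescent units; internal branches can be
    rescaled afterwards with :func:`scale_internal_branches` to tune the
    amount of ILS.  Deterministic given ``seed``.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"T{i + 1}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True

    # forward Yule: split a uniformly chosen tip after Exp(k) waiting time
    root = tree.seed_node
    root._birth = 0.0
    tips = []
    t = float(rng.exponential(1.0 / 2.0))
    for _ in range(2):
        c = dendropy.Node()
        c._birth = t
        root.add_child(c)
        tips.append(c)
    while len(tips) < n_taxa:
        k = len(tips)
        t += float(rng.exponential(1.0 / (k + 1)))
        nd = tips.pop(int(rng.integers(k)))
        for _ in range(2):
            c = dendropy.Node()
            c._birth = t
            nd.add_child(c)
            tips.append(c)
    t += float(rng.exponential(1.0 / (len(tips) + 1)))
    order = rng.permutation(n_taxa)
    for i, tip in enumerate(tips):
        tip.taxon = tns.require_taxon(labels[order[i]])
    # node time = its split time (leaves: present day t); edge length =
    # node time - parent split time, which is this node's _birth
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            nd.edge.length = None
            continue
        own_time = t if nd.is_leaf() else nd.child_nodes()[0]._birth
        nd.edge.length = own_time - nd._birth
    for nd in tree.preorder_node_iter():
        if hasattr(nd, "_birth"):
            del nd._birth
    return tree


def scale_internal_branches(tree: PhyloTree, factor: float) -> PhyloTree:
    """Return a copy with internal branch lengths multiplied by ``factor``.

    Shrinking internal branches (factor < 1) raises the amount of ILS the
    coalescent generates without touching tip branches.
    """
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    out = clone_tree(tree)
    for nd in out.preorder_node_iter():
        if nd.parent_node is not None and not nd.is_leaf() \
                and nd.edge.length is not None:
            nd.edge.length *= factor
    return out


# ---------------------------------------------------------------------------
# multispecies coalescent


def _node_ages(tree: PhyloTree) -> dict:
    """Age of every node: 0 at the deepest leaf, increasing toward root."""
    depth = {tree.seed_node: 0.0}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            depth[nd] = depth[nd.parent_node] + (nd.edge.length or 0.0)
    mx = max(depth[l] for l in tree.leaf_node_iter())
    return {nd: mx - d for nd, d in depth.items()}


def _coalesce_interval(lineages, t_start, t_end, rng, nodes_out):
    """Standard coalescent among ``lineages`` over [t_start, t_end)."""
    t = t_start
    while len(lineages) >= 2:
        k = len(lineages)
        w = rng.exponential(2.0 / (k * (k - 1)))
        if t + w >= t_end:
            break
        t += w
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        parent = dendropy.Node()
        parent._age = t
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = t - a._age
        b.edge.length = t - b._age
        nodes_out.append(parent)
        lineages = [l for m, l in enumerate(lineages) if m not in (i, j)]
        lineages.append(parent)
    return lineages, t


def sim_gene_trees_msc(species_tree: PhyloTree, n_loci: int,
                       ils_scale: float = 1.0, linked_flag: bool = False,
                       seed: int = 0) -> list[PhyloTree]:
    """Gene trees under the multispecies coalescent.

    One sampled lineage per species; within each species-tree branch of
    length ``t`` coalescent units, lineage pairs coalesce at rate 1 per
    pair; surviving lineages enter the parent branch.  ``ils_scale``
    multiplies internal species-tree branches before simulation (smaller
    values mean more discordance).  With ``linked_flag`` all loci share
    one drawn genealogy, emulating an organellar genome.  Deterministic
    given ``seed``.
    """
    if not species_tree.is_rooted:
        raise ValueError("species tree must be rooted")
    if n_loci < 1:
        raise ValueError("n_loci must be positive")
    sp = scale_internal_branches(species_tree, ils_scale) \
        if ils_scale != 1.0 else species_tree
    ages = _node_ages(sp)
    rng = np.random.default_rng(seed)

    def one_draw() -> PhyloTree:
        tns = dendropy.TaxonNamespace()
        gene = dendropy.Tree(taxon_namespace=tns)
        gene.is_rooted = True
        pool: dict = {}
        for nd in sp.postorder_node_iter():
            if nd.is_leaf():
                tip = dendropy.Node(
                    taxon=tns.require_taxon(nd.taxon.label))
                tip._age = ages[nd]
                pool[nd] = [tip]
            else:
                lineages = []
                for c in nd.child_nodes():
                    lineages.extend(pool.pop(c))
                if nd.parent_node is None:
                    t = ages[nd]
                    while len(lineages) > 1:
                        lineages, t = _coalesce_interval(
                            lineages, t, np.inf, rng, [])
                    pool[nd] = lineages
                else:
                    lineages, _ = _coalesce_interval(
                        lineages, ages[nd], ages[nd.parent_node], rng, [])
                    pool[nd] = lineages
        root = pool[sp.seed_node][0]
        gene.seed_node = root
        root.edge.length = None
        return gene

    if linked_flag:
        g = one_draw()
        return [clone_tree(g) for _ in range(n_loci)]
    return [one_draw() for _ in range(n_loci)]


# ---------------------------------------------------------------------------
# sequence simulation


def sim_alignment(gene_tree: PhyloTree, length: int,
                  model: SubstitutionModel = JC69, rate: float = 1.0,
                  missing_fraction: float = 0.0, seed: int = 0,
                  locus_id: str = "locus", class_tag: str = "CDS",
                  ) -> MultipleAlignment:
    """Evolve i.i.d. sites along a gene tree, then inject missing data.

    Branch lengths are multiplied by ``rate`` to convert coalescent units
    to substitutions per site.  Missingness is injected as whole-taxon
    dropout first (failed capture), then random cells, until the realized
    fraction matches the target to within rounding.  Deterministic given
    ``seed``.
    """
    if not (0.0 <= missing_fraction < 1.0):
        raise ValueError("missing_fraction must be in [0, 1)")
    if length < 1:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    pi = np.asarray(model.freqs, float)
    site_rates = model.gamma_rates()
    cat = rng.integers(len(site_rates), size=length) \
        if len(site_rates) > 1 else np.zeros(length, dtype=int)

    states: dict = {}
    order = list(gene_tree.preorder_node_iter())
    states[order[0]] = rng.choice(4, size=length, p=pi)
    for nd in order[1:]:
        parent = states[nd.parent_node]
        t = (nd.edge.length or 0.0) * rate
        child = np.empty(length, dtype=np.int64)
        for ci, r in enumerate(site_rates):
            mask_c = cat == ci
            if not mask_c.any():
                continue
            P = model.transition_matrix(t * r)
            sub = parent[mask_c]
            out = np.empty(sub.shape, dtype=np.int64)
            u = rng.random(sub.shape)
            cum = np.cumsum(P, axis=1)
            out = (u[:, None] > cum[sub]).sum(axis=1)
            child[mask_c] = out
        states[nd] = child

    leaves = [l for l in gene_tree.leaf_node_iter()]
    taxa = [l.taxon.label for l in leaves]
    alphabet = np.array([b"A", b"C", b"G", b"T"])
    mat = np.stack([alphabet[states[l]] for l in leaves])

    n_taxa = len(taxa)
    n_cells = n_taxa * length
    target = int(round(missing_fraction * n_cells))
    if target > 0:
        max_drop = max(0, n_taxa - 3)
        n_drop = min(int(0.5 * target / length), max_drop)
        dropped = rng.choice(n_taxa, size=n_drop, replace=False) \
            if n_drop else np.array([], dtype=int)
        mat[dropped] = b"-"
        residual = target - n_drop * length
        keep_rows = np.setdiff1d(np.arange(n_taxa), dropped)
        avail = keep_rows.size * length
        residual = min(residual, avail - 2 * keep_rows.size)  # keep signal
        if residual > 0:
            flat = rng.choice(avail, size=residual, replace=False)
            r, c = np.divmod(flat, length)
            mat[keep_rows[r], c] = b"N"
    return MultipleAlignment(locus_id, class_tag, taxa, mat)


# ---------------------------------------------------------------------------
# study-shaped dataset


@dataclass
class LocusClassConfig:
    """Per-class locus generation targets."""

    n_loci: int
    length_min: int
    length_max: int
    length_mean: float
    rate: float                    # substitutions/site per coalescent unit
    missing_fraction: float
    linked: bool = False
    ils_multiplier: float = 1.0    # extra internal-branch scaling per class


def _default_classes(full_scale: bool) -> dict[str, LocusClassConfig]:
    # emulation targets: locus counts, length spread, PIS% and missing%
    # of the three locus classes of a Hyb-Seq study (exons / introns /
    # off-target plastid loci).  Rates calibrated once against the PIS
    # targets 11.9 / 26.9 / 1 % on the default species tree.
    cds = LocusClassConfig(
        n_loci=306 if full_scale else 30,
        length_min=59, length_max=2713, length_mean=590.0,
        rate=0.0047, missing_fraction=0.161)
    intron = LocusClassConfig(
        n_loci=239 if full_scale else 24,
        length_min=243, length_max=47434 if full_scale else 4000,
        length_mean=1375.0,
        rate=0.0136, missing_fraction=0.346)
    plastid = LocusClassConfig(
        n_loci=44 if full_scale else 8,
        length_min=183, length_max=5613, length_mean=1116.0,
        rate=0.00125, missing_fraction=0.775,
        linked=True, ils_multiplier=0.25)
    return {"CDS": cds, "INT": intron, "PL": plastid}


@dataclass
class SimulationConfig:
    """Everything that defines one synthetic study.

    ``ils_scale`` multiplies the internal branches of the species tree
    (coalescent units); values below 1 increase gene-tree discordance.
    ``full_scale`` switches between the study-scale locus counts
    (306/239/44) and a small desk-scale default (30/24/8).
    """

    n_taxa: int = 8
    seed: int = 0
    ils_scale: float = 1.0
    full_scale: bool = False
    model: SubstitutionModel = field(default_factory=lambda: JC69)
    classes: dict[str, LocusClassConfig] | None = None
    #: optional fixed species tree (rooted Newick, coalescent-unit
    #: lengths); replaces the random Yule tree when set
    species_newick: str | None = None

    def __post_init__(self) -> None:
        if self.classes is None:
            self.classes = _default_classes(self.full_scale)
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        if self.ils_scale <= 0:
            raise ValueError("ils_scale must be positive")
        for tag, c in self.classes.items():
            if c.n_loci < 1:
                raise ValueError(f"{tag}: n_loci must be positive")
            if not (0.0 <= c.missing_fraction < 1.0):
                raise ValueError(f"{tag}: missing fraction must be in [0,1)")

    def to_yaml(self) -> str:
        d = {
            "n_taxa": self.n_taxa,
            "seed": self.seed,
            "ils_scale": self.ils_scale,
            "full_scale": self.full_scale,
            "species_newick": self.species_newick,
            "model": {"name": self.model.name, "kappa": self.model.kappa,
                      "freqs": list(self.model.freqs)},
            "classes": {
                tag: {
                    "n_loci": c.n_loci,
                    "length_min": c.length_min,
                    "length_max": c.length_max,
                    "length_mean": c.length_mean,
                    "rate": c.rate,
                    "missing_fraction": c.missing_fraction,
                    "linked": c.linked,
                    "ils_multiplier": c.ils_multiplier,
                }
                for tag, c in self.classes.items()
            },
        }
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        d = yaml.safe_load(text)
        model = SubstitutionModel(
            d.get("model", {}).get("name", "JC69"),
            kappa=d.get("model", {}).get("kappa", 1.0),
            freqs=tuple(d.get("model", {}).get("freqs",
                                               (0.25, 0.25, 0.25, 0.25))))
        classes = None
        if "classes" in d:
            classes = {
                tag: LocusClassConfig(**cc) for tag, cc in d["classes"].items()
            }
        return cls(n_taxa=d.get("n_taxa", 8), seed=d.get("seed", 0),
                   ils_scale=d.get("ils_scale", 1.0),
                   full_scale=d.get("full_scale", False),
                   model=model, classes=classes,
                   species_newick=d.get("species_newick"))


@dataclass
class LocusSet:
    """Simulated (or ingested) loci plus their provenance."""

    loci: list[MultipleAlignment]
    true_species_tree: PhyloTree | None = None
    true_gene_trees: dict[str, PhyloTree] = field(default_factory=dict)

    def by_class(self, class_tag: str) -> list[MultipleAlignment]:
        return [a for a in self.loci if a.class_tag == class_tag]

    def write(self, out_dir: str) -> None:
        """Per-locus FASTA, a partition CSV, and the true tree as Newick."""
        import csv
        import os
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "partitions.csv"), "w",
                  newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["locus_id", "class", "length"])
            for a in self.loci:
                write_alignment(a, os.path.join(out_dir, a.locus_id + ".fasta"))
                w.writerow([a.locus_id, a.class_tag, a.n_sites])
        if self.true_species_tree is not None:
            with open(os.path.join(out_dir, "true_species_tree.nwk"),
                      "w") as fh:
                fh.write(to_newick(self.true_species_tree) + "\n")


def _draw_lengths(c: LocusClassConfig, n: int, rng) -> np.ndarray:
    sigma = 0.55
    mu = np.log(c.length_mean) - sigma ** 2 / 2.0
    lens = np.exp(rng.normal(mu, sigma, size=n))
    return np.clip(np.round(lens), c.length_min, c.length_max).astype(int)


def build_study_dataset(config: SimulationConfig
                        ) -> tuple[LocusSet, PhyloTree]:
    """Simulate the full three-class locus set plus its species tree.

    The returned species tree is the generating truth, usable for
    parameter-recovery checks.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    if config.species_newick is not None:
        from .io_core import parse_newick
        species = parse_newick(config.species_newick, rooted=True)
        rng.integers(2 ** 31)  # keep the seed stream aligned
    else:
        species = sim_species_tree(config.n_taxa,
                                   seed=int(rng.integers(2 ** 31)))
    loci: list[MultipleAlignment] = []
    gene_trees: dict[str, PhyloTree] = {}
    for tag in sorted(config.classes):
        c = config.classes[tag]
        gts = sim_gene_trees_msc(
            species, c.n_loci,
            ils_scale=config.ils_scale * c.ils_multiplier,
            linked_flag=c.linked,
            seed=int(rng.integers(2 ** 31)))
        lens = _draw_lengths(c, c.n_loci, rng)
        for i, (gt, L) in enumerate(zip(gts, lens)):
            lid = f"{tag}_{i + 1:04d}"
            aln = sim_alignment(
                gt, int(L), model=config.model, rate=c.rate,
                missing_fraction=c.missing_fraction,
                seed=int(rng.integers(2 ** 31)),
                locus_id=lid, class_tag=tag)
            loci.append(aln)
            gene_trees[lid] = gt
    return LocusSet(loci, species, gene_trees), species
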