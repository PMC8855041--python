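"""End-to-end protocol: simulate (or ingest) a three-class locus set,
run locus QC, infer gene trees, build the 4-dataset x 5-method grid of
species trees, analyze the tree landscape, run topology tests against
the fixed concatenated reference, and tabulate concordance factors.

Datasets mirror a target-capture design: ``ncCDS`` (exon-like loci),
``ncINT`` (intron-like), ``ncGD`` (their union), and ``plCDS``
(linked plastid-like loci).  Methods per dataset: concatenated
partitioned (``Cpa``) and unpartitioned (``Cun``) trees with 100
site-bootstrap replicates, the quartet-support MSC tree (``As``), and
MSC trees with gene+site (``Abs``) and fast site-only (``AUFbs``)
bootstraps — 20 species trees in total.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .concordance import CladeDefinition, cf_heatmap_table, clade_recovery
from .io_core import (
    MultipleAlignment,
    PhyloTree,
    TreeCollection,
    harmonize_trees,
    leaf_labels,
    to_newick,
    write_trees,
)
from .locus_qc import SummaryTable, filter_loci_symtest, summarize_dataset, \
    trim_gapped_columns
from .phylo_engine import nj_gene_tree
from .simulate import JC69, LocusSet, SimulationConfig, build_study_dataset
from .species_tree import build_supermatrix, concatenated_tree, \
    msc_bootstrap, msc_tree
from .topology_tests import TestConfig, TopologyTestReport, compare_to_fixed
from .tree_landscape import Ordination, TreeDistanceMatrix, find_groves, \
    kc_distance_matrix, pcoa, rf_distance_matrix

__all__ = ["ProtocolRun", "run_protocol", "write_report"]

logger = logging.getLogger("phyloconcord")

DATASET_CLASSES = {"ncCDS": ("CDS",), "ncINT": ("INT",),
                   "ncGD": ("CDS", "INT"), "plCDS": ("PL",)}
METHOD_ORDER = ("Cpa", "Cun", "As", "Abs", "AUFbs")


@dataclass
class ProtocolRun:
    """Everything one protocol execution produced."""

    config: SimulationConfig
    seed: int
    trees: TreeCollection
    harmonized: TreeCollection
    summaries: dict[str, SummaryTable]
    qc_reports: dict[str, pd.DataFrame]
    rf: TreeDistanceMatrix
    kc: TreeDistanceMatrix
    rf_ordination: Ordination
    kc_ordination: Ordination
    topology_report: TopologyTestReport
    cf_table: pd.DataFrame
    clades: list[CladeDefinition]
    locus_set: LocusSet
    gene_trees: dict[str, list[PhyloTree]]
    supermatrices: dict[str, MultipleAlignment]
    provenance: list[str] = field(default_factory=list)


def _auto_clades(tree: PhyloTree, max_clades: int = 14
                 ) -> list[CladeDefinition]:
    """Track the internal clades of the generating species tree
    (largest first), the synthetic analog of a recurrent-clade list."""
    from .io_core import rooted_clades
    leaves = leaf_labels(tree)
    clades = sorted(
        (c for c in rooted_clades(tree) if 2 <= len(c) < len(leaves)),
        key=lambda c: (-len(c), sorted(c)))
    return [CladeDefinition(f"C{i + 1}", c)
            for i, c in enumerate(clades[:max_clades])]


def run_protocol(config: SimulationConfig | LocusSet,
                 cfg: TestConfig | None = None,
                 clades: list[CladeDefinition] | None = None,
                 seed: int = 0,
                 out_dir: str | None = None,
                 gt: float = 0.2, symtest_alpha: float = 0.05,
                 aufbs_replicates: int | None = None,
                 abs_replicates: int = 100,
                 scf_quartets: int = 100,
                 rf_groups: int = 2, kc_groups: int = 3,
                 drop: tuple[str, ...] = (),
                 root_on: str | None = None) -> ProtocolRun:
    """Run the whole protocol; returns the collected results.

    ``config`` is either a :class:`SimulationConfig` (data simulated) or
    an existing :class:`LocusSet` (data ingested).  ``aufbs_replicates``
    defaults to 1,000 at full scale and 200 at desk scale.
    """
    cfg = cfg or TestConfig(seed=seed)
    rng = np.random.default_rng(seed)
    prov: list[str] = []

    def log(stage: str, msg: str) -> None:
        logger.info("[%s] %s", stage, msg)
        prov.append(f"[{stage}] {msg}")

    # ----- data ------------------------------------------------------
    if isinstance(config, SimulationConfig):
        log("simulate", f"building study dataset (seed={config.seed})")
        locus_set, species_tree = build_study_dataset(config)
        sim_config = config
    else:
        locus_set = config
        species_tree = locus_set.true_species_tree
        sim_config = SimulationConfig()
        log("ingest", f"{len(locus_set.loci)} loci ingested")
    if aufbs_replicates is None:
        aufbs_replicates = 1000 if getattr(sim_config, "full_scale",
                                           False) else 200

    # ----- QC --------------------------------------------------------
    qc_reports: dict[str, pd.DataFrame] = {}
    kept_by_class: dict[str, list[MultipleAlignment]] = {}
    for tag in ("CDS", "INT", "PL"):
        class_loci = locus_set.by_class(tag)
        if not class_loci:
            continue
        trimmed = [trim_gapped_columns(a, gt=gt) for a in class_loci]
        kept, removed, report = filter_loci_symtest(
            trimmed, alpha=symtest_alpha)
        qc_reports[tag] = report
        kept_by_class[tag] = kept
        log("qc", f"{tag}: {len(kept)} kept, {len(removed)} removed "
                  f"(symmetry test, alpha={symtest_alpha})")

    dataset_loci = {
        ds: [a for t in tags for a in kept_by_class.get(t, [])]
        for ds, tags in DATASET_CLASSES.items()
    }
    dataset_loci = {ds: loci for ds, loci in dataset_loci.items() if loci}
    summaries = {ds: summarize_dataset(loci, dataset=ds)
                 for ds, loci in dataset_loci.items()}

    # ----- gene trees ------------------------------------------------
    gene_trees: dict[str, list[PhyloTree]] = {}
    for ds, loci in dataset_loci.items():
        gts = [nj_gene_tree(a) for a in loci]
        gene_trees[ds] = [g for g in gts if g is not None]
        log("genetrees", f"{ds}: {len(gene_trees[ds])}/{len(loci)} "
                         "informative gene trees")

    # ----- species trees ---------------------------------------------
    collection = TreeCollection()
    supermatrices: dict[str, MultipleAlignment] = {}
    for ds, loci in dataset_loci.items():
        sm, _ = build_supermatrix(loci, dataset=ds)
        supermatrices[ds] = sm
        for method in METHOD_ORDER:
            mseed = int(rng.integers(2 ** 31))
            if method in ("Cpa", "Cun"):
                tree, _info = concatenated_tree(
                    loci, partitioned=(method == "Cpa"),
                    bootstrap_replicates=100, seed=mseed, dataset=ds)
            elif method == "As":
                tree = msc_tree(gene_trees[ds])
            else:
                flavor = "gene_site" if method == "Abs" else "site_only"
                reps = abs_replicates if method == "Abs" \
                    else aufbs_replicates
                tree, _cons, _ = msc_bootstrap(
                    loci, gene_trees[ds], replicates=reps,
                    flavor=flavor, seed=mseed)
            collection.add(ds, method, tree)
            log("speciestree", f"{ds}/{method} done")

    # ----- harmonization ---------------------------------------------
    keys = list(collection.keys())
    trees = collection.trees()
    union = set().union(*(leaf_labels(t) for t in trees))
    common = set.intersection(*(set(leaf_labels(t)) for t in trees))
    auto_drop = (union - common) | set(drop)
    if root_on is None:
        root_on = sorted(common - auto_drop)[0]
    harmonized_trees = harmonize_trees(trees, drop=auto_drop,
                                       root_on=root_on)
    harmonized = TreeCollection()
    for key, t in zip(keys, harmonized_trees):
        harmonized.add(*key, t)
    log("harmonize", f"dropped {sorted(auto_drop)}; rooted on {root_on}")

    # ----- landscape --------------------------------------------------
    ids = [f"{ds}_{m}" for ds, m in keys]
    rf = rf_distance_matrix(harmonized_trees, ids)
    kc = kc_distance_matrix(harmonized_trees, ids, lam=0.0)
    rf_ord = pcoa(rf, k=3)
    kc_ord = pcoa(kc, k=3)
    find_groves(rf_ord, n_axes=3, k_groups=min(rf_groups, len(ids)))
    find_groves(kc_ord, n_axes=3, k_groups=min(kc_groups, len(ids)))
    log("landscape", "RF and KC ordinations with groves computed")

    # ----- topology tests ---------------------------------------------
    fixed = harmonized.get("ncCDS", "Cpa")
    eval_sm = supermatrices["ncCDS"]
    report = compare_to_fixed(fixed, harmonized, eval_sm, cfg)
    log("toptest", "SH/AU tests against the fixed ncCDS Cpa tree done")

    # ----- concordance -------------------------------------------------
    if clades is None:
        ref = species_tree if species_tree is not None \
            else harmonized.get("ncCDS", "Cpa")
        clades = _auto_clades(ref)
    cf = cf_heatmap_table(harmonized, clades, gene_trees, supermatrices,
                          q=scf_quartets, seed=int(rng.integers(2 ** 31)))
    log("concord", f"CF table over {len(clades)} clades done")

    run = ProtocolRun(
        config=sim_config, seed=seed, trees=collection,
        harmonized=harmonized, summaries=summaries,
        qc_reports=qc_reports, rf=rf, kc=kc,
        rf_ordination=rf_ord, kc_ordination=kc_ord,
        topology_report=report, cf_table=cf, clades=clades,
        locus_set=locus_set, gene_trees=gene_trees,
        supermatrices=supermatrices, provenance=prov,
    )
    if out_dir is not None:
        write_report(run, out_dir)
    return run


def write_report(run: ProtocolRun, out_dir: str,
                 figures: bool = True) -> str:
    """Write all artifacts (trees, CSVs, figures) plus a markdown report.

    Returns the report path.  Every numeric table in the report is also
    written as its own CSV next to it.
    """
    os.makedirs(out_dir, exist_ok=True)

    tree_path = os.path.join(out_dir, "species_trees.nwk")
    with open(tree_path, "w") as fh:
        for (ds, m), t in run.trees:
            fh.write(f"{to_newick(t)}\n")
    with open(os.path.join(out_dir, "species_tree_keys.txt"), "w") as fh:
        for (ds, m), _ in run.trees:
            fh.write(f"{ds}\t{m}\n")
    write_trees(run.harmonized.trees(),
                os.path.join(out_dir, "species_trees_harmonized.nwk"))

    summary = pd.concat([s.table for s in run.summaries.values()])
    summary.to_csv(os.path.join(out_dir, "summary_table.csv"), index=False)
    for tag, rep in run.qc_reports.items():
        rep.to_csv(os.path.join(out_dir, f"qc_symtest_{tag}.csv"),
                   index=False)
    run.rf.to_csv(os.path.join(out_dir, "rf_distances.csv"))
    run.kc.to_csv(os.path.join(out_dir, "kc_distances.csv"))
    run.topology_report.to_csv(os.path.join(out_dir, "topology_tests.csv"))
    run.cf_table.to_csv(os.path.join(out_dir, "concordance_factors.csv"),
                        index=False)
    groves = pd.DataFrame({
        "tree": run.rf_ordination.tree_ids,
        "rf_grove": run.rf_ordination.grove_labels,
        "kc_grove": run.kc_ordination.grove_labels,
    })
    groves.to_csv(os.path.join(out_dir, "groves.csv"), index=False)
    with open(os.path.join(out_dir, "run_config.yaml"), "w") as fh:
        fh.write(run.config.to_yaml())
    with open(os.path.join(out_dir, "provenance.log"), "w") as fh:
        fh.write("\n".join(run.provenance) + "\n")

    if figures:
        from .concordance import plot_cf_heatmap
        from .tree_landscape import plot_landscape
        plot_landscape(run.rf_ordination,
                       os.path.join(out_dir, "landscape_rf.png"),
                       title="RF landscape (unrooted trees)")
        plot_landscape(run.kc_ordination,
                       os.path.join(out_dir, "landscape_kc.png"),
                       title="KC landscape (rooted trees)")
        plot_cf_heatmap(run.cf_table, "gCF",
                        os.path.join(out_dir, "heatmap_gcf.png"))
        plot_cf_heatmap(run.cf_table, "sCF",
                        os.path.join(out_dir, "heatmap_scf.png"))

    report_path = os.path.join(out_dir, "report.md")
    lines = [
        "# Protocol run report",
        "",
        f"Run seed: {run.seed}",
        f"Species trees: {len(run.trees)} "
        f"({len(run.summaries)} datasets x {len(METHOD_ORDER)} methods)",
        "",
        "## Dataset summary (`summary_table.csv`)",
        "",
        summary.to_markdown(index=False),
        "",
        "## Topology tests (`topology_tests.csv`)",
        "",
        run.topology_report.table.to_markdown(index=False),
        "",
        "## Groves (`groves.csv`)",
        "",
        groves.to_markdown(index=False),
        "",
        "## Concordance factors (`concordance_factors.csv`)",
        "",
        run.cf_table.to_markdown(index=False),
        "",
    ]
    with open(report_path, "w") as fh:
        fh.write("\n".join(lines))
    return report_path
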