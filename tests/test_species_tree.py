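import numpy as np
import pytest

from phyloconcord.io_core import (
    bipartitions,
    leaf_labels,
    parse_newick,
)
from phyloconcord.phylo_engine import ml_distance_matrix, nj_gene_tree, \
    nj_tree
from phyloconcord.simulate import (
    LocusClassConfig,
    SimulationConfig,
    build_study_dataset,
    scale_internal_branches,
    sim_alignment,
    sim_gene_trees_msc,
    sim_species_tree,
)
from phyloconcord.species_tree import (
    MethodSpec,
    _adj_to_dendropy,
    _enumerate_adjacencies,
    concatenated_tree,
    msc_bootstrap,
    msc_tree,
    quartet_score,
)


def mild_ils_tree(n_taxa, seed, min_internal=1.0):
    sp = sim_species_tree(n_taxa, seed=seed)
    mn = min(nd.edge.length for nd in sp.preorder_node_iter()
             if nd.parent_node and not nd.is_leaf())
    return scale_internal_branches(sp, min_internal / mn)


class TestMethodSpec:
    def test_default_replicates(self):
        assert MethodSpec("Abs").replicates == 100
        assert MethodSpec("AUFbs").replicates == 1000

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            MethodSpec("XX")


class TestQuartetScore:
    def test_single_quartet_counting(self):
        sp = parse_newick("((A,B),(C,D));")
        gts = [parse_newick("((A,B),(C,D));")] * 2 + \
            [parse_newick("((A,C),(B,D));")]
        assert quartet_score(sp, gts) == 2

    def test_identical_gene_trees_score_all_quartets(self):
        # with huge internal branches every gene tree matches the
        # species tree, so every quartet agrees: score = n_loci * C(n,4)
        from math import comb
        sp = sim_species_tree(7, seed=1)
        gts = sim_gene_trees_msc(
            scale_internal_branches(sp, 1000.0), 5, seed=2)
        assert quartet_score(sp, gts) == 5 * comb(7, 4)

    def test_star_gene_tree_contributes_zero(self):
        sp = parse_newick("((A,B),(C,D));")
        star = parse_newick("(A,B,C,D);")
        assert quartet_score(sp, [star]) == 0

    def test_equals_brute_force_subtree_extraction(self):
        # oracle: prune each gene tree to every 4-taxon subset with
        # dendropy and compare induced splits explicitly
        import itertools
        from phyloconcord.io_core import clone_tree
        rng = np.random.default_rng(3)
        sp = sim_species_tree(6, seed=4)
        gts = sim_gene_trees_msc(sp, 8, ils_scale=0.3, seed=5)
        taxa = sorted(leaf_labels(sp))
        expected = 0
        for g in gts:
            for four in itertools.combinations(taxa, 4):
                sub_s = clone_tree(sp)
                sub_s.retain_taxa_with_labels(list(four))
                sub_g = clone_tree(g)
                sub_g.retain_taxa_with_labels(list(four))
                bs, bg = bipartitions(sub_s), bipartitions(sub_g)
                if bs and bg and bs == bg:
                    expected += 1
        assert quartet_score(sp, gts) == expected


class TestMSCTree:
    def test_identical_inputs_return_same_topology_full_support(self):
        g = parse_newick("(((A,B),(C,D)),(E,F));")
        est = msc_tree([parse_newick("(((A,B),(C,D)),(E,F));")
                        for _ in range(3)])
        assert bipartitions(est) == bipartitions(g)
        supports = [nd.quartet_support
                    for nd in est.preorder_node_iter()
                    if getattr(nd, "quartet_support", None) is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_exact_mode_is_enumeration_argmax(self):
        sp = sim_species_tree(6, seed=7)
        gts = sim_gene_trees_msc(sp, 12, ils_scale=0.4, seed=8)
        est = msc_tree(gts, mode="exact")
        best = quartet_score(est, gts)
        taxa = sorted(leaf_labels(sp))
        for adj in _enumerate_adjacencies(6):
            t = _adj_to_dendropy(adj, taxa)
            assert quartet_score(t, gts) <= best

    def test_recovery_under_mild_ils(self):
        # >= 95/100 seeds recover the true 7-taxon species tree from 50
        # MSC gene trees when internal branches are >= 1 coalescent unit
        recovered = 0
        for seed in range(100):
            sp = mild_ils_tree(7, seed=1000 + seed)
            gts = sim_gene_trees_msc(sp, 50, seed=seed)
            est = msc_tree(gts, mode="exact")
            recovered += bipartitions(est) == bipartitions(sp)
        assert recovered >= 95

    def test_heuristic_beats_or_matches_start_tree(self):
        from phyloconcord.species_tree import _avg_path_distances
        sp = sim_species_tree(10, seed=9)
        gts = sim_gene_trees_msc(sp, 25, ils_scale=0.5, seed=10)
        taxa = sorted(leaf_labels(sp))
        start = nj_tree(_avg_path_distances(gts, taxa), taxa)
        est = msc_tree(gts, mode="heuristic")
        assert quartet_score(est, gts) >= quartet_score(start, gts)

    def test_too_few_gene_trees_rejected(self):
        with pytest.raises(ValueError):
            msc_tree([parse_newick("((A,B),(C,D));")])


class TestConcatenated:
    def test_single_locus_partitioned_equals_unpartitioned(self):
        sp = mild_ils_tree(6, seed=11)
        (gt,) = sim_gene_trees_msc(sp, 1, seed=12)
        aln = sim_alignment(gt, 800, rate=0.3, seed=13)
        t_pa, _ = concatenated_tree([aln], partitioned=True,
                                    bootstrap_replicates=10, seed=1)
        t_un, _ = concatenated_tree([aln], partitioned=False,
                                    bootstrap_replicates=10, seed=1)
        assert bipartitions(t_pa) == bipartitions(t_un)

    def test_equal_rate_loci_recover_homogeneous_scalars(self):
        # all loci evolve on the same genealogy at the same rate, so
        # the only scalar spread left is sequence sampling noise
        sp = mild_ils_tree(6, seed=14)
        (gt,) = sim_gene_trees_msc(sp, 1, seed=15)
        alns = [sim_alignment(gt, 1500, rate=0.3, seed=100 + i,
                              locus_id=f"L{i}")
                for i in range(5)]
        _, info = concatenated_tree(alns, partitioned=True,
                                    bootstrap_replicates=5, seed=2)
        rates = np.array(list(info["partition_rates"].values()))
        assert np.all((rates > 0.8) & (rates < 1.2))

    def test_strong_signal_gives_full_support(self):
        sp = mild_ils_tree(6, seed=16, min_internal=5.0)
        gts = sim_gene_trees_msc(sp, 4, seed=17)
        alns = [sim_alignment(g, 2000, rate=0.4, seed=200 + i,
                              locus_id=f"L{i}")
                for i, g in enumerate(gts)]
        tree, _ = concatenated_tree(alns, partitioned=False,
                                    bootstrap_replicates=50, seed=3)
        supports = [nd.bootstrap_support
                    for nd in tree.preorder_node_iter()
                    if getattr(nd, "bootstrap_support", None) is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_empty_locus_list_rejected(self):
        from phyloconcord.species_tree import build_supermatrix
        with pytest.raises(ValueError):
            build_supermatrix([])


@pytest.fixture(scope="module")
def clean_data():
    sp = mild_ils_tree(6, seed=18, min_internal=8.0)
    gts = sim_gene_trees_msc(sp, 6, seed=19)
    alns = [sim_alignment(g, 1200, rate=0.4, seed=300 + i,
                          locus_id=f"L{i}")
            for i, g in enumerate(gts)]
    gene_trees = [nj_gene_tree(a) for a in alns]
    return sp, alns, [g for g in gene_trees if g is not None]


class TestMSCBootstrap:
    def test_discordance_free_support_is_100(self, clean_data):
        sp, alns, gts = clean_data
        main, cons, reps = msc_bootstrap(alns, gts, replicates=20,
                                         flavor="gene_site", seed=4)
        supports = [nd.bootstrap_support
                    for nd in main.preorder_node_iter()
                    if getattr(nd, "bootstrap_support", None) is not None]
        assert supports and all(s == 100.0 for s in supports)
        assert bipartitions(main) == bipartitions(sp)
        assert bipartitions(cons) == bipartitions(sp)

    def test_supports_bounded(self, clean_data):
        _, alns, gts = clean_data
        main, _, reps = msc_bootstrap(alns, gts, replicates=10,
                                      flavor="site_only", seed=5)
        supports = [nd.bootstrap_support
                    for nd in main.preorder_node_iter()
                    if getattr(nd, "bootstrap_support", None) is not None]
        assert all(0.0 <= s <= 100.0 for s in supports)
        assert len(reps) == 10

    def test_support_decreases_with_ils(self):
        def mean_support(ils):
            sp = mild_ils_tree(7, seed=20, min_internal=ils)
            gts_true = sim_gene_trees_msc(sp, 12, seed=21)
            alns = [sim_alignment(g, 600, rate=0.4, seed=400 + i,
                                  locus_id=f"L{i}")
                    for i, g in enumerate(gts_true)]
            gts = [g for g in (nj_gene_tree(a) for a in alns)
                   if g is not None]
            main, _, _ = msc_bootstrap(alns, gts, replicates=20,
                                       flavor="site_only", seed=6)
            vals = [nd.bootstrap_support
                    for nd in main.preorder_node_iter()
                    if getattr(nd, "bootstrap_support", None) is not None]
            return float(np.mean(vals))

        assert mean_support(5.0) > mean_support(0.05)


class TestConcatVsMSC:
    def test_msc_at_least_as_accurate_under_severe_ils(self):
        # directional property: with every internal branch at 0.1
        # coalescent units the quartet method (consistent under the MSC
        # given error-free gene trees) should not recover the species
        # tree less often than concatenation of the same loci
        from phyloconcord.species_tree import build_supermatrix
        msc_hits = concat_hits = 0
        for seed in range(100):
            sp = sim_species_tree(7, seed=9000 + seed)
            mx = max(nd.edge.length for nd in sp.preorder_node_iter()
                     if nd.parent_node and not nd.is_leaf())
            sp = scale_internal_branches(sp, 0.1 / mx)
            gts = sim_gene_trees_msc(sp, 100, seed=seed)
            alns = [sim_alignment(g, 500, rate=0.3,
                                  seed=70000 + seed * 1000 + i,
                                  locus_id=f"L{i}")
                    for i, g in enumerate(gts)]
            est_msc = msc_tree(gts, mode="exact")
            sm, _ = build_supermatrix(alns)
            est_cat = nj_tree(ml_distance_matrix(sm), sm.taxa)
            truth = bipartitions(sp)
            msc_hits += bipartitions(est_msc) == truth
            concat_hits += bipartitions(est_cat) == truth
        assert msc_hits >= concat_hits
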