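import itertools

import numpy as np
import pytest

from phyloconcord.concordance import (
    BranchConcordance,
    CladeDefinition,
    cf_heatmap_table,
    clade_recovery,
    classify_scores,
    gcf,
    scf,
)
from phyloconcord.io_core import (
    MultipleAlignment,
    TreeCollection,
    bipartitions,
    clone_tree,
    leaf_labels,
    parse_newick,
)
from phyloconcord.simulate import (
    scale_internal_branches,
    sim_alignment,
    sim_gene_trees_msc,
    sim_species_tree,
)


def uniform_random_alignment(rng, taxa, n_sites):
    chars = np.array([b"A", b"C", b"G", b"T"])
    return MultipleAlignment(
        "noise", "CDS", list(taxa),
        chars[rng.integers(4, size=(len(taxa), n_sites))])


class TestGCF:
    def test_counting_example(self, quartet_ref):
        gts = [parse_newick("((A,B),(C,D));")] * 3 + \
            [parse_newick("((A,C),(B,D));")]
        res = gcf(quartet_ref, gts)
        assert len(res) == 1
        assert res[0].decisive == 4
        assert res[0].concordant == 3
        assert res[0].gcf_pct == 75.0

    def test_identical_gene_trees_reach_100_everywhere(self):
        ref = sim_species_tree(10, seed=1)
        gts = [clone_tree(ref) for _ in range(20)]
        res = gcf(ref, gts)
        assert len(res) > 0
        assert all(bc.gcf_pct == 100.0 for bc in res)

    def test_one_sided_gene_tree_not_decisive(self, quartet_ref):
        one_sided = parse_newick("(A,B);")
        res = gcf(quartet_ref, [one_sided,
                                parse_newick("((A,B),(C,D));")])
        assert res[0].decisive == 1

    def test_matches_bruteforce_restriction_oracle(self):
        # oracle: prune the gene tree to the branch's restricted taxa
        # with dendropy and check split presence explicitly
        rng = np.random.default_rng(2)
        for rep in range(5):
            ref = sim_species_tree(8, seed=100 + rep)
            gts = sim_gene_trees_msc(ref, 15, ils_scale=0.4,
                                     seed=200 + rep)
            # drop random taxa from some gene trees to exercise
            # decisiveness edge cases
            for g in gts[::3]:
                keep = sorted(leaf_labels(g))
                drop = [keep[rng.integers(len(keep))]]
                if len(keep) - len(drop) >= 4:
                    g.prune_taxa_with_labels(drop)
            res = gcf(ref, gts)
            for bc in res:
                side_a, side_b = tuple(bc.split)
                dec = conc = 0
                for g in gts:
                    gl = leaf_labels(g)
                    a, b = side_a & gl, side_b & gl
                    if len(a) < 2 or len(b) < 2:
                        continue
                    dec += 1
                    sub = clone_tree(g)
                    sub.retain_taxa_with_labels(sorted(a | b))
                    if frozenset([a, b]) in bipartitions(sub):
                        conc += 1
                assert (bc.decisive, bc.concordant) == (dec, conc)

    def test_no_gene_trees_rejected(self, quartet_ref):
        with pytest.raises(ValueError):
            gcf(quartet_ref, [])

    def test_concordant_cannot_exceed_decisive(self):
        bc = BranchConcordance(split=frozenset(), decisive=3, concordant=5)
        with pytest.raises(ValueError):
            bc.finalize_gcf()


class TestSCF:
    def test_single_quartet_site_counting(self, quartet_ref):
        cols = ([[b"A", b"A", b"T", b"T"]] * 8       # support AB|CD
                + [[b"A", b"G", b"A", b"G"]] * 2     # support AC|BD
                + [[b"C", b"C", b"C", b"C"]] * 5)    # non-decisive
        aln = MultipleAlignment("s", "CDS", list("ABCD"),
                                np.array(cols).T)
        res = scf(quartet_ref, aln, q=100, seed=0)
        assert len(res) == 1
        assert res[0].scf_pct == pytest.approx(80.0)
        assert res[0].quartet_decisive_sites == [10]

    def test_noise_floor_near_one_third(self):
        # i.i.d. uniform sites carry no signal: every resolution is
        # equally likely, so mean sCF ~ 33%
        rng = np.random.default_rng(3)
        ref = sim_species_tree(12, seed=4)
        aln = uniform_random_alignment(rng, sorted(leaf_labels(ref)), 1000)
        res = scf(ref, aln, q=50, seed=5)
        vals = [bc.scf_pct for bc in res if bc.scf_pct is not None]
        assert 30.0 <= float(np.mean(vals)) <= 36.0

    def test_strong_signal_high_scf(self):
        # sites evolved directly on the reference (no ILS) with
        # moderate, unsaturated branch lengths: decisive sites almost
        # always support the true pairing
        sp = parse_newick(
            "(((A:.05,B:.05):.2,(C:.05,D:.05):.2):.2,"
            "((E:.05,F:.05):.2,(G:.05,H:.05):.2):.2);")
        aln = sim_alignment(sp, 3000, rate=1.0, seed=7)
        res = scf(sp, aln, q=100, seed=8)
        vals = [bc.scf_pct for bc in res if bc.scf_pct is not None]
        assert vals and min(vals) > 80.0

    def test_exhaustive_mode_deterministic_and_convergent(self):
        sp = sim_species_tree(7, seed=9)
        aln = sim_alignment(sp, 800, rate=0.4, seed=10)
        exhaustive1 = scf(sp, aln, q=10 ** 6, seed=1)
        exhaustive2 = scf(sp, aln, q=10 ** 6, seed=2)
        for b1, b2 in zip(exhaustive1, exhaustive2):
            assert b1.scf_pct == b2.scf_pct  # seed-independent
        # sampled sCF approaches the exhaustive value as q grows
        err = []
        for q in (10, 100):
            sampled = scf(sp, aln, q=q, seed=3)
            err.append(np.mean([
                abs(s.scf_pct - e.scf_pct)
                for s, e in zip(sampled, exhaustive1)
                if s.scf_pct is not None and e.scf_pct is not None]))
        assert err[1] <= err[0]


class TestClassify:
    @pytest.mark.parametrize("value,kind,label", [
        (80.0, "gcf", "high"),
        (79.9, "gcf", "moderate"),
        (30.0, "gcf", "moderate"),
        (29.9, "gcf", "low"),
        (0.9, "support_pp", "high"),
        (0.75, "support_pp", "moderate"),
        (0.749, "support_pp", "low"),
        (90.0, "support_bs", "high"),
        (74.9, "support_bs", "low"),
    ])
    def test_band_edges(self, value, kind, label):
        assert classify_scores(value, kind) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_scores(101.0, "gcf")
        with pytest.raises(ValueError):
            classify_scores(2.0, "support_pp")


class TestCladeRecovery:
    def _collection(self):
        tc = TreeCollection()
        tc.add("d1", "m1", parse_newick("((A,B),(C,(D,E)));"))
        tc.add("d1", "m2", parse_newick("((A,C),(B,(D,E)));"))
        tc.add("d1", "m3", parse_newick("(A,B,C,D,E);"))
        return tc

    def test_recovered_and_conflicting(self):
        tc = self._collection()
        clades = [CladeDefinition("ab", frozenset("AB")),
                  CladeDefinition("de", frozenset("DE"))]
        m = clade_recovery(tc, clades)
        assert m.loc["ab", ("d1", "m1")] == "recovered"
        assert m.loc["ab", ("d1", "m2")] == "not_recovered"
        assert m.loc["de", ("d1", "m1")] == "recovered"

    def test_star_tree_gives_na(self):
        tc = self._collection()
        m = clade_recovery(tc, [CladeDefinition("ab", frozenset("AB"))])
        assert m.loc["ab", ("d1", "m3")] == "NA"

    def test_absent_tip_gives_na(self):
        tc = self._collection()
        m = clade_recovery(tc, [CladeDefinition("ax",
                                                frozenset(["A", "X"]))])
        assert (m.loc["ax"] == "NA").all()


class TestHeatmapTable:
    def test_composition_shape_and_values(self):
        sp = sim_species_tree(6, seed=11)
        mn = min(nd.edge.length for nd in sp.preorder_node_iter()
                 if nd.parent_node and not nd.is_leaf())
        sp = scale_internal_branches(sp, 10.0 / mn)  # no discordance
        gts = sim_gene_trees_msc(sp, 10, seed=12)
        aln = sim_alignment(sp, 1500, rate=0.5, seed=13)
        tc = TreeCollection()
        for ds in ("ncCDS", "plCDS"):
            tc.add(ds, "As", clone_tree(sp))
        from phyloconcord.io_core import rooted_clades
        clades = [CladeDefinition(f"C{i}", c) for i, c in enumerate(
            sorted(rooted_clades(sp), key=lambda c: (-len(c), sorted(c))))
            if len(c) >= 2][:3]
        table = cf_heatmap_table(
            tc, clades,
            {"ncCDS": gts, "plCDS": gts},
            {"ncCDS": aln, "plCDS": aln}, q=20, seed=14)
        assert len(table) == len(clades) * len(tc)
        recovered = table[table.recovery == "recovered"]
        # no discordance: recovered clades have gCF 100
        assert (recovered.gCF == 100.0).all()
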