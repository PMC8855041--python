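# phyloconcord

Species-tree congruence analysis for multi-locus target-capture
(Hyb-Seq) data.

Target-capture studies routinely build *many* species trees from one
sample set — different locus classes (exons, intron/flanking "splash
zone", off-target plastid loci) crossed with different reconstruction
strategies (concatenation vs. the multispecies coalescent, several
branch-support flavors) — and then have to decide which differences
among those trees are real conflict and which are noise.  `phyloconcord`
implements that comparison protocol end-to-end as a reusable, tested
library for phylogeneticists:

* **Locus QC** — trimAl-style gap-threshold column trimming (`-gt 0.2`:
  drop columns with >80% gaps), the matched-pairs (Bowker) test of
  symmetry for excluding loci that violate stationary/reversible/
  homogeneous evolution (α = 0.05), parsimony-informative-site counts
  and dataset summary tables.
* **Species trees** — a 4-dataset × 5-method grid: concatenated
  partitioned/unpartitioned ML trees (`Cpa`, `Cun`) with site-bootstrap
  support, and maximum-quartet-support MSC trees (`As`, plus `Abs` with
  a gene+site bootstrap and `AUFbs` with a fast site-only bootstrap
  analog) — 20 species trees in total.
* **Tree landscapes** — Robinson–Foulds (unrooted) and Kendall–Colijn
  (rooted) pairwise distances, classical PCoA, and grove detection by
  Ward clustering of the leading axes.
* **Topology tests** — RELL-based Shimodaira–Hasegawa and approximately
  unbiased tests of every species tree against a fixed concatenated
  reference, with ±-style accept/reject reporting at α = 0.05.
* **Concordance factors** — per-branch gene concordance factors
  (gCF = 100 · concordant/decisive gene trees) and site concordance
  factors (sCF = mean % of decisive sites supporting a branch over
  sampled quartets; noise floor ≈ 33% because a quartet has three
  resolutions), plus clade-recovery and heatmap tables.
* **A coalescent simulator** — species trees, MSC gene trees with a
  tunable incomplete-lineage-sorting (ILS) knob, a linked-genealogy
  plastid class, and sequence evolution under JC69/HKY85, with defaults
  that emulate a real study's three locus classes (306/239/44 loci,
  mean lengths 590/1375/1116 bp, ~11.9/26.9/1% informative sites,
  16.1/34.6/77.5% missing data).

The central statistics, in the field's usual notation: the quartet
score maximized by the MSC estimator is
`S(T) = Σ_g Σ_{q ∈ Q(g)} 1[T|q = g|q]` over gene trees *g* and their
resolved 4-taxon subsets; `gCF = 100 · n_concordant / n_decisive` per
branch; and the AU test fits `Φ⁻¹(1 − BP(r)) ≈ d√r + c/√r` across RELL
bootstrap scales *r* and reports `p = 1 − Φ(d − c)`.

## Worked example

Simulate a desk-scale study (8 taxa, 30 exon-like + 24 intron-like + 8
linked plastid-like loci), infer gene trees, estimate the MSC species
tree, and annotate it with concordance factors:

```python
from phyloconcord import (SimulationConfig, build_study_dataset,
                          msc_tree, quartet_score, gcf, scf, to_newick)
from phyloconcord.phylo_engine import nj_gene_tree
from phyloconcord.species_tree import build_supermatrix

cfg = SimulationConfig(n_taxa=8, seed=42)          # desk-scale defaults
loci, species_tree = build_study_dataset(cfg)

cds = loci.by_class("CDS")
gene_trees = [g for g in (nj_gene_tree(a) for a in cds) if g is not None]

est = msc_tree(gene_trees)                          # quartet-support MSC tree
print(to_newick(est, include_lengths=False))
print("quartet score:", quartet_score(est, gene_trees))

branch_gcf = gcf(est, gene_trees)
sm, _ = build_supermatrix(cds)
branch_scf = scf(est, sm, q=100, seed=42)
for g_, s_ in zip(branch_gcf, branch_scf):
    side = min(map(sorted, g_.split), key=len)
    print(f"branch {'|'.join(side):<12} gCF {g_.gcf_pct:5.1f}  "
          f"sCF {s_.scf_pct:5.1f}  ({g_.concordant}/{g_.decisive} trees)")
```

Output:

```
(T1,T2,((((T3,T6)69.1,T5)78.2,(T4,T8)84.2)81.3,T7)64.0);
quartet score: 1540
branch T3|T6        gCF  40.0  sCF  65.7  (12/30 trees)
branch T3|T5|T6     gCF  56.7  sCF  88.6  (17/30 trees)
branch T4|T8        gCF  76.7  sCF  76.9  (23/30 trees)
branch T1|T2|T7     gCF  60.0  sCF  78.5  (18/30 trees)
branch T1|T2        gCF  33.3  sCF  13.4  (10/30 trees)
```

The internal-node labels are normalized quartet supports (%).  The
numbers read like a real target-capture backbone: only 12 of the 30
decisive single-locus trees contain the `T3|T6` branch (gCF 40), yet
65.7% of the decisive sites support it — the classic gCF < sCF
signature of noisy individual gene trees layered on genuine
coalescent discordance.  A gCF of 40% over 30 decisive trees is the
"12 concordant loci" statement in tree counts; `classify_scores(40,
"gcf")` labels it `moderate` (bands: <30 low, 30–80 moderate, ≥80
high).  Branches can also fall *below* the 33% sCF floor (here 13.4)
when sites actively favor a conflicting resolution.

The whole protocol — QC, the 20-tree grid, landscapes, topology tests,
CF heatmaps, and a markdown report — runs as one call (or
`phyloconcord run-all --seed 7 --out run7` from the shell):

```python
from phyloconcord import run_protocol, TestConfig
run = run_protocol(SimulationConfig(seed=7), TestConfig(B=2000, seed=7),
                   seed=7, out_dir="run7")
```

On this synthetic study the plastid-dataset trees are rejected against
the fixed nuclear-exon reference by both SH and AU tests while the
nuclear concatenated trees are accepted, and RF groves at k = 2
separate plastid from nuclear trees — the qualitative structure such
comparisons show on real organellar-vs-nuclear conflict.

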