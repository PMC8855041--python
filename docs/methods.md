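# Methods

This note documents the models, defaults, and numerical choices behind
`phyloconcord`, stage by stage, and what the synthetic-data generator
does and does not emulate.

## Scope and overall design

The package reimplements, at desk scale, the comparison protocol used in
target-capture phylogenomics to diagnose conflict among species trees:
per-locus QC, a 4-dataset × 5-method species-tree grid (20 trees),
tree-landscape ordination, RELL-based topology tests against a fixed
reference, and per-branch gene/site concordance factors.  External
heavy tooling (read assembly, PASTA alignment, ModelFinder model
selection, full ML tree search, ASTRAL's constrained dynamic program,
UFboot/aBayes/SH-aLRT internals) is deliberately outside the package;
each such step is replaced by a transparent, testable analog documented
below, chosen so that the *comparison structure* of the protocol — not
any one tool's heuristics — is what the pipeline reproduces.

## Data model

Alignments are taxa × sites matrices over `{A,C,G,T,-,N}`; ambiguity
codes other than `N` collapse to `N` on input, and `-`/`N` are both
treated as missing by every statistic (the trimming rule, PIS, Bowker
counts, distances, likelihoods, sCF decisiveness).  Trees are dendropy
objects; all split-based statistics operate on label-set bipartitions so
rooted and unrooted encodings of the same topology compare equal.
Newick I/O follows the dominant dialect: lengths after `:`, internal
node labels read and written as support values, quoted labels allowed.

## Locus QC

* **Column trimming** keeps exactly the columns whose non-gap fraction
  is ≥ `gt` (default 0.2), i.e. removes columns with gaps in *more*
  than 80% of sequences; a column at exactly 80% gaps is kept.
  Trimming is idempotent by construction.
* **Matched-pairs symmetry test** (Bowker): over sites where both rows
  are called, `X² = Σ_{x<y} (n_xy − n_yx)² / (n_xy + n_yx)` over
  unordered state pairs with a nonzero denominator; df = number of such
  pairs; upper-tail χ² p-value, with df = 0 ⇒ p = 1.  The *locus*
  decision takes the pair with the largest statistic among all taxon
  pairs sharing ≥ 50 called sites (no multiple-test correction) and
  removes the locus when that p < α (default 0.05).  The max-pair rule
  is a documented aggregation choice mirroring common tool behavior;
  note that with many taxa it is intentionally conservative at locus
  level — rejection well above α per locus is expected and mirrors the
  heavy intron-class attrition seen in real data.  The nominal-α
  calibration property therefore holds for the single-pair case, which
  is what the test suite checks.  Loci with no testable pair are kept
  and flagged.
* **PIS**: a column is parsimony-informative when ≥ 2 called states
  each occur in ≥ 2 sequences.

## Synthetic data

The generator is first-class, tested code: it defines the study
conditions the rest of the pipeline is exercised under.

* **Species tree**: forward Yule (pure-birth) process with exponential
  waiting times, cut at the target tip count; ultrametric, branch
  lengths in coalescent units.  A fixed species tree can be supplied as
  Newick instead (`species_newick`) when a test needs controlled branch
  lengths.
* **ILS knob**: `ils_scale` (with a per-class multiplier) rescales
  internal branches before coalescent simulation; smaller ⇒ more
  discordance.  The three-taxon concordance law `P = 1 − (2/3)e^{−t}`
  is the analytic anchor for the simulator.
* **MSC gene trees**: one sampled lineage per species; within each
  species-tree branch of duration *t*, lineage pairs coalesce at rate 1
  per pair (exponential waiting times); survivors enter the parent
  branch; unbounded coalescence above the root.  The plastid class sets
  `linked=True`: one drawn genealogy shared by every locus, emulating
  uniparental organellar inheritance.  Its default `ils_multiplier` of
  0.25 reflects the smaller effective population size of a haploid,
  uniparentally inherited genome, and makes nuclear–plastid conflict —
  the phenomenon the protocol exists to diagnose — a property of the
  default data rather than a tuning knob.
* **Sequences**: i.i.d. sites evolved root→tips under JC69 (default) or
  HKY85 with closed-form transition probabilities via spectral
  decomposition of the normalized rate matrix; optional discrete-Γ
  heterogeneity (off by default; no acceptance property needs it).
  Branch lengths in coalescent units × a per-class `rate`
  (substitutions/site per coalescent unit) give substitution lengths.
* **Missing data**: whole-taxon dropout first (failed capture; at most
  half of the missing budget, always leaving ≥ 3 taxa), then random
  cells as `N`, hitting the class target to within rounding.
* **Class defaults** emulate the three locus classes of a 54-taxon
  Hyb-Seq study: counts 306/239/44 (exon/intron/plastid), lognormal
  lengths (σ = 0.55) clipped to the observed ranges with means
  590/1375/1116 bp, missingness 16.1/34.6/77.5%.  The per-class rates
  (0.0047/0.0136/0.00125) were calibrated once, on the default
  54-taxon species tree, against the parsimony-informative-site targets
  11.9/26.9/1% and then frozen.  A `full_scale` flag switches between
  study-scale counts and the desk-scale default (8 taxa, 30/24/8 loci)
  used throughout the tests.

What the generator does **not** emulate: indels and alignment error
(missingness is injected, not evolved), paralogy and capture bias,
among-site rate variation by default, gene flow/introgression, and
codon structure.  Passing tests therefore demonstrate correctness of
the statistics and the qualitative conflict structure, not calibration
against every property of real Angiosperms-353 data.

## Likelihoods, distances, gene trees

* **Distances**: JC69 closed form `d = −(3/4)·ln(1 − 4p/3)` on shared
  called sites; saturation (p ≥ 3/4) maps to an infinite sentinel,
  which neighbor-joining imputes as (max finite + 1).  HKY85 distances
  by bounded 1-D likelihood maximization.
* **Gene trees** are neighbor-joining trees on pairwise ML distances —
  a deliberate stand-in for per-locus ML search that preserves the
  discordance structure the downstream congruence machinery must
  detect while staying desk-scale.  Externally inferred Newick gene
  trees can be supplied instead at every entry point.  Loci with fewer
  than four usable taxa yield no gene tree.
* **Per-site log-likelihoods**: Felsenstein pruning over unique site
  patterns with per-node rescaling; gaps/N contribute a flat partial of
  1; root at the stationary frequencies (placement-invariant for these
  reversible models; checked to 1e−8).
* **Branch-length optimization**: cyclic bounded scalar search per
  branch on [0, 10] substitutions/site, sweeps until the total lnL
  improves < 1e−6 (cap 20 sweeps; 8 in the pipeline's inner loops),
  with a convergence flag.  The [0, 10] bound and 1e−6 tolerance are
  generous, otherwise-unconstrained choices.

## Species-tree methods (the 4 × 5 grid)

Datasets: `ncCDS` (exon class), `ncINT` (intron class), `ncGD` (their
union: union supermatrix for concatenation, pooled gene trees for MSC),
`plCDS` (plastid class).  Methods:

* **Cpa / Cun** (concatenated partitioned/unpartitioned): supermatrix
  over the union taxon set (missing taxa gap-padded); topology by NJ on
  supermatrix ML distances; branch lengths re-optimized by ML.  The
  partitioned scheme gives each locus a rate scalar multiplying the
  shared branch lengths — scalars and lengths optimized alternately
  (two outer iterations, two sweeps each), scalars normalized to mean 1
  with the mean absorbed into the lengths for identifiability.
  Support: % of 100 site-resampling bootstrap replicates (sites
  resampled within loci, partition sizes preserved) whose NJ tree
  contains the branch.
* **As** (MSC): maximum-quartet-support estimation.  Induced quartet
  topologies are read off the four-point condition on path-length
  matrices (unit edge lengths), so multifurcations yield ties ⇒
  unresolved ⇒ no score contribution.  With ≤ 8 taxa the estimator
  enumerates all (2n−5)!! unrooted binary topologies (cached per n) and
  returns the argmax — the enumeration *is* the oracle; ties break to
  the lexicographically smallest Newick.  Above 8 taxa: NJ on average
  gene-tree path-count distances, then NNI hill-climbing to a local
  optimum.  Branch annotation is **normalized quartet support** (share
  of resolved gene-tree quartets spanning the branch that agree with
  it), deliberately *not* ASTRAL's local posterior probability, whose
  formula is a different quantity; mixing the two silently would be
  misleading.  An optional flag collapses branches below a support
  threshold (default off; 1/3 + ε is the natural choice for
  polytomy-like behavior).
* **Abs**: gene+site bootstrap — resample loci with replacement and
  sites within each sampled locus, re-infer gene trees, re-run the MSC
  estimator; 100 replicates.
* **AUFbs**: the fast-bootstrap *analog* — site resampling within each
  locus only (no locus resampling, no tree-proposal machinery), 1,000
  replicates at full scale, 200 at desk scale.  It is labeled an
  analog: the comparison structure across support flavors, not
  UFboot's algorithm, is what the grid reproduces.  A greedy
  majority-rule consensus of the replicates is also emitted.

## Harmonization and landscapes

Before comparison, trees are pruned to a common leaf set (an explicit
drop list; the pipeline additionally drops any tips not shared by all
20 trees, since an ingested or heavily-missing dataset can lose a
taxon) and rooted on a designated outgroup's pendant edge, suppressing
degree-2 nodes with lengths summed.  RF distances are computed on
unrooted trees (symmetric difference of non-trivial bipartition sets,
unnormalized by default, with a 2(n−3) normalization option); KC
vectors on rooted trees (root-to-MRCA depths per tip pair plus pendant
entries, λ-mixture of edge counts and lengths, λ = 0 default:
topology only, matching the common treespace default).  A source
ambiguity is resolved here deliberately: where a figure caption and the
methods text of the motivating protocol disagree about which metric is
rooted, this package follows the methods text (RF unrooted, KC rooted).
PCoA is classical scaling (double-center −D²/2, `eigh`, top-k positive
axes, k = 3 default); negative eigenvalues are dropped and counted.
Groves are Ward-linkage clusters on the first three axes, labels
canonicalized by first appearance; all-zero landscapes yield a single
grove.

## Topology tests

Branch lengths of the fixed tree (concatenated-partitioned exon tree in
the pipeline) and all 20 candidates are re-optimized on the exon
supermatrix — RELL requires per-site log-likelihoods under one common
alignment, so re-optimization is the only coherent choice and is stated
here explicitly.  RELL replicates draw multinomial site weights
(`round(scale × n)` sites with replacement, identical draws across
trees within a replicate, chunked matrix products for memory).  SH:
centered replicate deltas versus observed deltas; the best tree gets
p = 1 by construction.  AU: bootstrap proportions at ten scales
(0.5…1.4), ties for the replicate maximum split equally, BP clipped to
[1/(2B), 1−1/(2B)], weighted least squares of Φ⁻¹(1−BP) on
d√r + c/√r with binomial-variance weights, p = 1 − Φ(d − c);
all-degenerate BP profiles short-circuit to 0/1 with a flag, and a
singular fit falls back to the SH p-value with a warning.  Defaults:
B = 10,000 replicates, α = 0.05; the pipeline's desk-scale runs use
B = 1,000–2,000, which leaves the ±-decisions of the report unchanged
in the regimes tested.

## Concordance factors

gCF decisiveness requires ≥ 2 taxa on each restricted side of a branch
(the standard convention, stated so the brute-force oracle can mirror
it); concordance is exact membership of the restricted bipartition in
the gene tree's splits; gCF = 100·concordant/decisive, undefined (not
0) when nothing is decisive.  sCF samples q = 100 quartets per branch
(one taxon per adjacent subtree, with replacement across quartets,
seeded and recorded); a site is decisive for a quartet when all four
taxa are called and the site supports exactly one pairing
(`state(a)=state(a′) ≠ state(b)=state(b′)`); per-quartet concordance is
concordant/decisive sites, and sCF is the mean over quartets with ≥ 1
decisive site — `None`/NA, never 0, when no quartet has decisive sites.
When fewer than q distinct quartets exist they are enumerated
exhaustively, making small-tree sCF deterministic and
seed-independent.  Each dataset's own supermatrix feeds its trees'
sCF.  Classification bands: gCF low < 30 ≤ moderate < 80 ≤ high;
posterior-probability support low < 0.75, high ≥ 0.9; bootstrap
support low < 75, high ≥ 90.  Clade recovery distinguishes `recovered`
(split present), `not_recovered` (split incompatible with the tree),
and `NA` (< 2 clade tips present, or split compatible but unresolved —
e.g. any clade against a star tree).  The pipeline's default clade
list tracks the internal clades of the generating species tree
(largest first, up to 14), the synthetic analog of a recurrent-clade
panel.

## Problem sizes

The shipped defaults are desk-scale choices: 8 taxa (keeping the MSC
estimator in exact-enumeration mode), 30/24/8 loci, Abs = 100 and
AUFbs = 200 bootstrap replicates, RELL B = 2,000 in the acceptance
script, q = 100 sCF quartets.  Calibration suites use 100–1,000
seeded replicates with B = 1,000.  Full-scale settings (54 taxa,
306/239/44 loci, AUFbs = 1,000, B = 10,000) are one flag away and use
the identical code paths (the MSC estimator switches to NNI
hill-climbing above 8 taxa).

## Known limitations

* NJ gene trees and NJ concatenation topologies understate what full
  ML search would recover from weak loci; the per-branch supports and
  CF values are exact for the trees actually built.
* The partitioned model shares one topology and relative branch
  lengths across loci with a single rate scalar per locus — no
  per-locus substitution-model selection.
* Normalized quartet support is not a posterior probability; its
  `support_pp` classification bands apply only to externally supplied
  posterior values.
* The NNI hill-climb (> 8 taxa) is a local optimizer; only exact mode
  carries the argmax guarantee.
* Under very short internal branches *and* high rates, sequence
  saturation erodes all signal; the simulator will happily produce such
  regimes, and the concatenated and MSC estimates then disagree for
  reasons unrelated to ILS.
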