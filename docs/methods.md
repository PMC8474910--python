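# Methods

`panphen` links bacterial gene presence/absence variation to a quantitative
host-fitness phenotype measured in mono-association experiments: germ-free
hosts are each reared with a single bacterial isolate, the phenotype
(offspring per female, a count) is measured over replicate vials, and every
gene cluster in the pan-genome is scored for association with the
per-strain phenotype while accounting for the strain phylogeny.

## The association score

For gene *g* let

* *D*<sub>g</sub> — difference in mean offspring between strains carrying
  and lacking the gene (offspring units, signed);
* *σ* — the global standard deviation of offspring across strains;
* *n*<sub>g</sub> — the minimum number of gain/loss events needed to
  explain the gene's presence/absence pattern on the strain tree
  (homoplasy count).

The score is **√n<sub>g</sub> · D<sub>g</sub> / σ**. It is dimensionless,
signed (presence-increases-phenotype is positive), and invariant under any
affine rescaling of the phenotype. The √n<sub>g</sub> factor addresses the
dominant failure mode of pan-genome association: vertical descent makes
gene presence patterns strongly correlated genome-wide, so a lineage that
happens to confer high fitness drags hundreds of clade-marker genes with
it. A pattern that arose once is indistinguishable from clade identity and
is down-weighted; repeated, independent gains and losses that still track
the phenotype constitute stronger evidence and are up-weighted. Two genes
with identical histories necessarily get identical scores — the method
cannot separate perfectly linked genes (e.g. one operon), only flag the
block.

**σ definition.** σ is the sample SD (ddof = 1) of the per-strain mean
offspring over the analysis strains. A configuration switch
(`sigma_mode="replicates"`) uses the SD over all replicate counts instead;
this rescales every score by a common factor and cannot change rankings.
The strain-means default is used everywhere in the tests and validation
experiments.

**Event counting.** *n*<sub>g</sub> is computed by unit-cost Sankoff
dynamic programming (the generalisation of Fitch parsimony to
multifurcations), which handles polytomies natively and is independent of
root placement because the transition costs are symmetric. Parsimony
rather than a likelihood model: the count enters only through √n<sub>g</sub>,
the tree is small, and a rate model would add parameters the data cannot
constrain. Gains and losses are not distinguished in the count. Genes
invariant over the analysis strains have no defined *D*<sub>g</sub> and
are excluded up front with a logged count.

## Null distributions

**Permutation test.** Strains are the experimental unit, so the minimal
exchangeable null permutes the per-strain mean phenotypes across strain
labels while tree and matrix stay fixed. All gene scores are recomputed
per permutation (σ is re-derived, though a relabelling leaves either σ
definition unchanged) and p-values use the add-one rule
p = (1 + #{|score*| ≥ |score|}) / (1 + N), so p ≥ 1/(N+1). Default
N = 10,000. Benjamini–Hochberg q-values are attached as a convenience.

**Tree-aware statistics.** Three companion statistics adapt the treeWAS
score family to a continuous phenotype. With Δy<sub>b</sub> the phenotype
change along branch *b* from a squared-change-parsimony reconstruction of
the strain means, Δx<sub>b</sub> ∈ {−1, 0, +1} the genotype change from a
minimum-change ancestral labelling, x̄<sub>b</sub> the mean genotype state
at the branch ends and ℓ<sub>b</sub> the relative branch length:

* *terminal* = |Pearson r between tip presence and tip strain means|;
* *simultaneous* = |Σ<sub>b</sub> Δx<sub>b</sub>·Δy<sub>b</sub>|;
* *subsequent* = |Σ<sub>b</sub> ℓ<sub>b</sub>·x̄<sub>b</sub>·Δy<sub>b</sub>|.

Their null distributions come from genotype vectors simulated under the
observed homoplasy: for each observed n<sub>g</sub>, state-flip events are
dropped on branches with probability proportional to branch length (root
state fair Bernoulli) and the statistics recomputed; genes sharing an
n<sub>g</sub> share one null sample, and p-values again use the add-one
rule. This preserves both the tree and each gene's amount of homoplasy, so
a gene is only called associated if its pattern tracks the phenotype better
than equally-homoplastic patterns scattered at random over the same tree.
The minimum-change ancestral labelling breaks ties deterministically (root
prefers absence; every other node prefers its parent's state).

**Continuous reconstruction.** Internal phenotype values minimise
Σ<sub>branches</sub> (Δy)²/length — squared-change parsimony, equal to the
Brownian-motion ML states on a fixed tree — solved exactly as a weighted
Laplacian linear system. Unspecified branch lengths count as 1; zero
lengths are lifted to 10⁻⁸ × tree depth for this reconstruction only.

## Strain-group contrasts

* **Heterogeneity:** Kruskal–Wallis (tie-corrected, χ² p) of replicate
  offspring across strains.
* **Pathway groups:** strains are labelled pathway-positive when they
  carry *all* genes of a declared set (default `thiC thiD thiO thiS thiG
  thiE`, the thiamine biosynthesis pathway), or by an explicit assignment
  file. The group test is a two-sided Mann–Whitney on per-strain
  *medians* — medians feed the group test while means feed
  *D*<sub>g</sub>, and the two conventions are kept deliberately separate.
  The exact null is used for panels of ≤ 20 strains.
* **Load adjustment:** `offspring ~ strain + log10(CFU+1)` with a type-II
  ANOVA p for the strain term, plus the load-only slope test. The log10
  transform is this package's choice; CFU counts span orders of magnitude.
* **Supplementation contrast:** relative offspring = each
  pathway-negative replicate divided by the mean offspring of the
  pathway-positive controls in the same treatment arm (parity = 1, and the
  ratio is invariant to any common rescaling within an arm). The
  treatment effect is tested with a linear mixed model (treatment fixed,
  pathway-negative strain as random intercept, REML). The p-value is the
  Wald z test of the treatment coefficient; statsmodels does not provide
  containment-rule degrees of freedom, and with ≤ a handful of strains the
  normal approximation is the honest label for what is computed.
* **Fold difference:** ratio of larger to smaller strain mean, orientation
  reported; an infinite ratio is flagged rather than raised.

## Synthetic data generator

The generator produces the statistical structure the analysis assumes, so
every stage is testable without external data.

* **Tree:** pure-birth (Yule) with unit-depth rescaling, or a supplied
  newick. Rescaling makes branch lengths interact with the gain/loss rates
  only through the products a·t and b·t.
* **Genes:** each gene evolves independently as a two-state continuous-time
  Markov chain — gain 0→1 at rate *a*, loss 1→0 at rate *b* per unit
  branch length, root state Bernoulli(π₀). The exact number of state
  flips per gene is recorded; any parsimony count is a lower bound on it,
  and that bound is asserted on every fixture. Defaults a = 0.3, b = 0.6,
  π₀ = a/(a+b) = 1/3 (stationary start) give a moderately homoplastic
  accessory genome (mean ≈ 2–3 events per gene on a 17-strain tree) in
  which almost every gene is variable. A fixed-cluster CTMC was chosen
  over infinitely-many-genes models because the analysis scores fixed
  clusters; a single rate class cannot reproduce the U-shaped frequency
  spectrum of real pan-genomes (simultaneous large core and many
  singletons), which is a known limitation of the emulation.
* **Phenotypes:** strain mean = max(0.5, μ₀ + Σ β·presence + ε),
  ε ~ N(0, τ²), with negative-binomial replicates of size k around it
  (counts with between-vial overdispersion; k → ∞ recovers Poisson).
  Defaults μ₀ = 40 offspring, τ = 4, k = 10, 10 replicates per strain —
  a plausible operating point for a 16-day offspring-count assay. The
  floor keeps the NB mean positive and is logged when applied. Optional
  covariate columns: log10-normal CFU (independent of strain, i.e. a
  pure-noise covariate) and normal per-fly weight.
* **Causal genes:** listed as (index, β) pairs; a `None` index
  auto-selects the most homoplastic variable pattern (minor group ≥ 3
  strains, frequency closest to ½ within the top homoplasy class, lowest
  index on ties). Homoplastic causal patterns are deliberate: a causal
  gene whose pattern needs a single event is confounded with clade
  identity and is down-weighted by the score *by design*, so planting
  effects there would test a regime the method explicitly discounts.
  Pathways repeatedly lost and regained (e.g. by horizontal transfer) are
  the regime the score targets. The `paperlike` preset (17 strains,
  2,000 genes, 5–13 replicates per strain) plants a six-gene *linked
  block* — one history copied across six gene columns, total effect
  12 offspring (two null strain-mean SDs) split evenly — emulating an
  operon-level causal pathway; the effect size in offspring units is a
  free parameter of the emulation, not an estimate.
* **Supplementation experiment:** pathway-negative strains start 30 %
  below baseline; the supplemented arm multiplies their means by 1.3.
* **Seeding:** one top-level seed fans out to fixed per-stage
  `SeedSequence` spawn keys (tree / matrix / phenotypes / permutations /
  tree-null / covariates), so identical configs give byte-identical
  fixtures and each stage is independently reproducible.

## Validation experiments and what they show

`panphen.evaluation` packages the study-scale experiments that
`tests/test_acceptance.py` asserts and `scripts/acceptance.py` reports:

* Sankoff counts equal brute-force enumeration over all internal
  labelings on 200 random trees of ≤ 8 tips.
* The 4-strain worked example scores √1·10/5.7735 = 1.7321.
* Type-I calibration: under β = 0 (20 strains, 500 genes, 999
  permutations) the fraction of genes at p < 0.05 averages 0.045 over
  many seeds (theoretical 0.049 under the add-one rule). Genes share one
  phenotype draw per dataset, so the per-dataset fraction has SD ≈ 0.035;
  a 3-seed mean is accordingly noisy, and single triples can land outside
  0.05 ± 0.02 without any miscalibration.
* Recovery: a single causal gene at β = 2 × null strain-mean SD is
  ranked first by |score| in roughly 75–85 % of simulated datasets
  (2,000 genes, 20 strains, 10 replicates). The ceiling is intrinsic at
  this effect size: the causal score is ≈ 3.7 with SD ≈ 0.85 while the
  maximum null score over 2,000 correlated genes is ≈ 2.8, and the ratio
  does not depend on the noise scale (β is defined relative to it) or
  materially on the gain/loss rates.
* Affine invariance, the exact Mann–Whitney example (p = 0.1), and the
  parsimony-vs-truth lower bound are asserted exactly.

Because the generator draws strain means independently of the tree
(phenotype noise is not phylogenetically autocorrelated except through the
causal genes) and evolves genes at a single rate, passing these tests
shows the machinery is correct and calibrated under the assumed model —
not that real data meet those assumptions. Phylogenetically autocorrelated
phenotype noise, rate heterogeneity across genes and genome-wide linkage
beyond the planted block are exactly the conditions in which the
permutation null is anticonservative, which is why the tree-aware
statistics accompany every score.

## Numerical choices

* Add-one empirical p-values everywhere; comparisons use a 10⁻¹² slack so
  exact float ties count as "at least as extreme".
* Ranking sorts on |score| descending with lexicographic gene-id
  tie-break (stable sort), for deterministic golden outputs.
* Mann–Whitney switches from the exact null to the normal approximation
  above 20 strains.
* The weighted-Laplacian solve is dense (trees here have tens of nodes).
* Hard errors: σ = 0 ("degenerate phenotype"), fewer than 3 shared
  strains, no variable gene, missing tip states, duplicate gene or tip
  ids, non-binary cells in a binary matrix (reported with row/column).

## Known limitations

* Perfectly linked genes are inseparable by construction; results report
  the block, interpretation must break the tie (annotation, synteny).
* The permutation unit is the strain; with 17–20 strains the resolution
  of p-values is limited and multiplicity correction across thousands of
  correlated genes is conservative.
* No kinship/LMM population-structure correction, no SNP-level tests, no
  gene-cluster construction: the matrix and tree are consumed as given.
* The mixed model uses a Wald z p-value (see above); with very few
  strains a containment-df t test would be slightly more conservative.
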