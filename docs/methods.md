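# Methods

`agetraj` re-implements, as a tested library, a temporal transcriptome
analysis of brain aging in a short-lived fish: five age groups sampled at
5, 12, 20, 27 and 39 weeks with five biological replicates each, bulk
RNA-seq counts normalized to RPKM, and a chain of analyses — differential
expression, fuzzy temporal clustering, quadratic shape classification,
gene-set enrichment, coexpression networks and ordination. Because the raw
sequencing data are not distributed with the package, every method is
exercised and validated on a synthetic-data generator that emulates the
study design and carries ground truth.

## Normalization

RPKM is computed from the count matrix itself:
`value(g,s) = counts(g,s) · 10^9 / (length(g) · total_counts(s))`, with the
library size taken as the column total (self-contained, no side files).
Downstream analyses that are sensitive to heteroscedasticity (clustering,
correlation networks, MDS, quadratic fits) run on `log2(RPKM + 1)` by
default; the pseudocount of 1 keeps zeros at zero. A `--no-log` switch
gives literal RPKM parity where wanted.

A practical caveat of column-total normalization, visible in the synthetic
experiments: when a large fraction of the library changes with age, the
denominator absorbs part of the signal (composition bias). The generator's
recovery experiments therefore keep strongly regulated genes a minority of
the library, as in real transcriptomes.

## Synthetic-data generator

Six temporal archetypes define expected RPKM curves over age `t` normalized
to the design span:

- flat: `b`
- linear up/down: `b·(1 ± A·t)`
- rapid decay: `b·((1−A) + A·exp(−λ·(age−a0)))`, λ = 0.3/week — a fast
  approach to a nonzero asymptote
- U / bell: `b·exp(±A·τ²)`, `τ = (age − vertex)/(a_max − a0)` — Gaussian
  bumps rather than raw parabolas so intensities stay positive; the
  downstream quadratic fit faces a deliberately mismatched generative form
  (in log space the bump is exactly quadratic, in linear space it is not)

Defaults: baseline 100 RPKM with a per-gene lognormal spread (σ = 0.5 on the
log scale), amplitude 0.8 for linear/decay shapes and 2.0 for U/bell. The
U/bell amplitude differs because it acts on `τ² ≤ ~0.42`: amplitude 2 gives
a ~2× peak-to-edge fold change, matching the ~1.8× span of the linear
archetypes, so every non-flat archetype carries a comparable, realistic
effect size. The bell vertex defaults to 25 weeks and the U vertex to 27
weeks — inversion points near median lifespan, where the emulated study
located them.

Counts are negative binomial with size (dispersion) 10 — moderate bulk
RNA-seq overdispersion — and mean obtained by inverting the RPKM formula for
a library size drawn uniformly from [8×10^5, 1.2×10^6] reads and a
transcript length from [500, 5000] b. One seeded generator stream drives all
draws, so identical configs are bitwise reproducible. The generator does
not model gene–gene correlation beyond archetype sharing, batch or sex
effects, GC/length biases, or outlier samples; passing recovery tests
therefore demonstrate correctness of the estimators under the stated
model, not robustness to every artifact of real data. Two separate planted
scaffolds (a driver gene with correlated followers; two latent blocks that
decouple at the last age) exist purely to test network recovery.

## Differential expression

A gene is a DEG when all three tests pass BH FDR < α (default 0.05) in at
least one of the C(5,2) = 10 pairwise age-group comparisons; no fold-change
cutoff is applied. The three tests are methodologically independent in
kind:

1. **NB Wald** — Wald statistic on the difference of log group means under
   a negative-binomial model. Size factors are median-of-ratios; dispersion
   is a method-of-moments *common* estimate (median of per-gene moment
   estimates across all genes of the comparison, floored at 10^-8), which
   stabilizes the small-sample variance. The reference distribution is
   t(n_a + n_b − 2): with 5 replicates per group a normal reference was
   measured anticonservative (null rate 0.061 at α = 0.05) while the t
   reference is conservative (0.028); control of type-I error is preferred.
2. **Rank-sum** — Mann-Whitney U, exact when the pooled sample is untied
   and has ≤ 12 observations, midrank/tie-corrected normal approximation
   otherwise.
3. **Permutation** — |log2 fold change| of group means against the label
   permutation distribution; exhaustive over all C(n, n_a) splits when that
   number is ≤ 20 000 (it is 252 for the default design), seeded Monte
   Carlo with the add-one estimator otherwise.

BH is applied per test per comparison. The per-comparison FDR guarantee
does **not** transfer to the union over comparisons: when a large fraction
of genes carries very strong signal, the BH threshold within a comparison
rises above the exact tests' attainable p-value floor (2/252 at 5v5), and
null genes with chance complete separation slip through; the realized FDR
of the union can then run above α (measured ~0.07–0.10 in a 25 %-strong-DEG
composite). Under the default generator mix the realized FDR stays ≈ 0.04.
This behavior is a property of the published calling rule, reproduced
deliberately.

## Temporal clustering

Profiles are per-age replicate means (5 values per gene), centered to mean
0 and scaled to variance 1; constant profiles are excluded and reported.
Fuzzy c-means uses the standard alternating updates with Euclidean
distance, fuzzifier m = 2, membership-change tolerance 10^-6, ≤ 500
iterations, and the best objective over 20 random starts (pipeline default
5 starts for speed; the methods are identical). A profile coincident with a
centroid receives full membership there.

The number of clusters is chosen by majority vote of five validity indices
— partition coefficient (max), partition entropy (min), Xie–Beni (min),
Fukuyama–Sugeno (min), fuzzy silhouette (max) — with ties broken toward
smaller k. On low-noise simulations of the five *shaped* archetypes the
electorate is unanimous at k = 5. Two structural limits are documented
rather than hidden: per-gene standardization maps flat genes to isotropic
unit-variance noise (a "no-shape" archetype cannot form a cluster), and at
realistic noise the partition coefficient/entropy indices carry their
well-known bias toward very small k, dragging the vote to k = 2 on the
default-noise synthetic data even though a k = 6 FCM partition still
matches archetype truth with ≥ 0.8 accuracy after Hungarian matching.

Monotonicity (single-signed consecutive differences) and initial direction
are properties of the cluster *mean* profile; the percentage bookkeeping
weights clusters by membership, matching how the emulated analysis reports
"% of DEGs in monotonic clusters". Group-average trajectories standardize
each member gene and average; the percent change between first and last age
is computed on the unstandardized group mean.

## Quadratic shape analysis

Each gene's `log2(RPKM+1)` values are regressed on `[1, age, age²]` by OLS
over all 25 samples (not the 5 per-age means — this preserves n − 3 = 22
residual df for the t-test). The quadratic coefficient's two-sided t-test
at P < 0.05 (raw, no cross-gene multiplicity correction — deliberately, as
in the emulated analysis) labels the gene U (a > 0) or bell (a < 0); the
inversion age is the vertex −b/(2a), flagged when outside the sampled range.
Peak summaries use 2-week histogram bins and report in-range medians.

## Enrichment

Hypergeometric upper-tail test of a query list against the expressed-gene
background (never the whole annotation); sets are intersected with the
background before K is computed; BH across tested sets; fold enrichment
(k/n)/(K/N). Fisher's two-sided 2×2 test is provided for parity; its
one-sided tail is identical to the hypergeometric urn. Significant terms
are grouped by Cohen's kappa between gene-membership vectors over the
background, single linkage at κ ≥ 0.4 (configurable), each group annotated
by the member with the largest query overlap. An EASE-style offset is not
implemented; plain hypergeometric is the declared choice.

## Networks

Pearson correlation over the chosen samples on `log2(RPKM+1)` (config flag
for raw RPKM), edge when the signed r ≥ threshold (default 0.95; positive
correlations only by default, since the emulated question is coregulation —
both knobs config-exposed). Computation is blocked/tiled so memory stays
linear in block size, with results identical to the naive double loop (a
1e-12 slack keeps exact duplicates connected at threshold 1.0). Only genes
incident to an edge are nodes. Hub = maximum degree, ties broken
lexicographically and all tied nodes listed. Age-stratified networks reuse
the machinery per stratum (≥ 3 samples required) and are compared by
edge-set Jaccard; with 5 samples per stratum correlation estimates are
heavy-tailed, and thresholds are deliberately not recalibrated.

## Ordination

Classical (Torgerson) MDS: B = −½·J·D²·J, eigendecomposition, top-k axes
scaled by √λ, each axis sign-fixed so its first nonzero coordinate is
positive. Distances are Euclidean on `log2(RPKM+1)` over all genes. The
per-age "confidence circle" is defined (the emulated figure legend does
not define it) as the 95th percentile of within-group distances to the
centroid; singleton groups are flagged with NaN radius.

## Problem sizes and determinism

The test suite and the acceptance script run the default design (1200
genes × 25 samples), 2000-gene null simulations over 10 seeds, 20-seed
vote/hub recovery loops, and reduced FCM restart counts (5–10) — sizes
chosen so the whole suite completes in about a minute on one CPU while
keeping every Monte-Carlo margin at ≥ 3 standard errors. All stochastic
stages take explicit seeds; the pipeline writes a manifest with a config
hash, and re-running an identical config reproduces byte-identical TSVs.

## Known limitations

- The three DEG tests are declared functional stand-ins chosen for
  methodological independence; the emulated study's exact test identities
  are in its supplementary material and are not claimed.
- Union-over-comparisons FDR inflation under strong composite signal (see
  above).
- The validity-index electorate inherits the small-k bias of the partition
  coefficient/entropy at realistic noise; interpret the vote jointly with
  the per-k validity table the pipeline writes.
- RPKM from column totals carries composition bias when regulated genes
  dominate the library.
- No GO DAG topology, ortholog mapping, covariate adjustment, dispersion
  shrinkage, or non-metric MDS.
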