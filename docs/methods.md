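# Methods

## The model

Expression of one probe across fetuses is modelled on the log2 scale as

    y = X beta + Z u + e,    u ~ N(0, sigma_sow^2 I),   e ~ N(0, sigma^2 I)

where `Z` indicates the sow (litter) of each fetus, so littermates share a
random intercept. The fixed part `X beta` is one of a family of treatment-
coded structures (reference levels d90 and LW):

* full: age + fetal genotype + age:genotype (8 cell means);
* additive, age-only, genotype-only (the BIC sub-model family);
* parental: age + maternal + paternal + age:maternal + age:paternal +
  maternal:paternal. The four fetal genotypes map onto the 2x2 parental
  grid (LW = LW/LW, MS = MS/MS, LWMS = MS dam x LW sire, MSLW = LW dam x MS
  sire), which is what makes the two parental contributions separable; the
  model is the full 2x2x2 cell-mean model minus the three-way interaction.

Sows are sampled once (caesarean), so the sow effect is nested within
age x maternal genotype; the generator and all design validation enforce
this (a sow with two ages, or a litter implying two dams, is rejected).

## Fitting

Writing `gamma = sigma_sow^2 / sigma^2`, the marginal covariance is
`sigma^2 (I + gamma ZZ')`. `ZZ'` is constant across probes, so it is
eigendecomposed once; in the rotated basis each candidate `gamma` costs one
weighted least squares and the profile log-likelihood

    l(gamma) = -n/2 (log(2 pi RSS_w(gamma)/n) + 1) - 1/2 sum log(1 + gamma d_i)

is evaluated for all probes simultaneously on a log-spaced grid
({0} and 141 points over [1e-6, 1e4]), then refined per probe by bounded
scalar minimisation between the bracketing grid points (tolerance 1e-9 in
`gamma`). The optimum agrees with an independent dense-grid search to
better than 1e-6 log-likelihood units, and with statsmodels' MixedLM ML
fits to ~1e-9 (both are test oracles, not dependencies of the fitting
path). When the profile is flat — one fetus per sow makes `gamma`
unidentifiable — the smallest `gamma` within numerical tolerance of the
maximum is taken, so the fit resolves to OLS with `sigma_sow^2 = 0`.

Estimation is by ML, not REML, because BIC comparisons across sub-models
with different fixed effects need comparable likelihoods; one fitting path
serves both testing and classification. The known downward ML bias in the
variance components is documented in the parameter-recovery test and does
not enter the testing path (next section).

## Testing and calibration

Differential expression is an extra-sum-of-squares F on data whitened at a
variance ratio `g`:

    F = ((RSS_red - RSS_full)/dp) / (RSS_full/(N - p_full)),  F ~ F(dp, N - p_full)

with the residual/containment denominator convention. With `g` known the
test is exact. With `g` re-estimated per probe from only 18 litters it is
measurably anti-conservative (null fraction below p = 0.01 is ~1.8% with
per-probe ML, ~1.5% with per-probe REML). The package therefore estimates a
single **consensus** ratio by maximising the summed per-probe REML
log-likelihood over a common `gamma` — the practice established by limma's
`duplicateCorrelation` for exactly this situation — and whitens every probe
with it. Under the default synthetic conditions this restores exact
calibration (KS uniformity comfortably passed at 5,000 null genes;
family-wise error at Bonferroni 1% at or below nominal over 50 replicates).
Per-probe whitening remains available (`gamma_mode="per_probe"` or the
`gamma=` argument of `ftest_vs_reduced`); the consensus assumes the
intra-litter correlation is shared across probes, which is the study-design
view (the litter effect is a property of the sampling, not of single genes)
but is an approximation whenever true per-gene ratios are heterogeneous.

BIC uses `-2 loglik + k log(n)` with `n` the number of fetuses (the
observation count, resolving the usual mixed-model ambiguity) and `k` the
fixed-effect rank plus 2 variance components; since every sub-model carries
the same 2, differences reduce to fixed-effect complexity. Exact ties go to
the most parsimonious sub-model.

Multiple testing: Bonferroni (capped) and BH step-up via statsmodels, with
the family equal to all testable probes. Zero-variance probes are excluded
from the family and reported as `not_testable` rather than given p = 1.

## Power structure of the design

Not all effects are equally testable, and this asymmetry is a property of
the design, not of the implementation. Age and maternal genotype are
constant within litters, so their effects are tested against between-sow
variation (18 sows); fetal purebred-vs-crossbred contrasts and therefore
the paternal genotype vary within litters and are tested against the much
larger residual information. Concretely, at effect 1.0 log2 under default
noise, the omnibus 7-df DEP test detects essentially all interaction,
additive and block genes but only ~1/3 of pure age-only genes (analytic
noncentrality ~28 on F(7, 57) at the Bonferroni threshold agrees), and
paternal interactions are called far more reliably than maternal ones. The
pipeline regression tests freeze these honest levels. The same asymmetry is
why reciprocal-cross studies report many more paternally than maternally
regulated genes.

## Enrichment

Probes collapse to genes by keeping each gene's largest-|log2FC| probe;
unannotated probes are dropped with a logged count. Regulated lists use
`|log2FC| >= log2(1.4) ~ 0.485` inclusive (the threshold is a rounded fold
change, so the boundary is included; it is configurable). The universe is
the set of annotated genes measured on the array, not the genome. The
hypergeometric upper tail comes from scipy and is checked against full
enumeration for every configuration with a universe of 12 or fewer. GO
hierarchy propagation is out of scope: sets are taken as the GMT provides
them.

## Relevance network

Pearson correlations are computed across all samples pooled over
conditions (per-condition networks are possible by subsetting). Edges
require `|r| > 0.98` strictly; at ~60 samples this keeps only
near-deterministic co-expression, so the graph decomposes into near-clique
modules. One probe represents each gene — the highest-variance one.
Communities come from an in-package Clauset-Newman-Moore implementation:
singleton start, merge the connected pair with the largest modularity gain
(ties to the smallest community-index pair), cut at the first maximum of Q.
Greedy agglomeration is not a global optimiser: on unstructured G(n,p)
graphs it misses the exhaustive-search optimum a few percent of the time
(a known property of the algorithm), while on the near-clique graphs this
threshold actually produces it attains the optimum — the oracle suite
tests both regimes, equality on the structured one and the upper bound on
the unstructured one.
Degree and betweenness (Brandes, unnormalized, so a value is a raw count of
bridging shortest paths) come from networkx and are checked against a
path-enumeration oracle. Communities are reported within the largest
connected component by default (one interpretable module map), or on the
full graph (`community_scope="full"`), which is what block-recovery ARI
uses since planted blocks form separate components.

## qPCR

Efficiency is the least-squares slope of Ct on log10 relative
concentration, `E = 10^(-1/slope)`; a 2-fold series at perfect efficiency
gives slope -3.3219 and E = 2 exactly. Estimates may overshoot 2 slightly
under Ct noise, so Pfaffl inputs accept E up to 2.5. The calibrator is the
gene's mean Ct over samples (configurable); technical replicates are
averaged on the Ct scale first. qPCR ratios are log2-transformed before
Pearson correlation with the (log2) array values, keeping both sides on
like scales.

## Synthetic-data generator

The generator is the package's study stand-in and defines the default test
conditions: 9 LW + 9 MS sows, one age per sow split so all 8 conditions are
populated, litters of 3-4 with the purebred and the crossbred genotype
always present (~63 fetuses), `sigma_sow = 0.3`, `sigma_resid = 0.5` log2
units, baseline intensities N(8, 1), 10% of probes unannotated.

Planted classes follow one convention: **the effect size e is the marginal
(genotype-averaged) d110-minus-d90 log2 fold change of the class**, the
scale on which the 1.4-fold filter operates. Age-only and additive classes
realise it as a uniform age effect `e`; interaction classes as
genotype-dependent age slopes `(0, 2e, e, e)` for (LW, MS, LWMS, MSLW) —
the "maturation delayed in one breed" archetype — plus a genotype main
effect with spread `e`; parental classes as slope `2e` in the MS-dam (or
MS-sire) half and 0 otherwise. Interaction deviations of magnitude `e` are
what makes the classes BIC-separable at the default sample size; an
interaction confined to a single cell at amplitude 0.5e sits below the
3-parameter BIC penalty and is indistinguishable from additivity at n ~ 63.

Network blocks are driven by a shared latent factor
`f = pattern + N(0, 0.4^2)` per sample; children add independent noise
sized so the within-block correlation hits the target (0.99 by default,
`var(f)(1-rho)/rho`), and the first gene of each block is the noiseless
"parent", the planted hub. Blocks 1-3 fall by d110 (most strongly in MS),
block 4 rises — so blocks pass the DEP and sub-model-1 gates and carry the
biology the network stage expects, while between-block correlations
(~0.5-0.8, shared pattern against independent factor noise) stay safely
below the 0.98 threshold.

What the generator does **not** emulate: probe-level technical artifacts
(dye bias, spatial effects), heavy-tailed intensity noise,
annotation errors, heterogeneous per-gene litter correlations, and
realistic gene-gene correlation beyond the planted blocks. Passing tests
therefore demonstrate correctness and calibration of the statistical
machinery under the design's correlation structure, not robustness to
microarray artifacts.

Ct tables use `Ct = 32 - log_E(2^y) + N(0, 0.2^2)` with per-gene
E ~ U(1.8, 2.0), a stable reference gene at the baseline mean, and a
4-point (1, 1/2, 1/4, 1/8) standard curve per gene.

All randomness flows from a single integer seed through named
sub-streams, so every artifact is byte-reproducible.

## Numerical and edge-case choices

* Quantile normalization: ties receive the mean of the sorted-row means
  over the tied ranks (deterministic, permutation-invariant). Idempotence
  and the equal-multiset property hold exactly for tie-free columns; with
  ties they hold up to tie-averaging. The pipeline assumes log2 input and
  normalizes on the supplied scale (normalize-then-log2 when raw
  intensities are supplied with `normalize: true`).
* PCA: variables (probes) centered, not scaled; components truncated to the
  rank with a warning.
* Largest-component ties break toward the component containing the
  lexicographically smallest node id; hub-table ties break by gene id.
* Degenerate probes (zero residual variance) are flagged, never tested.
* The parental "both" call is reported as such — the overlap of the
  maternal and paternal lists is exposed rather than assigned to one side.

## Problem sizes

Default test and acceptance runs use the study-scale design (~63 fetuses)
with 550-5,000 genes per experiment, 50 replicates for family-wise error,
250 genes per class for recovery, and exhaustive oracles up to 12 nodes /
universe 12 — sizes chosen so each property is measured with adequate
precision while the whole suite remains quick on a single CPU.
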