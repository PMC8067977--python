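# Methods

This note documents the models and procedures implemented in
`tec_coexnet`, the parameters that matter, the numerical choices, and what
the synthetic-data generator does and does not emulate.

## Study design and synthetic data

The package targets a paired 2×2 design: each subject contributes up to
four cell fractions — origin ∈ {non-tumour, tumour} crossed with
angiogenic activation ∈ {ENG−, ENG+} — with fraction-specific
missingness.  The generator's defaults mirror the emulated cohort: 16
subjects, per-fraction missing probabilities (1/16, 1/2, 2/16, 10/16)
chosen so the used-array counts are (15, 8, 14, 6), i.e. 43 of 48 arrays.
Missingness is applied as an exact count by default (`missingness="exact"`,
exactly `round(p·n)` fractions dropped at random), which reproduces the
design pattern deterministically; `"bernoulli"` draws independently per
(subject, fraction).

Expression is generated in log2 units.  Module m has a latent eigengene

    e_m(sample) = β1_m·origin + β2_m·activation + b_subject + ε,

with `b_subject ~ N(0, subject_sd²)` (default 0.5) shared across a
subject's fractions and `ε ~ N(0, eigengene_sd²)` (default 1.0) per
sample.  The `eigengene_sd` term is essential: without it a module with
zero planted effects would carry no shared variation and could never be
detected.  A module gene is

    baseline + loading·e_m + N(0, noise_sd²),

with the baseline drawn from the expressed Gaussian
(`background_high_mean` = 8, SD 1), loadings uniform in [0.7, 1.0] and
`noise_sd` = 0.3.  Background genes draw their baseline from a low/high
bimodal mixture (means 4 and 8, weight 0.5 high): the low component is the
unexpressed background the mixture filter must remove; the high component
supplies expressed-but-uncorrelated noise genes that module detection must
leave unassigned.  Outlier arrays are generated by replacing the entire
sample with i.i.d. noise, which destroys inter-sample correlation — the
exact quantity the zK statistic detects — rather than mean-shifting, which
it would not.

Default module sizes (40, 60, 80, 100, 120, 100) plus 1500 background
genes give a 2000-gene, 43-array dataset that runs through the full
pipeline in well under a minute; effect sizes (origin: 2, 0, −1.5, 1, 0, 1;
activation: 0, 1.5, 0.5, 0, −1, 1 log2 units on the eigengene) cover
origin-only, activation-only, mixed and null modules.  Effect magnitudes
are chosen for test power, not biological realism — the emulated study
reports none.  One integer seed drives all randomness through spawned
sub-streams (cohort, expression, gene sets), so outputs are bit-identical
under a fixed seed.

What the generator does **not** emulate: probe-level structure and
normalisation artifacts, batch effects, heavy-tailed and gene-specific
noise, correlated background genes, mean–variance coupling, and realistic
gene-set overlap structure.  Passing tests therefore demonstrate the
correctness and calibration of the procedures under the stated generative
model, not their performance on real microarray data.

## Preprocessing

*Probe summarisation* keeps, per gene, the probe with the maximal
interquartile range across samples (ties broken by lexicographic probe
id).

*Two-Gaussian filter.* The pooled log2 intensities are fitted with a
2-component Gaussian mixture by EM (k-means initialisation with a fixed
seed, ≤500 iterations, tolerance 1e−8, free means/variances/weights).  The
filter threshold is the smallest point between the component means where
the posterior probability of the high (expressed) component reaches 0.5,
located by a 2001-point grid scan refined with Brent root finding; for the
symmetric equal-weight mixture N(3,1)+N(8,1) this reproduces the analytic
midpoint 5.5.  A gene is retained if its **maximum** over samples clears
the threshold (a gene expressed in any sample is kept), making the filter
idempotent.

*Outlier arrays.* k_i = Σ_{j≠i} cor(sample_i, sample_j) (Pearson by
default), zK = (k − mean k)/sd(k).  Exclusion is one-sided, zK < −1.96:
only *low* connectivity indicates a disconnected array; the two-sided rule
is available (`one_sided=False`).  Constant samples get zero correlations
with a warning; if sd(k) vanishes (all samples identical up to float
jitter) no outliers are called.  The pipeline removes outlier arrays
*before* the mixture fit and gene filter — a pure-noise array at the
expressed level would otherwise lift every gene's maximum above the
threshold and void the filter.

## Differential expression

The model is `expression ~ 0 + group` with the four-level group factor
(NECneg, NECpos, TECneg, TECpos) and subjects as blocks.

*Consensus correlation.* Per gene, the within-subject intraclass
correlation of a random-intercept model is estimated on the residuals from
the group-means fit by profiled REML, vectorised over a 241-point grid on
ρ ∈ (−0.2, 0.99) with parabolic refinement; the consensus is the 10%
trimmed mean on the Fisher-z scale, clamped to (−0.99, 0.99).  This is the
same estimand as limma's `duplicateCorrelation` without its boosting
refinements.

*GLS.* With equicorrelation ρ inside blocks, the per-block whitening
matrix has the closed form
`(1−ρ)^{-1/2}(I − J/m) + (1+(m−1)ρ)^{-1/2} J/m`; all genes are whitened
once and fitted by OLS.

*Moderation.* The variance prior (d0, s0²) is fitted by moment matching on
log s² with digamma/trigamma corrections (Newton inversion of the
trigamma); posterior variances are the usual (d0·s0² + df·s²)/(d0 + df),
moderated t uses df + d0 degrees of freedom (normal when d0 = ∞, which
arises when the observed log-variance spread does not exceed its
theoretical chi-square value).  Sample variances are floored at 1e−12;
with fewer than 10 genes the prior is unstable and the code falls back to
d0 = 0 (ordinary t) with a warning.  Agreement with limma's
`lmFit`/`eBayes` at a fixed correlation is at machine precision (tested).

*Multiple testing* is Benjamini–Hochberg by default; Hochberg's step-up is
available because the emulated workflow names both.  DE calls use
|log2FC| > 2 and adjusted p < 0.05.

## Gene-set variation scoring

Per gene, expression is normalised across samples by a Gaussian-kernel CDF
(`mean_k Φ((x_j − x_k)/h)`, bandwidth h = SD/4).  Per sample, genes are
ranked by the kernel score; the statistic carried forward is the signed
centred rank r − (p+1)/2, whose magnitude is the walk weight (τ = 1) and
whose sign orders the walk.  The set score is the sum of the largest
positive and most negative deviations of the weighted random walk
(inside-set steps add normalised |r|^τ, outside steps subtract a uniform
decrement), bounded in [−1, 1].  A set covering the entire universe has no
outside-set contrast and is scored 0; sets overlapping the universe in
fewer than 2 genes are dropped.  Scores are invariant to gene order and to
per-gene monotone transforms (rank-based), and the set/complement score
signs oppose in ~90% of random samples — approximately, not exactly,
because the max+min statistic is not an odd function of the walk.

Differential pathway analysis reuses the moderated GLS machinery on the
score matrix, with the consensus correlation re-estimated on the scores so
subject pairing is carried through.  Under the generator defaults the
power to flag a planted set at FDR 0.05 (16 subjects) is ≈0.44 at a unit
eigengene effect and ≈0.98 at twice that — the score compresses effects,
so unit effects on a noisy eigengene sit near the detection boundary.

## Co-expression network

*Correlation.* Biweight midcorrelation: median-centred values weighted by
`(1−u²)²` for |u| < 1, u = (x − median)/(9·MAD); a row with zero MAD falls
back to Pearson standardisation.  Implemented as row-normalised matrix
products, so the full gene-gene matrix is one BLAS call.

*Adjacency and TOM.* Signed soft-thresholding `((1+c)/2)^β` with β = 12
(given, not tuned by scale-free fit), unit diagonal; topological overlap
`TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)`.

*Module detection.* Average-linkage clustering of 1 − TOM, cut at a
quantile of the merge heights (deepsplit ∈ 0..4 maps to quantiles 0.999,
0.995, 0.99, 0.98, 0.95); clusters below `min_module_size` = 30 dissolve.
A single global cut is too blunt when uncorrelated genes dominate: noisy
merges accumulate at the top of the tree and modules fuse below the cut.
Any cluster whose median module membership (kME, correlation with its own
eigengene) falls below the 0.8 threshold is therefore re-split recursively
on its own subtree with a progressively lower quantile (halving the
retained top-merge mass per level, floored at 0.5, ≤6 levels):
heterogeneous branches separate, pure-noise branches dissolve, and
coherent modules are never re-split.  With the PAM stage on, unassigned
genes are adopted by the best-matching eigengene when kME ≥ 0.8.
`mm_prune_threshold=0` disables both the coherence recursion and pruning,
reducing the iterative algorithm to a single detection pass.

*Eigengenes.* First right singular vector of the gene-standardised module
submatrix, scaled to unit sample variance and oriented so the mean
correlation with the module's genes is non-negative.  Note that this
orientation follows the genes: flipping the sign of every module gene
flips the oriented eigengene with them.

*Iteration.* Build the network on currently assigned genes → detect →
compute each gene's kME against its own eigengene → prune genes below 0.8
(and dissolve modules that fall below the minimum size) → repeat until the
assignment recurs or `max_iterations` = 10.  Afterwards pooled genes are
re-adopted by any module at kME ≥ 0.8, best first.  The reported kME
matrix is computed against the converged eigengenes, so every surviving
module's median kME clears the threshold by construction.  No eigengene-
similarity merge step is performed.  Dense matrices cap the gene count at
20,000 by configuration.

## Eigengene–trait association

Per module, the random-intercept model
`y = β0 + β1·origin + β2·activation + b_subject + ε` (traits coded 0/1) is
fitted by REML, profiled over the variance ratio with closed-form
per-block algebra; a boundary check at γ = 0 handles vanishing subject
variance (flagged singular below 1e−10 of the total).  t-tests use
Satterthwaite degrees of freedom: the gradient of the contrast variance
and the REML information are obtained by central finite differences
(relative step 1e−4) and df = 2·var_c²/(gᵀ·cov(θ̂)·g), clipped to
[1, 1e8].  Agreement with lme4/lmerTest is ~1e−6 in t and ~1e−2 in df
(tested); null calibration over 500 simulated cohorts gives type-I error
≈0.05 with uniform p-values.  BH adjustment is applied across modules,
separately per trait.

Module selection is strict: median |kME| > 0.8.  Intramodular connectivity
kWithin_i sums a gene's adjacencies to its own module; kWithin.norm
divides by the module maximum; hubs are the top `ceil(0.1·size)` genes by
normalised connectivity, ties broken by gene id for determinism.  Pairwise
group comparisons of eigengenes use Student's t with BH within module.
Druggability is a case-insensitive left join against a user-supplied
gene→drug table (no live database queries).

## Enrichment and term reduction

Annotations are closed over is_a and part_of ancestors before counting.
Terms annotating 15–500 background genes (inclusive; background = all
analysed genes) are tested with the one-sided hypergeometric upper tail;
BH < 0.05 defines significance.  Wang similarity computes semantic
S-values by dynamic programming over the ancestor sub-DAG (edge weights
0.8 is_a / 0.6 part_of, strongest edge kept between a pair).  Significant
terms are embedded in 2-D from 1 − similarity and clustered with DBSCAN
(ε = 0.6, minPts = 5 in embedded space); each cluster's representative is
its largest −log10(adjusted p) member, ties to the smaller term id; noise
points (cluster −1) stand alone.  Two embeddings are provided: UMAP
(workflow default; `init="random"` because the spectral initialisation is
not reproducible across calls even when seeded) and classical metric
scaling (`embedding="mds"`), which is deterministic and exactly
order-equivariant — structural tests use the latter since stochastic
embeddings make cluster topology seed-dependent.  With fewer significant
terms than minPts, every term is noise and its own representative.

## Pipeline

`run_pipeline` executes simulate → preprocess (zK, then mixture filter) →
differential expression → set scoring → iterative network → association →
enrichment, persisting every intermediate as TSV/JSON and logging
gene/sample counts after each filter.  The manifest records the package
version, the full configuration (with the output directory blanked — it
is a run location, not scientific configuration) and SHA256 hashes of
external inputs; identical configs and seeds reproduce every output byte
for byte.  The association stage refuses to run without network outputs.

## Problem sizes used in tests

Desk-scale fixtures use 8-subject cohorts with 2 planted modules
(~200–400 genes); recovery and calibration studies use the full design
(16 subjects, 43 arrays, 2000 genes, 20 replicate cohorts; 500 null
simulations for calibration).  These sizes keep the whole suite in the
low minutes on one CPU while leaving the planted-module recovery and
calibration claims statistically meaningful.

## Known limitations

- The tree cut is a simplified hybrid, not a port of the published dynamic
  hybrid algorithm; contracts are planted-module recovery, not cut-tree
  identity with WGCNA.
- The consensus-correlation estimator is simpler than limma's; estimates
  agree closely in simulation but are not numerically identical.
- Wang similarity and enrichment operate on a user-supplied OBO subset;
  obsolete terms, alt_ids and other relationship types are not handled.
- GSVA scores use the Gaussian kernel only (continuous log2 data); no
  Poisson kernel for counts.
- Dense network algebra: memory grows quadratically in genes (capped at
  20k).
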