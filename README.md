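# tec-coexnet

Co-expression network analysis of paired tumour / non-tumour liver
endothelial transcriptomes — and of any expression study with the same
paired 2×2 design.

Hepatocellular carcinoma studies that sort endothelial cells from tumour
and adjacent non-tumour tissue, with and without an angiogenic-activation
marker (endoglin / *ENG* / CD105), produce a paired design: up to four
arrays per patient (origin × activation), with some fractions missing.
This package implements the full analysis chain for such data as a tested,
reusable library with a CLI:

1. **Preprocessing** — probe→gene summarisation by maximal IQR; a
   two-Gaussian mixture fit to the pooled log2 intensities whose
   posterior-0.5 crossing defines the low-expression threshold; removal of
   outlier arrays by z-normalised inter-sample connectivity
   (zK < −1.96 by default).
2. **Differential expression** — per-gene GLS under a consensus
   within-subject correlation, empirical-Bayes variance moderation
   (moderated t), Benjamini–Hochberg control, DE at |log2FC| > 2 and
   adjusted p < 0.05.
3. **Single-sample gene-set scoring** — Gaussian-kernel CDF normalisation
   per gene, Kolmogorov–Smirnov-like weighted random walk per sample and
   set, and the same moderated linear model on the score matrix.
4. **Network** — signed weighted co-expression network from the biweight
   midcorrelation, `a_ij = ((1 + bicor_ij)/2)^β` with β = 12, topological
   overlap smoothing, average-linkage clustering with a quantile height
   cut, and *iterative* module detection that prunes genes with module
   membership kME < 0.8 and repeats until the assignment stabilises.
5. **Association** — per-module random-intercept mixed model
   `y = β0_subject + β1·origin + β2·activation + ε` fitted by REML with
   Satterthwaite-approximated t-tests (verified against lme4/lmerTest);
   module selection by median |kME| > 0.8; intramodular connectivity
   kWithin, its module-max-normalised form, top-10% hub genes, and a local
   gene→drug lookup.
6. **Enrichment** — hypergeometric GO over-representation against the
   analysed gene universe (term sizes 15–500, BH < 0.05), Wang semantic
   similarity, seeded 2-D embedding (UMAP or classical scaling) with
   DBSCAN (ε = 0.6, minPts = 5), one representative term per cluster.

A first-class synthetic-data generator emulates the study design (16
subjects, 43 of 48 arrays used, bimodal expression background, planted
co-expression modules with origin/activation effects on their eigengenes,
low-connectivity outlier arrays), so every stage is testable end to end
without downloading anything.

## Worked example

```python
from tec_coexnet import (SimulationConfig, simulate_cohort, simulate_expression,
                         fit_two_gaussian, filter_low_expression, sample_outliers,
                         NetworkConfig, iterative_wgcna, fit_eigengene_model)

cfg = SimulationConfig(seed=1, n_outlier_samples=2)
annotation = simulate_cohort(cfg)
X, truth = simulate_expression(cfg, annotation)

report = sample_outliers(X)
X = X.drop(columns=report.excluded_samples)
annotation = annotation[~annotation.sample_id.isin(report.excluded_samples)]

fit = fit_two_gaussian(X.to_numpy().ravel(), seed=1)
X = filter_low_expression(X, fit)

assignment, eigengenes, kme = iterative_wgcna(X, NetworkConfig())
result = fit_eigengene_model(eigengenes, annotation)
print(result.table[["beta1", "t1", "p1_adj", "beta2", "t2", "p2_adj"]].round(3))
```

prints

```
cohort: 43 arrays from 16 subjects
zK outliers removed: ['P04_N0', 'P11_T0']
expression threshold 5.66; 1375 genes retained
modules: {'M1': 120, 'M2': 100, 'M3': 100, 'M4': 80, 'M5': 60, 'M6': 40}
        beta1     t1  p1_adj  beta2     t2  p2_adj
module
M1      0.068  0.220   0.827 -0.532 -1.627   0.159
M2      0.335  1.301   0.245  0.433  1.547   0.159
M3      0.489  2.067   0.098  0.939  3.634   0.004
M4     -0.906 -4.450   0.000  0.547  2.442   0.042
M5     -0.364 -1.924   0.098  1.406  6.816   0.000
M6      1.502  8.579   0.000 -0.193 -1.022   0.315
```

The two planted outlier arrays are exactly the ones zK flags, the mixture
threshold separates the unexpressed background (the generator plants
components at 4 and 8 log2 units), and the six detected modules match the
six planted ones gene for gene.  `beta1` is the tumour-vs-non-tumour
effect and `beta2` the activation effect on each unit-variance module
eigengene, with BH-adjusted Satterthwaite p-values: module M6 here is the
planted strongly origin-driven module, M5 the activation-driven one
(module names order by size, so they permute the planted labels).

The same pipeline runs from the shell:

```bash
tec-coexnet simulate --seed 1 --out demo
tec-coexnet preprocess --expr demo/expression.tsv --out demo/prep
tec-coexnet network --expr demo/prep/expression_filtered.tsv --out demo/net
tec-coexnet associate --eigengenes demo/net/eigengenes.tsv --annot demo/annotation.tsv --out demo/assoc
```

or end to end from a YAML config with `tec-coexnet run --config pipeline.yaml`,
which persists every intermediate plus a manifest sufficient to reproduce
the run byte for byte.

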