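# radar-merip

Differential RNA methylation analysis for MeRIP-seq (m6A-seq) data.

A MeRIP-seq experiment yields, for every sample, a paired **INPUT**
library (RNA fragments before antibody pull-down, measuring expression)
and an **IP** library (fragments captured by the anti-m6A antibody,
measuring methylated RNA abundance). Differential methylation (DM) is a
change in methylated abundance *conditional on* expression, so neither
ordinary RNA-seq differential-expression tools nor single-channel peak
comparisons answer the question. This package detects DM loci by:

1. **Counting** — concatenated exons of each gene are tiled with 50-nt
   bins; INPUT and IP fragments are assigned to the bin containing their
   transcript-coordinate midpoint, and INPUT bins are summed into a
   gene-level count (*geneSum*), a robust expression proxy.
2. **Normalization** — INPUT samples get median-of-ratios size factors;
   IP samples get size factors from the fold enrichment
   E<sub>ij</sub> = t<sub>ij</sub>/s<sub>gene(i),j</sub> of the top 1%
   most IP-covered bins, capturing both depth and IP-efficiency
   differences. Normalized IP counts are divided by a gene-wise
   expression factor (normalized geneSum centered to 1), leaving
   adjusted counts Y that reflect methylation alone.
3. **Testing** — per bin, Y<sub>i</sub> ~ Poisson(λ<sub>i</sub>) with

       log λ_i = μ + X0 β0 + Σ_j Xj βj + e_i,   e_i = log w_i,  w_i ~ Gamma(ψ, ψ),

   a Poisson regression with a mean-1 multiplicative gamma random
   effect; the marginal is negative binomial with shape ψ. The marginal
   likelihood is maximized by gradient ascent with a backtracking line
   search (ψ on the log scale), and H0: β0 = 0 is tested with a Wald
   statistic whose standard error comes from the observed Fisher
   information. Covariates (batch, age, ...) enter the design directly.
   P-values are Benjamini–Hochberg adjusted.
4. **Reporting** — adjacent significant bins are merged into peaks and
   mapped back through the exon structure to genome coordinates as
   BED12 (multi-block records for intron-spanning peaks).

The package also ships the simulation generators and benchmark harness
used to characterize the method: a random-effect generator (the model
above, with per-bin μ and ψ drawn from parametric distributions), a
negative-binomial generator with inflated IP dispersion, a pooled-count
Fisher's-exact-test comparator, and a power-vs-replicates sweep.

## Worked example

```python
import numpy as np
from radar import simulate_radar_model, run_dm_test, evaluate

ds = simulate_radar_model(n_bins=2000, n_samples=8, truth_frac=0.2,
                          beta0=1.0, seed=12)
res = run_dm_test(ds.enrichment, ds.design_matrix())
sens, fdr = evaluate(res, ds.truth, cutoff=0.1)
print(f"sensitivity {sens:.2f}  empirical FDR {fdr:.2f}")
print(res[["beta0", "se", "z", "p", "padj"]].head(3).round(3))
```

prints (400 of the 2,000 bins carry a true log-effect of 1.0):

```
sensitivity 0.53  empirical FDR 0.33
   beta0     se      z      p   padj
0 -0.288  0.764 -0.377  0.707  0.899
1  0.600  0.419  1.430  0.153  0.435
2 -0.110  0.228 -0.482  0.630  0.854
```

`beta0` is the log fold change of methylation between groups; `padj`
is the BH-adjusted Wald p-value. At this small-sample, high-dispersion
setting the test detects most strong sites while the realized FDR
reflects the difficulty of estimating a per-bin dispersion from eight
observations (see `docs/methods.md`).

The same machinery is exposed as scikit-learn-style estimators
(`PoissonGammaRegression`, `DifferentialMethylationTest`,
`EnrichmentNormalizer`) and as a CLI for BAM/SAM + GTF input:

```sh
radar count --gtf genes.gtf --sample-sheet samples.tsv --out counts/
radar test --counts counts/ --sample-sheet samples.tsv --covariates batch --out dm/
radar report --results dm/dm_results.tsv --gtf genes.gtf --fdr 0.1 --out peaks/
radar simulate --model radar --beta0 0.75 --n 8 --bins 26324 --out sim/
radar benchmark --data sim/ --with-fisher --out bench/
```

The sample sheet is a TSV with columns `sample`, `input_bam`, `ip_bam`,
`group` and any covariate columns.

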