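# seedlong

Tools for analysing the **acquisition of seed longevity during late
maturation** from storage physiology and bulk RNA-seq, aimed at seed
biologists and quantitative plant scientists. The pipeline runs from
storage-viability curves and a gene × sample count matrix to a
trait-anchored transcription-factor (TF) co-expression module, stage-wise
differential expression and functional enrichment, with a seeded
synthetic-data generator providing planted ground truth for every stage.

## The science in brief

Soybean seeds acquire longevity — the ability to survive dry storage —
only after the end of seed filling. The package quantifies and connects
three layers:

* **Longevity (P50).** Seeds stored at 35 °C / 75 % RH lose viability
  along a sigmoid curve. Germination counts (4 replicates × 25 seeds per
  time point) are pooled and fitted by binomial maximum likelihood to
  G(t) = G₀ / (1 + exp((t − p₅₀)/s)); **P50** is the storage time at which
  germination falls to half its initial level (the logistic midpoint).
  Censoring and an interpolation fallback are handled explicitly.
* **Expression.** Counts are normalised by median-of-ratios size factors
  (geometric-mean-1 convention), log2(x+1) transformed, and filtered to
  genes with variance > 1. Differential expression is a
  negative-binomial Wald test with a pooled method-of-moments dispersion;
  a gene is significant when its fold change is at least two-fold
  (inclusive) and the BH-adjusted p-value is below α. Diagnostics include
  the pairwise sample-correlation matrix and median-centred PCA.
* **Network and trait anchoring.** TFs are connected when their profiles
  correlate at PCC ≥ 0.97 (positive correlations only; nodes need at
  least one edge). Each gene's **gene significance** is
  GS = |cor(stage-mean profile, P50 trajectory)|; the **longevity module**
  is the set of network nodes with GS > 0.9. Enrichment statistics cover
  χ² family enrichment, hypergeometric GO over/under-representation
  (BH and Bonferroni side by side), and bin-wise Wilcoxon tests whose
  Bonferroni-corrected p-values convert to signed z-scores
  (p = 0.05 ↔ |z| = 1.96). Contrast set algebra (Venn overlaps,
  chloroplast-gene shares) and 2^−ΔΔCt qPCR validation close the loop.

## Worked example

`examples/` contains one narrative script per capability. Building the TF
network on a synthetic dataset with a planted 27-TF longevity module
(`python examples/04_network_module.py`) prints:

```
129 TFs pass the variance filter
network: 109 nodes, 388 edges, 11 components
nodes per stage-of-max: {'7.2': 36, '7.3': 27, '9': 26, '8.1': 11, '7.1': 5, '8.2': 4}
longevity module (GS > 0.9): 27 TFs, 27 of the 27 planted module genes
module family composition: {'AP2/EREBP': 7, 'MADS': 3, 'WRKY': 3, ...}
```

Reading: of the TFs that vary during maturation, 109 are co-expressed
tightly enough (PCC ≥ 0.97) to enter the network; colouring nodes by their
stage of maximal expression recovers the temporal clusters (a transient
7.2–7.3 tail, a late 9-peaking group); and thresholding gene significance
at 0.9 recovers exactly the 27 planted longevity-tracking TFs, dominated
by the AP2/EREBP family. `examples/02_longevity_p50.py` likewise recovers
the planted P50 trajectory (0 → 28 → … → 48 d) to within a day per stage.

A thin CLI mirrors the library:
`seedlong simulate | p50 | expr | network | enrich | venn | qpcr`
(see `seedlong --help`).

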