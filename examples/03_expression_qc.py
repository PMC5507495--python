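"""Count-matrix QC, normalisation, filtering and sample diagnostics.

Reproduces the published library-mapping arithmetic, then normalises a
synthetic count matrix, applies the variance (> 1) filter, and runs the
sample correlation and median-centred PCA diagnostics plus one NB Wald
differential-expression contrast.
"""

from seedlong import (SimConfig, de_test, generate_expression_dataset,
                      library_qc, normalize_and_log, pca_median_centered,
                      sample_correlation_matrix, variance_filter)
from seedlong.datasets import soybean_library_reads

qc = library_qc(soybean_library_reads())
print(qc[["sample", "total_reads", "mapped_reads", "percent_mapped"]]
      .to_string(index=False))
print(f"minimum mapping rate: {qc.attrs['min_percent_mapped']}%\n")

counts, design, truth = generate_expression_dataset(SimConfig(seed=1))
norm = normalize_and_log(counts)
kept = variance_filter(norm)  # genes with log2 variance > 1
print(f"retained {len(kept)} of {len(counts)} genes (variance > 1)")

corr = sample_correlation_matrix(norm.log2.loc[kept])
print(f"replicate similarity 7.2aF/7.2bF: {corr.loc['7.2aF', '7.2bF']:.3f}")

coords, explained = pca_median_centered(norm.log2.loc[kept])
print(f"PC1 explains {100 * explained[0]:.0f}% of variance; sample order on PC1:")
print("  " + " < ".join(coords.sort_values('PC1').index))
# The dried-7.2 libraries fall between fresh 7.2 and 8.1: premature drying
# accelerates the maturation programme.

de = de_test(counts, design, ("7.2", "dried"), ("9", "fresh"), alpha=0.01)
up = de[de["significant"] & (de["log2fc"] > 0)]
down = de[de["significant"] & (de["log2fc"] < 0)]
print(f"9 vs 7.2D (fold >= 2, BH p < 0.01): {len(up)} up, {len(down)} down")
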