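"""Count-matrix QC, normalisation, filtering, differential expression and
sample-level diagnostics.

Normalisation is median-of-ratios (size factors rescaled to geometric mean
1) with a log2(normalised + pseudocount) layer on which per-gene variance,
the variance filter (strictly > 1 by default), the sample correlation
matrix and median-centred PCA operate.  Differential expression is a
negative-binomial Wald test with a single pooled dispersion (supplied, or
estimated by method of moments from replicated groups); genes are flagged
significant when the fold change is at least ``fold_threshold`` (inclusive)
and the BH-adjusted p-value is below ``alpha``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "library_qc",
    "size_factors",
    "normalize_and_log",
    "NormalizedMatrix",
    "variance_filter",
    "stage_means",
    "stage_ratio",
    "estimate_dispersion",
    "de_test",
    "sample_correlation_matrix",
    "pca_median_centered",
    "validate_design",
]

STAGE_LABELS = ("7.1", "7.2", "7.3", "8.1", "8.2", "8.3", "9")


def validate_design(design: pd.DataFrame, counts: pd.DataFrame | None = None) -> None:
    """Check sample-design invariants (unique ids, known stage labels,
    bijection with count-matrix columns)."""
    if design["sample"].duplicated().any():
        raise ValueError("sample ids must be unique")
    bad = set(design["stage"]) - set(STAGE_LABELS)
    if bad:
        raise ValueError(f"unknown stage labels: {sorted(bad)}")
    if counts is not None:
        if sorted(counts.columns) != sorted(design["sample"]):
            raise ValueError("count-matrix columns do not match design samples")
        if counts.index.duplicated().any():
            raise ValueError("duplicate gene ids in count matrix")


def library_qc(reads: pd.DataFrame) -> pd.DataFrame:
    """Mapping-rate arithmetic per library.

    ``reads`` needs columns sample, total_reads, mapped_reads.  Adds
    percent_mapped (one decimal) and attaches the minimum across libraries
    as ``result.attrs['min_percent_mapped']``.
    """
    df = reads.copy()
    if (df["total_reads"] <= 0).any():
        raise ValueError("total reads must be positive")
    if (df["mapped_reads"] > df["total_reads"]).any():
        raise ValueError("mapped reads cannot exceed total reads")
    pct = 100.0 * df["mapped_reads"] / df["total_reads"]
    df["percent_mapped"] = pct.round(1)
    df.attrs["min_percent_mapped"] = float(df["percent_mapped"].min())
    return df


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-gene geometric mean over samples, restricted to
    genes with all-positive counts; each sample's factor is the median of
    its count/reference ratios.
    """
    mat = counts.to_numpy(float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    logs = np.log(mat[positive])
    ref = logs.mean(axis=1)
    factors = np.exp(np.median(logs - ref[:, None], axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


class NormalizedMatrix:
    """Normalised counts plus a log2 layer and per-gene variance."""

    def __init__(self, normalized: pd.DataFrame, log2: pd.DataFrame,
                 factors: pd.Series, pseudocount: float):
        self.normalized = normalized
        self.log2 = log2
        self.factors = factors
        self.pseudocount = pseudocount
        self.gene_variance = log2.var(axis=1, ddof=1)


def normalize_and_log(counts: pd.DataFrame, factors: pd.Series | None = None,
                      pseudocount: float = 1.0) -> NormalizedMatrix:
    """Divide by size factors and build the log2(normalised + pc) layer."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if factors is None:
        factors = size_factors(counts)
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    normalized = counts / factors.reindex(counts.columns)
    log2 = np.log2(normalized + pseudocount)
    return NormalizedMatrix(normalized, log2, factors, pseudocount)


def variance_filter(norm: NormalizedMatrix, threshold: float = 1.0) -> pd.Index:
    """Genes whose log2-layer variance is strictly above ``threshold``."""
    return norm.gene_variance.index[norm.gene_variance > threshold]


def stage_means(values: pd.DataFrame, design: pd.DataFrame,
                treatment: str = "fresh") -> pd.DataFrame:
    """Per-stage replicate means (genes x stages, stages ordered by DAF).

    ``values`` is any genes x samples layer (normalised or log2).
    """
    sub = design[design["treatment"] == treatment]
    order = (sub[["stage", "daf"]].drop_duplicates()
             .sort_values("daf")["stage"].tolist())
    out = {}
    for stage in order:
        cols = sub.loc[sub["stage"] == stage, "sample"]
        out[stage] = values[list(cols)].mean(axis=1)
    return pd.DataFrame(out)


def stage_ratio(norm: NormalizedMatrix, design: pd.DataFrame,
                pseudocount: float = 0.0) -> pd.DataFrame:
    """Per-gene expression ratios of consecutive fresh stages (n+1 over n).

    Replicates are averaged per stage on the linear normalised scale first.
    An optional pseudocount guards against zero denominators.
    """
    means = stage_means(norm.normalized, design, "fresh")
    if means.shape[1] < 2:
        raise ValueError("need at least 2 stages for stage ratios")
    cols = list(means.columns)
    out = {}
    for a, b in zip(cols, cols[1:]):
        out[f"{b}/{a}"] = (means[b] + pseudocount) / (means[a] + pseudocount)
    return pd.DataFrame(out)


def estimate_dispersion(counts: pd.DataFrame, design: pd.DataFrame,
                        factors: pd.Series | None = None,
                        min_mean: float = 5.0) -> float:
    """Pooled NB dispersion by method of moments over replicated groups.

    For each (stage, treatment) group with >= 2 replicates and each gene,
    the within-group mean m and variance v of normalised counts satisfy
    E[v] = c*m + alpha*m^2 with c the group mean of 1/size_factor.  Alpha is
    estimated as the ratio of sums sum(v - c*m) / sum(m^2), which is stable
    where per-gene moment estimates (1 df at n=2) are not.
    """
    if factors is None:
        factors = size_factors(counts)
    normalized = counts / factors.reindex(counts.columns)
    num = 0.0
    den = 0.0
    for _, grp in design.groupby(["stage", "treatment"]):
        cols = list(grp["sample"])
        if len(cols) < 2:
            continue
        sub = normalized[cols]
        m = sub.mean(axis=1).to_numpy()
        v = sub.var(axis=1, ddof=1).to_numpy()
        c = float(np.mean(1.0 / factors[cols].to_numpy()))
        keep = m >= min_mean
        num += float(np.sum(v[keep] - c * m[keep]))
        den += float(np.sum(m[keep] ** 2))
    if den == 0.0:
        raise ValueError("no replicated groups available to estimate dispersion")
    return max(num / den, 1e-8)


def de_test(counts: pd.DataFrame, design: pd.DataFrame,
            group_a, group_b,
            factors: pd.Series | None = None,
            dispersion: float | str = "moments",
            fold_threshold: float = 2.0, alpha: float = 0.05) -> pd.DataFrame:
    """NB Wald test of group B vs group A.

    ``group_a``/``group_b`` are either lists of sample ids or (stage,
    treatment) pairs resolved through ``design``.  The log2 fold change is
    the ratio of mean normalised counts; its Wald standard error uses the
    NB mean-variance relation with the pooled dispersion.  ``significant``
    requires a fold change of at least ``fold_threshold`` (inclusive, i.e.
    ratio >= threshold or <= 1/threshold) and BH-adjusted p < ``alpha``.
    """
    def resolve(group) -> list[str]:
        if isinstance(group, tuple) and len(group) == 2 and group[0] in STAGE_LABELS:
            stage, trt = group
            cols = design.loc[(design["stage"] == stage)
                              & (design["treatment"] == trt), "sample"].tolist()
        else:
            cols = list(group)
        unknown = set(cols) - set(counts.columns)
        if unknown or not cols:
            raise ValueError(f"contrast references unknown samples: {sorted(unknown)}")
        return cols

    cols_a, cols_b = resolve(group_a), resolve(group_b)
    if factors is None:
        factors = size_factors(counts)
    if dispersion == "moments":
        disp = estimate_dispersion(counts, design, factors)
    else:
        disp = float(dispersion)
    if disp <= 0:
        raise ValueError("dispersion must be positive")

    s_a = factors[cols_a].to_numpy()
    s_b = factors[cols_b].to_numpy()
    norm_a = counts[cols_a].to_numpy(float) / s_a[None, :]
    norm_b = counts[cols_b].to_numpy(float) / s_b[None, :]
    # Half a normalised count keeps zero-mean genes finite without shifting
    # well-expressed genes.
    eps = 0.5 * float(np.mean(1.0 / np.concatenate([s_a, s_b])))
    qa = norm_a.mean(axis=1) + eps
    qb = norm_b.mean(axis=1) + eps
    var_ln_a = np.add.reduce(1.0 / (qa[:, None] * s_a[None, :]) + disp, axis=1) / len(cols_a) ** 2
    var_ln_b = np.add.reduce(1.0 / (qb[:, None] * s_b[None, :]) + disp, axis=1) / len(cols_b) ** 2
    wald = np.log(qb / qa) / np.sqrt(var_ln_a + var_ln_b)
    pvals = 2.0 * stats.norm.sf(np.abs(wald))
    log2fc = np.log2(qb / qa)
    padj = multipletests(pvals, method="fdr_bh")[1]
    significant = (np.abs(log2fc) >= np.log2(fold_threshold)) & (padj < alpha)
    return pd.DataFrame({
        "base_mean_a": qa - eps, "base_mean_b": qb - eps,
        "log2fc": log2fc, "wald": wald, "pvalue": pvals, "padj": padj,
        "significant": significant,
    }, index=counts.index)


def sample_correlation_matrix(log2_values: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation between samples (on the log2 layer)."""
    if log2_values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sd = log2_values.std(axis=0)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"samples with zero variance: {bad}")
    corr = np.corrcoef(log2_values.to_numpy(float), rowvar=False)
    return pd.DataFrame(corr, index=log2_values.columns, columns=log2_values.columns)


def pca_median_centered(log2_values: pd.DataFrame, n_components: int = 2
                        ) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of per-gene median-centred transcriptomes.

    Returns (sample coordinates on the leading PCs, explained-variance
    fractions).  The sign of each component is fixed so that its
    largest-magnitude gene loading is positive.
    """
    if log2_values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    centered = log2_values.sub(log2_values.median(axis=1), axis=0)
    x = centered.to_numpy(float).T  # samples x genes
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    for i in range(k):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    coords = u[:, :k] * s[:k]
    total = np.sum(x ** 2)
    explained = s ** 2 / total if total > 0 else np.zeros_like(s)
    cols = [f"PC{i+1}" for i in range(k)]
    return (pd.DataFrame(coords, index=log2_values.columns, columns=cols),
            explained[:k])
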