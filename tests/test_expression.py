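"""Normalisation, filtering, differential expression and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from seedlong import (de_test, library_qc, normalize_and_log,
                      pca_median_centered, sample_correlation_matrix,
                      size_factors, stage_ratio, variance_filter)
from seedlong.expression import estimate_dispersion, stage_means, validate_design


def toy_counts(data, samples=None):
    df = pd.DataFrame(data)
    if samples:
        df.columns = samples
    df.index = [f"g{i}" for i in range(len(df))]
    return df


# ---------------------------------------------------------------- library QC

def test_library_qc_percentages():
    reads = pd.DataFrame({
        "sample": ["a", "b", "c"],
        "total_reads": [25_673_031, 38_088_839, 100],
        "mapped_reads": [24_112_015, 34_971_702, 100],
    })
    qc = library_qc(reads)
    assert list(qc["percent_mapped"]) == [93.9, 91.8, 100.0]
    assert qc.attrs["min_percent_mapped"] == 91.8
    bad = reads.assign(mapped_reads=[1, 1, 101])
    with pytest.raises(ValueError):
        library_qc(bad)


# -------------------------------------------------------------- size factors

def test_size_factors_identical_libraries_are_one():
    counts = toy_counts(np.tile([[5], [10], [20]], (1, 4)))
    assert np.allclose(size_factors(counts), 1.0)


def test_size_factors_two_sample_closed_form():
    rng = np.random.default_rng(0)
    a = rng.integers(10, 1000, 50)
    counts = toy_counts(np.column_stack([a, 2 * a]), ["A", "B"])
    f = size_factors(counts)
    assert f["A"] == pytest.approx(1 / np.sqrt(2), rel=1e-9)
    assert f["B"] == pytest.approx(np.sqrt(2), rel=1e-9)


def test_size_factors_permutation_equivariant():
    rng = np.random.default_rng(1)
    counts = toy_counts(rng.integers(1, 500, (40, 4)), list("ABCD"))
    f = size_factors(counts)
    g = size_factors(counts[["C", "A", "D", "B"]])
    assert np.allclose(f[g.index], g)


def test_size_factors_require_a_common_positive_gene():
    counts = toy_counts([[0, 5], [5, 0]])
    with pytest.raises(ValueError):
        size_factors(counts)


# -------------------------------------------------------------- normalisation

def test_normalize_and_log_variance():
    counts = toy_counts(np.tile([[8]], (1, 3)), list("ABC"))
    norm = normalize_and_log(counts, pd.Series(1.0, index=list("ABC")))
    assert norm.gene_variance.iloc[0] == 0.0
    # log2 values {0, 2, 4}: sample variance (n-1 denominator) is 4.
    counts = toy_counts([[0, 3, 15]], list("ABC"))
    norm = normalize_and_log(counts, pd.Series(1.0, index=list("ABC")))
    assert norm.gene_variance.iloc[0] == pytest.approx(4.0)


def test_normalize_scale_cancellation():
    rng = np.random.default_rng(2)
    counts = toy_counts(rng.integers(0, 100, (20, 3)), list("ABC"))
    f = pd.Series([0.5, 1.0, 2.0], index=list("ABC"))
    a = normalize_and_log(counts, f)
    b = normalize_and_log(2 * counts, 2 * f)
    assert np.allclose(a.normalized, b.normalized)
    with pytest.raises(ValueError):
        normalize_and_log(counts, f, pseudocount=0.0)


def test_normalization_removes_library_scaling_up_to_global_factor():
    rng = np.random.default_rng(3)
    counts = toy_counts(rng.integers(1, 500, (60, 4)), list("ABCD"))
    a = normalize_and_log(counts).normalized
    scaled = counts.copy()
    scaled["B"] = scaled["B"] * 3
    b = normalize_and_log(scaled).normalized
    ratio = (b / a).to_numpy()
    assert np.allclose(ratio, ratio.flat[0])


# ------------------------------------------------------------ variance filter

def test_variance_filter_strict_boundary():
    counts = toy_counts([[7, 7, 7]], list("ABC"))
    norm = normalize_and_log(counts, pd.Series(1.0, index=list("ABC")))
    assert len(variance_filter(norm)) == 0  # constant gene excluded
    # Craft a gene whose log2 variance is exactly 1.0: values {m-1, m+1, m}
    # have variance 1; strict inequality excludes it.
    log2_vals = np.array([3.0, 5.0, 4.0])
    counts = toy_counts([np.exp2(log2_vals) - 1], list("ABC"))
    norm = normalize_and_log(counts, pd.Series(1.0, index=list("ABC")))
    assert norm.gene_variance.iloc[0] == pytest.approx(1.0)
    assert len(variance_filter(norm, 1.0)) == 0
    assert len(variance_filter(norm, 0.99)) == 1


def test_variance_filter_on_synthetic_truth(dataset, norm):
    _, _, truth = dataset
    kept = set(variance_filter(norm))
    assert truth.module_genes <= kept
    assert truth.tail_genes <= kept
    assert not (truth.reference_genes & kept)


# ---------------------------------------------------------------- stage ratio

def test_stage_ratio_toy():
    design = pd.DataFrame({
        "sample": ["s1", "s2", "s3", "s4"],
        "stage": ["7.1", "7.1", "7.2", "7.3"],
        "daf": [57, 57, 63, 69],
        "treatment": "fresh",
        "replicate": [1, 2, 1, 1],
    })
    counts = toy_counts([[3, 5, 8, 2], [4, 4, 4, 4], [2, 2, 4, 8]],
                        ["s1", "s2", "s3", "s4"])
    norm = normalize_and_log(counts, pd.Series(1.0, index=counts.columns))
    ratios = stage_ratio(norm, design)
    # Replicates averaged first: stage means (4, 8, 2) -> ratios (2.0, 0.25).
    assert list(ratios.columns) == ["7.2/7.1", "7.3/7.2"]
    assert ratios.iloc[0].tolist() == pytest.approx([2.0, 0.25])
    assert ratios.iloc[1].tolist() == pytest.approx([1.0, 1.0])  # flat gene
    assert ratios.iloc[2].tolist() == pytest.approx([2.0, 2.0])  # doubling


# -------------------------------------------------------------------- DE test

def two_group_design():
    return pd.DataFrame({
        "sample": ["A1", "A2", "B1", "B2"],
        "stage": ["7.2", "7.2", "9", "9"],
        "daf": [63, 63, 77, 77],
        "treatment": "fresh",
        "replicate": [1, 2, 1, 2],
    })


def test_de_identical_groups_are_null():
    counts = toy_counts(np.tile([[100], [50], [200]], (1, 4)),
                        ["A1", "A2", "B1", "B2"])
    res = de_test(counts, two_group_design(), ["A1", "A2"], ["B1", "B2"],
                  factors=pd.Series(1.0, index=counts.columns), dispersion=0.05)
    assert np.allclose(res["log2fc"], 0.0)
    assert np.allclose(res["pvalue"], 1.0)
    assert not res["significant"].any()


def test_de_fold_boundary_is_inclusive():
    # Group-B mean chosen so the shifted ratio is exactly two-fold.
    counts = toy_counts([[1000, 1000, 2000, 2001]] + [[100, 100, 100, 100]] * 5,
                        ["A1", "A2", "B1", "B2"])
    res = de_test(counts, two_group_design(), ["A1", "A2"], ["B1", "B2"],
                  factors=pd.Series(1.0, index=counts.columns), dispersion=1e-4)
    assert res["log2fc"].iloc[0] == pytest.approx(1.0, abs=1e-9)
    assert bool(res["significant"].iloc[0])


def test_de_group_resolution_and_errors(dataset):
    counts, design, _ = dataset
    res = de_test(counts, design, ("7.2", "dried"), ("9", "fresh"),
                  dispersion=0.01, alpha=0.01)
    assert len(res) == len(counts)
    assert (res["padj"] >= res["pvalue"] - 1e-15).all()
    with pytest.raises(ValueError, match="unknown samples"):
        de_test(counts, design, ["nope"], ["9aF"], dispersion=0.01)
    with pytest.raises(ValueError, match="dispersion"):
        de_test(counts, design, ("7.2", "dried"), ("9", "fresh"), dispersion=-1)


def test_moment_dispersion_estimator(dataset):
    counts, design, _ = dataset
    alpha = estimate_dispersion(counts, design)
    assert 0.003 < alpha < 0.03  # generator default is 0.01


# ------------------------------------------------------------------ diagnostics

def test_sample_correlation_properties():
    rng = np.random.default_rng(4)
    log2 = pd.DataFrame(rng.normal(5, 2, (30, 3)), columns=list("ABC"))
    log2["D"] = log2["A"]  # duplicated sample
    corr = sample_correlation_matrix(log2)
    assert np.allclose(np.diag(corr), 1.0)
    assert corr.loc["A", "D"] == pytest.approx(1.0)
    assert np.allclose(corr, corr.T)
    # Direct PCC formula oracle on one pair.
    x, y = log2["A"].to_numpy(), log2["B"].to_numpy()
    r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
    assert corr.loc["A", "B"] == pytest.approx(r, abs=1e-12)
    # Perfectly reversed sample.
    log2["E"] = -log2["A"]
    assert sample_correlation_matrix(log2).loc["A", "E"] == pytest.approx(-1.0)
    with pytest.raises(ValueError, match="zero variance"):
        sample_correlation_matrix(log2.assign(F=1.0))


def test_pca_median_centering_and_replicates(dataset, norm):
    counts, design, _ = dataset
    kept = variance_filter(norm)
    log2 = norm.log2.loc[kept]
    coords, explained = pca_median_centered(log2)
    assert coords.shape == (10, 2)
    assert 0 < explained.sum() <= 1.0
    # Identical samples get identical coordinates.
    dup = log2[["7.1F", "7.1F"]].copy()
    dup.columns = ["x", "y"]
    c2, _ = pca_median_centered(dup)
    assert np.allclose(c2.loc["x"], c2.loc["y"])
    # Replicate pairs sit closer together than to any other stage.
    for pair in (("7.2aF", "7.2bF"), ("9aF", "9bF")):
        d_rep = np.linalg.norm(coords.loc[pair[0]] - coords.loc[pair[1]])
        others = [s for s in coords.index if s not in pair]
        d_min = min(np.linalg.norm(coords.loc[pair[0]] - coords.loc[o])
                    for o in others)
        assert d_rep < d_min


def test_validate_design(dataset):
    counts, design, _ = dataset
    validate_design(design, counts)
    with pytest.raises(ValueError, match="unique"):
        validate_design(pd.concat([design, design]))
    bad = design.copy()
    bad.loc[0, "stage"] = "11.9"
    with pytest.raises(ValueError, match="unknown stage"):
        validate_design(bad)
    with pytest.raises(ValueError, match="columns"):
        validate_design(design, counts.iloc[:, :5])


def test_stage_means_ordering(dataset, norm):
    _, design, _ = dataset
    means = stage_means(norm.log2, design, "fresh")
    assert list(means.columns) == ["7.1", "7.2", "7.3", "8.1", "8.2", "9"]
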