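"""Co-expression edges, temporal annotation, gene significance and module."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seedlong import (SimConfig, build_coexpression_graph,
                      extract_longevity_module, gene_pcc_edges,
                      gene_significance, generate_annotation_and_sugars,
                      generate_expression_dataset, network_summary,
                      normalize_and_log, variance_filter)
from seedlong.network import assign_stage_of_max


def seven_stage_design():
    stages = ["7.1", "7.2", "7.3", "8.1", "8.2", "8.3", "9"]
    return pd.DataFrame({
        "sample": [f"s{i}" for i in range(7)],
        "stage": stages,
        "daf": [57, 63, 69, 71, 73, 75, 77],
        "treatment": "fresh",
        "replicate": 1,
    })


P50_7 = {"7.1": 0, "7.2": 28, "7.3": 30, "8.1": 35, "8.2": 40, "8.3": 44, "9": 48}


# ----------------------------------------------------------------- PCC edges

def test_edges_duplicate_and_anticorrelated():
    rng = np.random.default_rng(0)
    base = rng.normal(5, 2, 8)
    mat = pd.DataFrame({"a": base, "b": base, "c": -base}).T
    mat.columns = [f"s{i}" for i in range(8)]
    edges = gene_pcc_edges(mat, cutoff=0.97)
    assert len(edges) == 1
    row = edges.iloc[0]
    assert {row["gene_a"], row["gene_b"]} == {"a", "b"}
    assert row["pcc"] == pytest.approx(1.0)  # the c pairs are PCC = -1: no edge


def test_edges_cutoff_validation_and_zero_variance():
    mat = pd.DataFrame(np.random.default_rng(1).normal(size=(3, 5)))
    with pytest.raises(ValueError, match="cutoff"):
        gene_pcc_edges(mat, cutoff=0.0)
    with pytest.raises(ValueError, match="cutoff"):
        gene_pcc_edges(mat, cutoff=1.5)
    mat.iloc[0] = 3.0
    with pytest.raises(ValueError, match="zero variance"):
        gene_pcc_edges(mat, cutoff=0.9)


def test_edges_match_bruteforce_oracle():
    """Thresholded edge list equals brute-force all-pairs PCC on a toy matrix."""
    rng = np.random.default_rng(2)
    shared = rng.normal(0, 1, 10)
    mat = pd.DataFrame(
        [shared + rng.normal(0, sd, 10) for sd in (0.01, 0.02, 0.05, 0.5, 1.0, 2.0)],
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(10)])
    cutoff = 0.9
    edges = gene_pcc_edges(mat, cutoff)
    got = {frozenset((a, b)): w for a, b, w in edges.itertuples(index=False)}
    expected = {}
    genes = list(mat.index)
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            r, _ = stats.pearsonr(mat.iloc[i], mat.iloc[j])
            if r >= cutoff and r > 0:
                expected[frozenset((genes[i], genes[j]))] = r
    assert set(got) == set(expected)
    for key, w in expected.items():
        assert got[key] == pytest.approx(w, abs=1e-12)


# -------------------------------------------------------------- stage of max

def test_stage_of_max_profiles_and_tiebreak():
    design = seven_stage_design()
    cols = design["sample"].tolist()
    mat = pd.DataFrame(
        [np.arange(7),                      # strictly increasing -> stage 9
         [0, 5, 1, 0, 0, 0, 0],             # bump at 7.2
         [0, 4, 4, 0, 0, 0, 0]],            # tie 7.2/7.3 -> earliest wins
        index=["up", "bump", "tie"], columns=cols, dtype=float)
    som = assign_stage_of_max(mat, design)
    assert som["up"] == "9"
    assert som["bump"] == "7.2"
    assert som["tie"] == "7.2"


def test_stage_of_max_ignores_dried_samples(dataset, norm):
    _, design, _ = dataset
    som = assign_stage_of_max(norm.log2, design)
    fresh_only = design[design["treatment"] == "fresh"]
    som2 = assign_stage_of_max(norm.log2[fresh_only["sample"]], fresh_only)
    assert som.equals(som2)


# ---------------------------------------------------------- gene significance

def test_gene_significance_exact_profiles():
    design = seven_stage_design()
    cols = design["sample"].tolist()
    p50 = np.array([P50_7[s] for s in design["stage"]], float)
    mat = pd.DataFrame([p50, -p50, np.arange(1.0, 8.0)],
                       index=["pos", "neg", "ramp"], columns=cols)
    gs = gene_significance(mat, design, P50_7)
    assert gs.loc["pos", "gs"] == pytest.approx(1.0)
    assert gs.loc["pos", "sign"] == 1
    assert gs.loc["neg", "gs"] == pytest.approx(1.0)
    assert gs.loc["neg", "sign"] == -1
    # Formula oracle for the linear ramp.
    x = np.arange(1.0, 8.0)
    r = np.sum((x - x.mean()) * (p50 - p50.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((p50 - p50.mean()) ** 2))
    assert gs.loc["ramp", "gs"] == pytest.approx(abs(r), abs=1e-12)


def test_gene_significance_affine_invariance():
    design = seven_stage_design()
    cols = design["sample"].tolist()
    rng = np.random.default_rng(3)
    prof = rng.normal(5, 2, 7)
    mat = pd.DataFrame([prof, 3.0 * prof + 10.0, -2.0 * prof + 4.0],
                       index=["a", "b", "c"], columns=cols)
    gs = gene_significance(mat, design, P50_7)
    assert gs.loc["a", "gs"] == pytest.approx(gs.loc["b", "gs"], abs=1e-12)
    assert gs.loc["a", "gs"] == pytest.approx(gs.loc["c", "gs"], abs=1e-12)
    assert gs.loc["a", "sign"] == gs.loc["b", "sign"] == -gs.loc["c", "sign"]


def test_gene_significance_refuses_too_few_stages():
    design = seven_stage_design().iloc[:2]
    mat = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=design["sample"])
    with pytest.raises(ValueError, match="3 fresh stages"):
        gene_significance(mat, design, P50_7)


def test_dried_samples_never_enter_the_p50_alignment(dataset, norm):
    _, design, truth = dataset
    gs_all = gene_significance(norm.log2, design, truth.true_p50)
    fresh = design[design["treatment"] == "fresh"]
    gs_fresh = gene_significance(norm.log2[fresh["sample"]], fresh, truth.true_p50)
    pd.testing.assert_frame_equal(gs_all, gs_fresh)


# ------------------------------------------------------------ module & summary

def _tf_log2(cfg_seed=0, noise_sd=None):
    kwargs = {} if noise_sd is None else {"noise_sd": noise_sd}
    cfg = SimConfig(seed=cfg_seed, **kwargs)
    counts, design, truth = generate_expression_dataset(cfg)
    ann, _ = generate_annotation_and_sugars(cfg)
    norm = normalize_and_log(counts)
    kept = set(variance_filter(norm))
    tf = [g for g in ann.loc[ann["family"] != "", "gene"] if g in kept]
    return norm.log2.loc[tf], design, truth, ann


def test_module_extraction_cutoffs(dataset, norm, annotation):
    log2_tf, design, truth, ann = _tf_log2(0)
    graph = build_coexpression_graph(log2_tf, design, truth.true_p50, ann)
    gs = gene_significance(log2_tf, design, truth.true_p50)
    # gs_cutoff = 0: every network node with defined GS is in the module.
    module = extract_longevity_module(graph, gs, gs_cutoff=0.0)
    assert set(module.members) == set(graph.nodes) & set(gs.index)
    # Impossible cutoff: empty module is valid but warned about.
    with pytest.warns(UserWarning):
        module = extract_longevity_module(graph, gs, gs_cutoff=1.0)
    assert len(module) == 0


def test_module_recall_degrades_with_noise():
    """Planted-module recall falls monotonically as stage noise grows."""
    recalls = []
    for noise in (0.2, 1.2, 3.0):
        hits = []
        for seed in range(5):
            log2_tf, design, truth, ann = _tf_log2(seed, noise_sd=noise)
            graph = build_coexpression_graph(log2_tf, design, truth.true_p50, ann)
            gs = gene_significance(log2_tf, design, truth.true_p50)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                module = extract_longevity_module(graph, gs, 0.9)
            hits.append(len(set(module.members) & truth.module_genes) / 27)
        recalls.append(np.mean(hits))
    assert recalls[0] >= recalls[1] >= recalls[2]
    assert recalls[0] > recalls[2]


def test_network_summary_components():
    # Two co-expression blocks with no cross-correlation above the cutoff.
    rng = np.random.default_rng(5)
    b1 = rng.normal(0, 1, 10)
    b2 = rng.normal(0, 1, 10)
    mat = pd.DataFrame(
        [b1 + rng.normal(0, 0.01, 10) for _ in range(3)]
        + [b2 + rng.normal(0, 0.01, 10) for _ in range(3)],
        index=[f"g{i}" for i in range(6)], columns=[f"s{i}" for i in range(10)])
    edges = gene_pcc_edges(mat, 0.97)
    import networkx as nx
    graph = nx.Graph()
    for row in edges.itertuples(index=False):
        graph.add_edge(row.gene_a, row.gene_b, pcc=row.pcc)
    summary = network_summary(graph)
    assert summary["n_components"] == 2
    assert sorted(map(tuple, summary["components"])) == [
        ("g0", "g1", "g2"), ("g3", "g4", "g5")]
    # Empty edge set: node-inclusion invariant means zero nodes.
    empty = network_summary(nx.Graph())
    assert empty["n_nodes"] == 0 and empty["n_components"] == 0


def test_edge_invariants_on_synthetic_graph():
    log2_tf, design, truth, ann = _tf_log2(0)
    edges = gene_pcc_edges(log2_tf, 0.97)
    assert (edges["pcc"] >= 0.97).all() and (edges["pcc"] <= 1.0 + 1e-12).all()
    assert (edges["gene_a"] != edges["gene_b"]).all()  # irreflexive
    graph = build_coexpression_graph(log2_tf, design, truth.true_p50, ann)
    assert all(d >= 1 for _, d in graph.degree())
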