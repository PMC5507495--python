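"""TF co-expression network, temporal annotation and the longevity module.

Edges connect transcription-factor genes whose expression profiles across
libraries have a Pearson correlation at or above a high cutoff (0.97),
positive correlations only; a gene enters the graph only with at least one
qualifying edge.  Each node carries its stage-of-max (the fresh stage at
which its mean expression peaks, earliest stage on ties) and its gene
significance GS — the absolute Pearson correlation between the gene's
fresh-stage mean profile and the P50 longevity trajectory.  The longevity
module is the set of network nodes with GS above a threshold (0.9).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx

from .expression import stage_means

__all__ = [
    "gene_pcc_edges",
    "build_coexpression_graph",
    "assign_stage_of_max",
    "gene_significance",
    "LongevityModule",
    "extract_longevity_module",
    "network_summary",
    "export_graphml",
]


def gene_pcc_edges(log2_values: pd.DataFrame, cutoff: float = 0.97) -> pd.DataFrame:
    """All-pairs PCC edge list: pairs with PCC >= cutoff and PCC > 0.

    ``log2_values`` is genes x samples; every gene must have nonzero
    variance across samples.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must lie in (0, 1]")
    mat = log2_values.to_numpy(float)
    sd = mat.std(axis=1)
    if (sd == 0).any():
        bad = list(log2_values.index[sd == 0])
        raise ValueError(f"genes with zero variance: {bad[:5]}")
    corr = np.corrcoef(mat)
    genes = list(log2_values.index)
    iu, ju = np.triu_indices(len(genes), k=1)
    w = corr[iu, ju]
    keep = (w >= cutoff) & (w > 0)
    return pd.DataFrame({
        "gene_a": [genes[i] for i in iu[keep]],
        "gene_b": [genes[j] for j in ju[keep]],
        "pcc": w[keep],
    })


def assign_stage_of_max(log2_values: pd.DataFrame, design: pd.DataFrame) -> pd.Series:
    """Fresh stage at which each gene's stage-mean expression is maximal.

    Dried samples are excluded; ties resolve to the earliest stage.
    """
    means = stage_means(log2_values, design, "fresh")
    return means.idxmax(axis=1).rename("stage_of_max")


def gene_significance(log2_values: pd.DataFrame, design: pd.DataFrame,
                      p50_by_stage: dict | pd.Series) -> pd.DataFrame:
    """Trait-based gene significance against the longevity trajectory.

    GS = |PCC(fresh-stage mean profile, P50 per stage)|, with the sign of
    the underlying correlation retained.  Refuses fewer than 3 stages and
    genes with zero stage-mean variance.
    """
    means = stage_means(log2_values, design, "fresh")
    stages = [s for s in means.columns if s in dict(p50_by_stage)]
    if len(stages) < 3:
        raise ValueError("gene significance needs >= 3 fresh stages with P50 values")
    p50 = np.array([dict(p50_by_stage)[s] for s in stages], float)
    x = means[stages].to_numpy(float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = p50 - p50.mean()
    denom = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / denom
    out = pd.DataFrame({"gs": np.abs(r), "sign": np.sign(r)}, index=means.index)
    return out.dropna()


def build_coexpression_graph(log2_values: pd.DataFrame, design: pd.DataFrame,
                             p50_by_stage: dict | pd.Series,
                             annotation: pd.DataFrame | None = None,
                             cutoff: float = 0.97) -> nx.Graph:
    """Graph of TF genes with stage_of_max, GS and family node attributes.

    Only genes with at least one qualifying edge become nodes.
    """
    edges = gene_pcc_edges(log2_values, cutoff)
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_edge(row.gene_a, row.gene_b, pcc=float(row.pcc))
    som = assign_stage_of_max(log2_values, design)
    gs = gene_significance(log2_values, design, p50_by_stage)
    fam = {}
    if annotation is not None:
        fam = annotation.set_index("gene")["family"].to_dict()
    for node in g.nodes:
        g.nodes[node]["stage_of_max"] = str(som.get(node, ""))
        g.nodes[node]["gs"] = float(gs["gs"].get(node, float("nan")))
        g.nodes[node]["gs_sign"] = float(gs["sign"].get(node, 0.0))
        g.nodes[node]["family"] = str(fam.get(node, ""))
    return g


@dataclass
class LongevityModule:
    """Network nodes whose profiles track the P50 trajectory."""

    members: list[str]
    gs_cutoff: float
    family_counts: dict = field(default_factory=dict)
    edge_density: float = float("nan")

    def __len__(self) -> int:
        return len(self.members)


def extract_longevity_module(graph: nx.Graph, gs: pd.DataFrame,
                             gs_cutoff: float = 0.9) -> LongevityModule:
    """Module = network nodes with GS strictly above ``gs_cutoff``.

    Reports the family composition and the induced subgraph's edge density.
    An empty module is a valid (warned-about) result.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph: build the network first")
    members = sorted(n for n in graph.nodes
                     if n in gs.index and gs.loc[n, "gs"] > gs_cutoff)
    if not members:
        import warnings
        warnings.warn(f"no network node exceeds GS cutoff {gs_cutoff}")
        return LongevityModule([], gs_cutoff)
    sub = graph.subgraph(members)
    n = len(members)
    density = (2.0 * sub.number_of_edges() / (n * (n - 1))) if n > 1 else float("nan")
    fams = pd.Series([graph.nodes[m].get("family", "") for m in members])
    return LongevityModule(members, gs_cutoff,
                           fams.value_counts().to_dict(), density)


def network_summary(graph: nx.Graph) -> dict:
    """Node/edge counts, connected components, per-stage node counts and the
    degree distribution."""
    comps = sorted((sorted(c) for c in nx.connected_components(graph)),
                   key=len, reverse=True)
    per_stage = pd.Series(
        [graph.nodes[n].get("stage_of_max", "") for n in graph.nodes]
    ).value_counts().to_dict()
    degrees = sorted((d for _, d in graph.degree()), reverse=True)
    return {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "n_components": len(comps),
        "component_sizes": [len(c) for c in comps],
        "components": comps,
        "nodes_per_stage": per_stage,
        "degree_distribution": degrees,
    }


def export_graphml(graph: nx.Graph, path) -> None:
    """GraphML export for external viewers (layout is left to the viewer)."""
    nx.write_graphml(graph, path)
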