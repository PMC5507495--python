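"""Set-algebra between differential-expression contrasts, heat-map gene
selection and qPCR cross-validation.

The Venn logic compares gene sets from two contrasts (e.g. transcripts
higher in mature seeds vs prematurely dried seeds against transcripts
responding to enforced drying) with percentages rounded half-up to match
printed figures.  qPCR relative expression uses the comparative 2^-ddCt
method with the arithmetic mean of two reference-gene Ct values; the
amplification efficiency is assumed to be 2.0 per cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "round_half_up",
    "VennResult",
    "venn_overlap",
    "compartment_overlap",
    "heatmap_selection",
    "ddct_relative_expression",
    "rnaseq_qpcr_agreement",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero-to-up."""
    return int(math.floor(x + 0.5))


@dataclass
class VennResult:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    n_both: int
    pct_of_a: int
    pct_of_b: int

    @property
    def n_a_only(self) -> int:
        return self.n_a - self.n_both

    @property
    def n_b_only(self) -> int:
        return self.n_b - self.n_both

    @property
    def n_union(self) -> int:
        return self.n_a + self.n_b - self.n_both


def venn_overlap(set_a, set_b, label_a: str = "A", label_b: str = "B") -> VennResult:
    """Two-set overlap with integer percentages of each set."""
    a, b = set(set_a), set(set_b)
    both = a & b
    return VennResult(
        label_a, label_b, len(a), len(b), len(both),
        pct_of_a=round_half_up(100.0 * len(both) / len(a)) if a else 0,
        pct_of_b=round_half_up(100.0 * len(both) / len(b)) if b else 0,
    )


def compartment_overlap(gene_set, annotation: pd.DataFrame,
                        compartment: str = "chloroplast") -> tuple[int, int, int]:
    """(count, compartment size, integer percentage) of a compartment's genes
    found in ``gene_set``."""
    members = set(annotation.loc[annotation["compartment"] == compartment, "gene"])
    if not members:
        raise ValueError(f"no genes annotated to compartment {compartment!r}")
    hit = len(set(gene_set) & members)
    return hit, len(members), round_half_up(100.0 * hit / len(members))


def heatmap_selection(log2_stage_means: pd.DataFrame, gs: pd.DataFrame,
                      stage_pair: tuple[str, str] = ("7.2", "9"),
                      fc_log2: float = 4.0, gs_cutoff: float = 0.85) -> pd.DataFrame:
    """Strongly stage-regulated, longevity-correlated genes for heat maps.

    Selects genes with |log2 mean(stage b) - log2 mean(stage a)| strictly
    above ``fc_log2`` and GS strictly above ``gs_cutoff``; returns their
    mean-centred log2 stage-mean matrix (rows ready for plotting).
    """
    a, b = stage_pair
    for s in (a, b):
        if s not in log2_stage_means.columns:
            raise ValueError(f"stage {s!r} missing from stage means")
    diff = (log2_stage_means[b] - log2_stage_means[a]).abs()
    gs_aligned = gs["gs"].reindex(log2_stage_means.index)
    keep = (diff > fc_log2) & (gs_aligned > gs_cutoff)
    sel = log2_stage_means.loc[keep.fillna(False)]
    return sel.sub(sel.mean(axis=1), axis=0)


def ddct_relative_expression(records: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """Comparative 2^-ddCt relative expression against a calibrator sample.

    ``records`` columns: gene, sample, ct_target, ct_ref1, ct_ref2.  Per
    record, dCt = Ct_target - mean(Ct_ref1, Ct_ref2); ddCt subtracts the
    gene's calibrator dCt; relative expression is 2^-ddCt (calibrator = 1).
    """
    req = {"gene", "sample", "ct_target", "ct_ref1", "ct_ref2"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    df = records.copy()
    if df[["ct_target", "ct_ref1", "ct_ref2"]].isna().any().any():
        raise ValueError("missing Ct values (both reference Cts are required)")
    if (df[["ct_target", "ct_ref1", "ct_ref2"]] <= 0).any().any():
        raise ValueError("Ct values must be positive")
    df["dct"] = df["ct_target"] - 0.5 * (df["ct_ref1"] + df["ct_ref2"])
    out = []
    for gene, grp in df.groupby("gene", sort=False):
        cal = grp.loc[grp["sample"] == calibrator, "dct"]
        if cal.empty:
            raise ValueError(f"calibrator sample {calibrator!r} missing for gene {gene}")
        grp = grp.copy()
        grp["ddct"] = grp["dct"] - float(cal.iloc[0])
        grp["rel_expr"] = np.exp2(-grp["ddct"])
        out.append(grp)
    result = pd.concat(out, ignore_index=True)
    result.attrs["efficiency"] = 2.0  # assumed perfect doubling per cycle
    result.attrs["calibrator"] = calibrator
    return result


def rnaseq_qpcr_agreement(qpcr: pd.DataFrame, rnaseq_stage_means: pd.DataFrame,
                          sample_to_stage: dict | None = None) -> pd.DataFrame:
    """Per-gene agreement (r^2, and signed r) between platforms.

    ``qpcr`` is the output of :func:`ddct_relative_expression`;
    ``rnaseq_stage_means`` holds linear-scale stage means.  Profiles are
    compared on the log2 scale over shared stages (>= 3 required).
    """
    s2s = sample_to_stage or {}
    rows = []
    for gene, grp in qpcr.groupby("gene", sort=False):
        if gene not in rnaseq_stage_means.index:
            continue
        stages = [s2s.get(s, s) for s in grp["sample"]]
        shared = [s for s in stages if s in rnaseq_stage_means.columns]
        if len(shared) < 3:
            raise ValueError(f"gene {gene}: fewer than 3 shared stages")
        x = np.log2(grp.set_index(pd.Index(stages)).loc[shared, "rel_expr"]
                    .to_numpy(float))
        y = np.log2(rnaseq_stage_means.loc[gene, shared].to_numpy(float) + 1e-9)
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"gene": gene, "r": r, "r2": r * r, "n_stages": len(shared)})
    return pd.DataFrame(rows)
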