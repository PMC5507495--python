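"""Readers for the plain-text dataset files the pipeline exchanges."""

from __future__ import annotations

import pandas as pd

from .phenotyping import StorageViabilityCurve

__all__ = [
    "read_counts",
    "read_design",
    "read_annotation",
    "read_germination",
    "read_sugars",
    "annotation_term_map",
]


def read_counts(path) -> pd.DataFrame:
    """Gene x sample integer count matrix from TSV (gene ids in column 1)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df < 0).any().any():
        raise ValueError("counts must be non-negative")
    return df


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"stage": str, "sample": str})
    return df


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return df


def annotation_term_map(annotation: pd.DataFrame) -> dict[str, set]:
    """GO term -> gene set from a semicolon-joined annotation table."""
    terms: dict[str, set] = {}
    for gene, joined in zip(annotation["gene"], annotation["go_terms"]):
        for term in str(joined).split(";"):
            term = term.strip()
            if term:
                terms.setdefault(term, set()).add(gene)
    return terms


def read_germination(path) -> list[StorageViabilityCurve]:
    """germination.csv (stage, time_d, replicate, n_seeds, n_germinated)."""
    df = pd.read_csv(path, dtype={"stage": str})
    return [StorageViabilityCurve(stage, grp.drop(columns="stage"))
            for stage, grp in df.groupby("stage", sort=False)]


def read_sugars(path) -> pd.DataFrame:
    return pd.read_csv(path)
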