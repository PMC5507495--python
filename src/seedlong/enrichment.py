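"""Over-representation statistics: chi-square family enrichment,
hypergeometric GO tests, multiple-testing corrections and the bin-wise
Wilcoxon functional enrichment with z-score conversion.

GO annotations are consumed as already-propagated gene -> term lists (no
ontology traversal); the genome size for hypergeometric tests defaults to
the number of annotated genes supplied.  Bin-wise testing follows the
PageMan convention: a two-sided rank-sum test of each functional bin
against all remaining genes, Bonferroni correction over bins, and the
corrected p-value converted to a signed z-score (p = 0.05 -> |z| = 1.96).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "bonferroni_adjust",
    "chi2_family_enrichment",
    "hypergeometric_enrichment",
    "wilcoxon_bin_test",
    "z_from_corrected_p",
]


def _check_pvalues(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = _check_pvalues(pvalues)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(pvalues) -> np.ndarray:
    """Family-wise Bonferroni correction, min(1, m*p)."""
    p = _check_pvalues(pvalues)
    return np.minimum(p * p.size, 1.0)


def chi2_family_enrichment(tail_genes, background_genes,
                           families: pd.Series) -> pd.DataFrame:
    """Per-family 2x2 chi-square test of enrichment in a gene subset.

    ``families`` maps gene id -> family label over the background (e.g. all
    differentially expressed TFs); ``tail_genes`` is the subset of interest
    (e.g. the transient maturation tail).  Pearson chi-square, 1 df, no
    continuity correction.  Reports each family's share of the tail as a
    percentage.
    """
    tail = set(tail_genes)
    background = set(background_genes)
    if not tail <= background:
        raise ValueError("tail genes must be a subset of the background")
    fam = families.reindex(sorted(background)).dropna()
    rows = []
    for family, members in fam.groupby(fam):
        in_fam = set(members.index)
        a = len(tail & in_fam)
        b = len(tail) - a
        c = len(in_fam) - a
        d = len(background) - len(tail) - c
        table = np.array([[a, b], [c, d]], float)
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        if (expected == 0).any():
            raise ValueError(f"family {family!r}: zero expected cell count")
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append({"family": family, "n_tail": a, "n_background": len(in_fam),
                     "pct_of_tail": 100.0 * a / len(tail) if tail else 0.0,
                     "chi2": chi2, "pvalue": p})
    return pd.DataFrame(rows).sort_values("pvalue").reset_index(drop=True)


def hypergeometric_enrichment(gene_list, term_to_genes: dict,
                              genome_size: int | None = None,
                              descriptions: dict | None = None) -> pd.DataFrame:
    """Term-level over/under-representation by the hypergeometric test.

    For each term with K genes in a genome of N, and a query list of n genes
    containing k of them, the upper tail P(X >= k) measures
    over-representation and the lower tail P(X <= k) under-representation.
    Both BH and Bonferroni corrections (across tested terms, on the
    direction-specific smaller p) are reported side by side.
    """
    query = set(gene_list)
    universe = set().union(*term_to_genes.values()) if term_to_genes else set()
    n_genome = genome_size if genome_size is not None else len(universe)
    if not query:
        raise ValueError("empty gene list")
    n = len(query)
    rows = []
    for term, members in term_to_genes.items():
        members = set(members)
        big_k = len(members)
        k = len(query & members)
        if k > big_k or k > n:
            raise ValueError(f"term {term}: annotation inconsistency (k > K or k > n)")
        p_over = float(stats.hypergeom.sf(k - 1, n_genome, big_k, n))
        p_under = float(stats.hypergeom.cdf(k, n_genome, big_k, n))
        direction = "over" if p_over <= p_under else "under"
        rows.append({"term": term,
                     "description": (descriptions or {}).get(term, ""),
                     "genome_count": big_k, "list_count": k,
                     "list_size": n, "genome_size": n_genome,
                     "p_over": p_over, "p_under": p_under,
                     "direction": direction,
                     "pvalue": min(p_over, p_under)})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bh"] = bh_adjust(out["pvalue"].to_numpy())
        out["p_bonferroni"] = bonferroni_adjust(out["pvalue"].to_numpy())
        out = out.sort_values("pvalue").reset_index(drop=True)
    return out


def z_from_corrected_p(p_corrected: float, sign: float = 1.0) -> float:
    """Two-sided corrected p-value to signed z-score (0.05 -> 1.96)."""
    p = min(max(float(p_corrected), 1e-300), 1.0)
    return float(np.sign(sign) if sign else 1.0) * float(stats.norm.ppf(1.0 - p / 2.0))


def wilcoxon_bin_test(values: pd.Series, bins: dict,
                      exact_below: int = 10) -> pd.DataFrame:
    """Bin-wise two-sided Wilcoxon rank-sum enrichment with z conversion.

    ``values`` holds one statistic per gene (typically a stage-wise log2
    expression change); ``bins`` maps bin name -> gene set.  Each bin is
    compared against all remaining genes: exact rank-sum p for tie-free
    bins smaller than ``exact_below``, tie-corrected normal approximation
    otherwise.  P-values are Bonferroni-corrected over bins and converted
    to z-scores signed by the direction of the bin's median shift.
    """
    values = values.dropna()
    rows = []
    for name, members in bins.items():
        in_bin = values.index.isin(set(members))
        x = values[in_bin].to_numpy(float)
        y = values[~in_bin].to_numpy(float)
        if len(x) == 0:
            raise ValueError(f"bin {name!r} has no scored members")
        if len(y) == 0:
            raise ValueError(f"bin {name!r} covers the entire gene set")
        pooled = np.concatenate([x, y])
        ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(x) < exact_below and not ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        shift = np.median(x) - np.median(y)
        if shift == 0:
            shift = float(np.mean(x) - np.mean(y))
        rows.append({"bin": name, "n_bin": len(x), "n_rest": len(y),
                     "statistic": float(res.statistic), "pvalue": float(res.pvalue),
                     "median_shift": float(shift)})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = bonferroni_adjust(out["pvalue"].to_numpy())
    out["z"] = [z_from_corrected_p(p, s) for p, s in
                zip(out["p_bonferroni"], out["median_shift"])]
    return out
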