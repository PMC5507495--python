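"""Seeded synthetic datasets with the structure the downstream analysis assumes.

The generator emulates a late seed-maturation study: ten RNA-seq libraries
spanning phenological stages 7.1 (end of seed filling) to 9 (dry mature
seed) with nested replication at stages 7.2 and 9 plus two prematurely
dried 7.2 libraries, negative-binomial counts, and planted gene cohorts
with known ground truth:

* a longevity "module" of transcription factors whose log2 stage-mean
  profile is an affine function of the P50 longevity trajectory
  (0 -> 28 -> ... -> 48 days);
* a transient "tail" cohort peaking at stages 7.2-7.3, enriched for the
  AP2/EREBP and WRKY families;
* a repressed chloroplast-like cohort decaying monotonically after 7.1;
* low-variance reference genes (qPCR normalisers);
* background genes with flat or stage-transient profiles.

Matching phenotype data are generated: logistic loss-of-viability curves
(4 replicates x 25 seeds) whose midpoints are the per-stage P50 values, a
gene annotation table (32 TF families, GO terms, compartment), and sugar
profiles whose axis RFO/Suc ratio rises with longevity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .phenotyping import StorageViabilityCurve

__all__ = [
    "SimConfig",
    "GroundTruth",
    "TF_FAMILIES",
    "generate_expression_dataset",
    "generate_viability_curves",
    "generate_annotation_and_sugars",
    "simulate_two_group_counts",
    "write_dataset",
]

# 32 transcription-factor families; AP2/EREBP and WRKY carry the transient
# maturation-tail enrichment.
TF_FAMILIES: tuple[str, ...] = (
    "AP2/EREBP", "WRKY", "MYB", "bHLH", "NAC", "bZIP", "C2H2", "HSF",
    "ARF", "GRAS", "HD-ZIP", "MADS", "C3H", "Trihelix", "GATA", "B3",
    "LBD", "SBP", "TCP", "ARR-B", "CO-like", "Dof", "E2F/DP", "EIL",
    "G2-like", "GeBP", "HB-other", "NF-YA", "NF-YB", "NF-YC", "Nin-like",
    "ZF-HD",
)

# (GO id, description) pool used for annotation; module genes oversample the
# heat/folding terms and chloroplast genes the photosynthesis terms.
GO_POOL: tuple[tuple[str, str], ...] = (
    ("GO:0009408", "response to heat"),
    ("GO:0042542", "response to hydrogen peroxide"),
    ("GO:0009644", "response to high light intensity"),
    ("GO:0006457", "protein folding"),
    ("GO:0034976", "response to endoplasmic reticulum stress"),
    ("GO:0015979", "photosynthesis"),
    ("GO:0019684", "photosynthesis, light reaction"),
    ("GO:0006091", "generation of precursor metabolites and energy"),
    ("GO:0045333", "cellular respiration"),
    ("GO:0006355", "regulation of transcription, DNA-templated"),
    ("GO:0009737", "response to abscisic acid"),
    ("GO:0005975", "carbohydrate metabolic process"),
    ("GO:0006952", "defense response"),
    ("GO:0009414", "response to water deprivation"),
    ("GO:0048316", "seed development"),
    ("GO:0010431", "seed maturation"),
)

MODULE_GO = ("GO:0009408", "GO:0006457", "GO:0042542")
CHLORO_GO = ("GO:0015979", "GO:0019684", "GO:0006091")

# Table-1-style library layout: (stage, DAF, treatment, n_replicates).
DEFAULT_STAGES: tuple[tuple[str, int, str, int], ...] = (
    ("7.1", 57, "fresh", 1),
    ("7.2", 63, "fresh", 2),
    ("7.2", 63, "dried", 2),
    ("7.3", 69, "fresh", 1),
    ("8.1", 71, "fresh", 1),
    ("8.2", 73, "fresh", 1),
    ("9", 77, "fresh", 2),
)

# Longevity trajectory (days): sharp rise at physiological maturity (7.2)
# then a near two-fold further increase to the dry mature seed.
DEFAULT_P50: dict[str, float] = {
    "7.1": 0.0, "7.2": 28.0, "7.3": 33.0, "8.1": 38.0, "8.2": 43.0, "9": 48.0,
}


@dataclass
class SimConfig:
    """Study-design and noise parameters of the synthetic dataset."""

    seed: int = 0
    n_genes: int = 2000
    stages: tuple = DEFAULT_STAGES
    p50_by_stage: dict = field(default_factory=lambda: dict(DEFAULT_P50))
    module_size: int = 27
    tail_size: int = 40
    chloro_size: int = 60
    n_reference: int = 20
    tf_background: int = 150
    nb_dispersion: float = 0.01
    lib_size_range: tuple[float, float] = (0.7, 1.4)
    noise_sd: float = 0.2
    module_log2_range: float = 5.0
    tail_log2_amp: float = 4.0
    chloro_log2_amp: float = 4.0
    dried_mix: float = 0.6  # weight of stage 7.3 (vs 8.1) in the dried-7.2 mean
    families: tuple = TF_FAMILIES
    tail_family_weights: dict = field(
        default_factory=lambda: {"AP2/EREBP": 0.20, "WRKY": 0.11})
    storage_times: tuple = tuple(range(0, 71, 7))
    decay_scale: float = 3.0
    n_storage_replicates: int = 4
    n_seeds: int = 25

    def validate(self) -> None:
        planted = (self.module_size + self.tail_size + self.chloro_size
                   + self.n_reference + self.tf_background)
        if self.n_genes < planted:
            raise ValueError("n_genes smaller than the planted cohorts")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0 (0 = deterministic limit)")
        seen = set()
        for label, _daf, trt, n_rep in self.stages:
            if (label, trt) in seen:
                raise ValueError(f"duplicate stage entry {(label, trt)}")
            seen.add((label, trt))
            if n_rep < 1:
                raise ValueError("each stage needs >= 1 replicate")
        fresh = self.fresh_stages()
        p50 = [self.p50_by_stage[s] for s, _ in fresh]
        if any(b < a for a, b in zip(p50, p50[1:])):
            raise ValueError("p50_by_stage must be non-decreasing over fresh stages")
        if not self.families:
            raise ValueError("family list must not be empty")
        if min(self.storage_times) < 0:
            raise ValueError("storage times must be non-negative")

    def fresh_stages(self) -> list[tuple[str, int]]:
        """(label, DAF) of fresh stages ordered by DAF."""
        fresh = [(s, d) for s, d, t, _ in self.stages if t == "fresh"]
        return sorted(fresh, key=lambda x: x[1])


@dataclass
class GroundTruth:
    """Planted cohorts and effect sizes underlying a generated dataset."""

    module_genes: set
    tail_genes: set
    chloro_genes: set
    reference_genes: set
    true_log2fc: pd.DataFrame  # genes x contrasts
    true_p50: dict
    stage_log2_means: pd.DataFrame  # genes x fresh stages (+ dried column)

    def __post_init__(self) -> None:
        sets = [self.module_genes, self.tail_genes, self.chloro_genes,
                self.reference_genes]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("ground-truth gene cohorts must be disjoint")


def _gene_ids(n: int) -> list[str]:
    # Glyma-like synthetic identifiers; no real accessions emitted.
    return [f"SYN.{(i % 20) + 1:02d}G{(i + 1) * 100:06d}" for i in range(n)]


def _stage_profiles(cfg: SimConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, dict]:
    """Log2 stage-mean matrix over fresh stages plus cohort index ranges."""
    fresh = cfg.fresh_stages()
    labels = [s for s, _ in fresh]
    n_stage = len(labels)
    p50 = np.array([cfg.p50_by_stage[s] for s in labels], float)
    idx = np.arange(n_stage, dtype=float)
    genes = _gene_ids(cfg.n_genes)

    prof = np.empty((cfg.n_genes, n_stage))
    lo = 0
    cohorts = {}
    # Longevity module: affine in P50 with positive slope.
    hi = lo + cfg.module_size
    amp = cfg.module_log2_range * rng.uniform(0.8, 1.2, cfg.module_size)
    base = rng.uniform(5.0, 8.0, cfg.module_size)
    span = max(p50.max(), 1.0)
    prof[lo:hi] = base[:, None] + amp[:, None] * (p50[None, :] / span)
    cohorts["module"] = (lo, hi)
    lo = hi
    # Transient tail: Gaussian bump centred on stages 7.2-7.3.
    hi = lo + cfg.tail_size
    centers = []
    for target in ("7.2", "7.3"):
        if target in labels:
            centers.append(labels.index(target))
    if not centers:
        centers = [min(1, n_stage - 1)]
    c = rng.choice(centers, cfg.tail_size) + rng.uniform(-0.3, 0.3, cfg.tail_size)
    width = rng.uniform(0.5, 0.8, cfg.tail_size)
    amp = cfg.tail_log2_amp * rng.uniform(0.8, 1.2, cfg.tail_size)
    base = rng.uniform(4.0, 7.0, cfg.tail_size)
    prof[lo:hi] = base[:, None] + amp[:, None] * np.exp(
        -((idx[None, :] - c[:, None]) ** 2) / (2 * width[:, None] ** 2))
    cohorts["tail"] = (lo, hi)
    lo = hi
    # Chloroplast-like cohort: high during filling, monotone decay after 7.1.
    hi = lo + cfg.chloro_size
    d = (idx - idx[0]) / max(idx[-1] - idx[0], 1.0)
    amp = cfg.chloro_log2_amp * rng.uniform(0.8, 1.2, cfg.chloro_size)
    base = rng.uniform(7.0, 10.0, cfg.chloro_size)
    prof[lo:hi] = base[:, None] - amp[:, None] * (d[None, :] ** rng.uniform(0.6, 1.0, (cfg.chloro_size, 1)))
    cohorts["chloro"] = (lo, hi)
    lo = hi
    # Reference genes: constant stage means (only counting noise downstream).
    hi = lo + cfg.n_reference
    prof[lo:hi] = rng.uniform(6.0, 9.0, cfg.n_reference)[:, None]
    cohorts["reference"] = (lo, hi)
    lo = hi
    # Background TFs: transient bumps centred away from the final stage so
    # that the only genes tracking P50 are the planted module.
    hi = lo + cfg.tf_background
    c = rng.uniform(0.0, max(n_stage - 2, 1), cfg.tf_background)
    width = rng.uniform(0.6, 1.2, cfg.tf_background)
    amp = rng.uniform(1.5, 3.5, cfg.tf_background)
    base = rng.uniform(4.0, 8.0, cfg.tf_background)
    prof[lo:hi] = base[:, None] + amp[:, None] * np.exp(
        -((idx[None, :] - c[:, None]) ** 2) / (2 * width[:, None] ** 2))
    cohorts["tf_background"] = (lo, hi)
    lo = hi
    # Remaining background: 70% flat, 30% transient.
    n_rest = cfg.n_genes - lo
    base = rng.uniform(3.0, 9.0, n_rest)
    rest = np.repeat(base[:, None], n_stage, axis=1)
    n_var = int(round(0.3 * n_rest))
    if n_var:
        c = rng.uniform(0.0, n_stage - 1, n_var)
        width = rng.uniform(0.6, 1.5, n_var)
        amp = rng.uniform(1.5, 4.0, n_var) * rng.choice([-1.0, 1.0], n_var)
        rest[:n_var] += amp[:, None] * np.exp(
            -((idx[None, :] - c[:n_var, None]) ** 2) / (2 * width[:, None] ** 2))
    prof[lo:] = rest
    cohorts["background"] = (lo, cfg.n_genes)

    if cfg.noise_sd > 0:
        # Stage-level biological noise on every gene except the references.
        noise = rng.normal(0.0, cfg.noise_sd, prof.shape)
        ref_lo, ref_hi = cohorts["reference"]
        noise[ref_lo:ref_hi] = 0.0
        prof = prof + noise
    return pd.DataFrame(prof, index=genes, columns=labels), cohorts


def _dried_log2_means(cfg: SimConfig, stage_means: pd.DataFrame) -> pd.Series:
    """Dried-7.2 stage means as a linear-scale mixture of 7.3 and 8.1.

    Premature drying accelerates maturation, so the dried library's
    transcriptome sits between stages 7.3 and 8.1.
    """
    labels = list(stage_means.columns)
    a = "7.3" if "7.3" in labels else labels[min(2, len(labels) - 1)]
    b = "8.1" if "8.1" in labels else labels[min(3, len(labels) - 1)]
    linear = (cfg.dried_mix * np.exp2(stage_means[a])
              + (1.0 - cfg.dried_mix) * np.exp2(stage_means[b]))
    return np.log2(linear)


def generate_expression_dataset(
        config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (counts, design, truth) for the ten-library study design.

    Counts are NB(mean = libsize x stage-mean, dispersion); with
    ``nb_dispersion == 0`` counts are the rounded means (deterministic
    limit).  Identical seeds give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    stage_means, cohorts = _stage_profiles(config, rng)
    genes = list(stage_means.index)
    fresh_labels = list(stage_means.columns)

    # Per-treatment stage mean lookup (linear scale).
    dried = _dried_log2_means(config, stage_means)
    log2_lookup = {("fresh", s): stage_means[s] for s in fresh_labels}

    design_rows = []
    sample_means = []
    for label, daf, trt, n_rep in config.stages:
        if trt == "fresh":
            mu_log2 = log2_lookup[("fresh", label)]
        else:
            mu_log2 = dried
        for r in range(n_rep):
            rep = chr(ord("a") + r) if n_rep > 1 else ""
            sample = f"{label}{rep}{'F' if trt == 'fresh' else 'D'}"
            design_rows.append({"sample": sample, "stage": label, "daf": daf,
                                "treatment": trt, "replicate": r + 1})
            sample_means.append(np.exp2(mu_log2.to_numpy()))
    design = pd.DataFrame(design_rows)
    mu = np.column_stack(sample_means)
    lib = rng.uniform(*config.lib_size_range, size=mu.shape[1])
    mu = mu * lib[None, :]
    alpha = config.nb_dispersion
    if alpha > 0:
        counts = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))
    else:
        counts = np.rint(mu).astype(np.int64)
    counts_df = pd.DataFrame(counts, index=genes, columns=design["sample"].tolist())

    # True per-contrast log2 effects from the realised stage means.
    full = stage_means.copy()
    full["7.2D"] = dried
    contrasts = {}
    for a, b in zip(fresh_labels, fresh_labels[1:]):
        contrasts[f"{b}_vs_{a}"] = full[b] - full[a]
    last = fresh_labels[-1]
    if "7.2" in fresh_labels:
        contrasts[f"{last}_vs_7.2F"] = full[last] - full["7.2"]
        contrasts[f"{last}_vs_7.2D"] = full[last] - full["7.2D"]
        contrasts["7.2D_vs_7.2F"] = full["7.2D"] - full["7.2"]
    truth = GroundTruth(
        module_genes=set(genes[slice(*cohorts["module"])]),
        tail_genes=set(genes[slice(*cohorts["tail"])]),
        chloro_genes=set(genes[slice(*cohorts["chloro"])]),
        reference_genes=set(genes[slice(*cohorts["reference"])]),
        true_log2fc=pd.DataFrame(contrasts),
        true_p50={s: config.p50_by_stage[s] for s in fresh_labels},
        stage_log2_means=full,
    )
    return counts_df, design, truth


def generate_viability_curves(config: SimConfig) -> list[StorageViabilityCurve]:
    """Storage-viability assays per fresh stage (replicated binomial counts).

    Germination probability decays logistically, q(t) = 1/(1+exp((t-P50)/s));
    each (stage, time, replicate) draws Binomial(n_seeds, q(t)).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    t = np.asarray(config.storage_times, float)
    curves = []
    for label, _daf in config.fresh_stages():
        p50 = config.p50_by_stage[label]
        z = np.clip((t - p50) / max(config.decay_scale, 1e-12), -500, 500)
        q = 1.0 / (1.0 + np.exp(z))
        rows = []
        for r in range(config.n_storage_replicates):
            germ = rng.binomial(config.n_seeds, q)
            for ti, gi in zip(t, germ):
                rows.append({"time_d": float(ti), "replicate": r + 1,
                             "n_seeds": config.n_seeds, "n_germinated": int(gi)})
        curves.append(StorageViabilityCurve(label, pd.DataFrame(rows)))
    return curves


def _family_probs(cfg: SimConfig, weights: dict | None) -> np.ndarray:
    fams = list(cfg.families)
    probs = np.full(len(fams), 1.0 / len(fams))
    if weights:
        probs = np.zeros(len(fams))
        named = {f: w for f, w in weights.items() if f in fams}
        total = sum(named.values())
        rest = [f for f in fams if f not in named]
        for f, w in named.items():
            probs[fams.index(f)] = w
        if total > 1.0:
            probs /= total
        elif rest:
            probs[[fams.index(f) for f in rest]] = (1.0 - total) / len(rest)
        else:
            probs /= total
    return probs


def generate_annotation_and_sugars(
        config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene annotation (TF family, GO terms, compartment) and sugar tables.

    Tail genes oversample AP2/EREBP and WRKY according to
    ``tail_family_weights``; the axis sugar table is constructed so that the
    RFO/Suc ratio is non-decreasing across DAF.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    counts, design, truth = generate_expression_dataset(config)
    genes = list(counts.index)
    fams = list(config.families)
    uniform = np.full(len(fams), 1.0 / len(fams))
    tail_probs = _family_probs(config, config.tail_family_weights)
    module_probs = _family_probs(config, {"AP2/EREBP": 0.30, "WRKY": 0.10})

    go_ids = [g for g, _ in GO_POOL]
    rows = []
    for g in genes:
        family = ""
        compartment = "nuclear"
        if g in truth.module_genes:
            family = fams[rng.choice(len(fams), p=module_probs)]
            terms = list(rng.choice(MODULE_GO, size=2, replace=False))
        elif g in truth.tail_genes:
            family = fams[rng.choice(len(fams), p=tail_probs)]
            terms = list(rng.choice(go_ids, size=2, replace=False))
        elif g in truth.chloro_genes:
            compartment = "chloroplast"
            terms = list(rng.choice(CHLORO_GO, size=2, replace=False))
        else:
            terms = list(rng.choice(go_ids, size=rng.integers(1, 4), replace=False))
        rows.append({"gene": g, "family": family,
                     "go_terms": ";".join(sorted(set(terms))),
                     "compartment": compartment})
    # Background TF cohort (uniform family draw).
    lo = config.module_size + config.tail_size + config.chloro_size + config.n_reference
    for i in range(lo, lo + config.tf_background):
        rows[i]["family"] = fams[rng.choice(len(fams), p=uniform)]
    annotation = pd.DataFrame(rows)

    # Deterministic sugar curves (mg / g DW). Axis: Suc non-increasing and
    # RFO non-decreasing, so RFO/Suc is non-decreasing by construction.
    daf = np.array([46, 57, 63, 69, 71, 73, 77], float)
    x = (daf - daf[0]) / (daf[-1] - daf[0])
    sugar_rows = []
    axis = {
        "glc": 30.0 * np.exp(-3.0 * x) + 0.5,
        "fru": 20.0 * np.exp(-3.5 * x) + 0.3,
        "suc": 80.0 - 40.0 * np.clip((daf - 57) / (73 - 57), 0, 1),
        "raf": 1.0 + 7.0 * x ** 1.5,
        "sta": 2.0 + 53.0 * np.clip(x / 0.7, 0, 1) ** 1.2,
        "ver": 0.2 + 1.8 * x,
    }
    sta_cot = 1.0 + 44.0 * np.clip((daf - 57) / (73 - 57), 0, 1) ** 1.3
    sta_cot = np.where(daf > 73, sta_cot * 0.7, sta_cot)  # late ~30% decline
    cot = {
        "glc": 25.0 * np.exp(-4.0 * x) + 0.3,
        "fru": 15.0 * np.exp(-4.0 * x) + 0.3,
        "suc": np.where(daf < 63, 33.0 - 20.0 * np.clip((daf - 57) / 6.0, 0, 1), 13.0),
        "raf": 0.5 + 4.5 * x ** 1.5,
        "sta": sta_cot,
        "ver": 0.1 + 0.9 * x,
    }
    for tissue, table in (("axis", axis), ("cotyledon", cot)):
        for i, d in enumerate(daf):
            sugar_rows.append({"tissue": tissue, "daf": int(d),
                               **{k: float(v[i]) for k, v in table.items()}})
    sugars = pd.DataFrame(sugar_rows)
    return annotation, sugars


def simulate_two_group_counts(
        n_genes: int = 500, n_a: int = 2, n_b: int = 2,
        dispersion: float = 0.05, log2fc=None,
        mean_log2_range: tuple[float, float] = (5.0, 9.0),
        lib_size_range: tuple[float, float] = (0.8, 1.25),
        seed: int = 0) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Two-group NB counts for differential-expression calibration studies.

    ``log2fc`` is a scalar or per-gene array of true group-B effects
    (default 0: fully null).  Returns (counts, group_a samples, group_b
    samples).
    """
    rng = np.random.default_rng(seed)
    base = np.exp2(rng.uniform(*mean_log2_range, n_genes))
    lfc = np.zeros(n_genes) if log2fc is None else np.broadcast_to(
        np.asarray(log2fc, float), (n_genes,))
    lib = rng.uniform(*lib_size_range, n_a + n_b)
    mu = np.column_stack([base] * n_a + [base * np.exp2(lfc)] * n_b) * lib[None, :]
    if dispersion > 0:
        counts = rng.negative_binomial(1.0 / dispersion,
                                       1.0 / (1.0 + dispersion * mu))
    else:
        counts = np.rint(mu).astype(np.int64)
    samples = [f"A{i+1}" for i in range(n_a)] + [f"B{i+1}" for i in range(n_b)]
    return (pd.DataFrame(counts, index=_gene_ids(n_genes), columns=samples),
            samples[:n_a], samples[n_a:])


def write_dataset(config: SimConfig, out_dir) -> dict[str, Path]:
    """Generate everything and write the on-disk dataset.

    Files: counts.tsv, design.tsv, annotation.tsv, germination.csv,
    sugars.csv, truth.json, truth_log2fc.tsv.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts, design, truth = generate_expression_dataset(config)
    annotation, sugars = generate_annotation_and_sugars(config)
    curves = generate_viability_curves(config)

    paths = {}
    paths["counts"] = out / "counts.tsv"
    counts.rename_axis("gene").to_csv(paths["counts"], sep="\t")
    paths["design"] = out / "design.tsv"
    design.to_csv(paths["design"], sep="\t", index=False)
    paths["annotation"] = out / "annotation.tsv"
    annotation.to_csv(paths["annotation"], sep="\t", index=False)
    paths["germination"] = out / "germination.csv"
    germ = pd.concat([c.observations.assign(stage=c.stage_label) for c in curves])
    germ[["stage", "time_d", "replicate", "n_seeds", "n_germinated"]].to_csv(
        paths["germination"], index=False)
    paths["sugars"] = out / "sugars.csv"
    sugars.to_csv(paths["sugars"], index=False)
    paths["truth"] = out / "truth.json"
    payload = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "module_genes": sorted(truth.module_genes),
        "tail_genes": sorted(truth.tail_genes),
        "chloro_genes": sorted(truth.chloro_genes),
        "reference_genes": sorted(truth.reference_genes),
        "true_p50": truth.true_p50,
    }
    paths["truth"].write_text(json.dumps(payload, indent=1))
    paths["truth_log2fc"] = out / "truth_log2fc.tsv"
    truth.true_log2fc.rename_axis("gene").to_csv(paths["truth_log2fc"], sep="\t")
    return paths
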