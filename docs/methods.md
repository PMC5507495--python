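# Methods

This note documents the models implemented in `seedlong`, the defaults
and their rationale, what the synthetic-data generator does and does not
emulate, and the numerical choices a user should know about. No empirical
claim here goes beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Longevity estimation (P50)

Controlled deterioration stores seeds at 35 °C / 75 % RH and assays
germination at intervals. The estimator pools replicate counts per time
point and maximises the binomial likelihood of

G(t) = G₀ / (1 + exp((t − p₅₀) / s)),

over (logit G₀, p₅₀, log s) with Nelder–Mead, initialised from the
linearly interpolated half-viability crossing. P50 is defined against the
*initial* (t = 0) germination — "loss of viability of 50 %" — which for
this parameterisation is exactly the midpoint parameter, so no root
finding is needed. Numerical choices:

* **Censoring.** If observed germination never falls to half its initial
  level within the assay window, the lot is censored and P50 is reported
  as a lower bound equal to the last storage time. A fitted midpoint
  beyond the window is likewise reported censored.
* **Fallback.** If the optimiser fails, the earliest linear-interpolated
  crossing of the half-viability level is reported
  (`method="interpolation"`); flat segments at exactly 50 % resolve to
  the earliest crossing time.
* **Diagnostics.** Residual deviance against the saturated model is
  attached to MLE fits.

Whether the original assays were fitted or interpolated is not knowable
from summaries alone, so both routes exist and the method used is recorded
in the output.

## Normalisation and differential expression

Size factors are DESeq-style median-of-ratios (per-gene geometric-mean
reference over genes positive in all samples), rescaled to geometric mean
1. A consequence worth knowing: multiplying one of *n* libraries by *c*
rescales *every* normalised value by c^(1/n) — relative profiles are
invariant, absolute totals are not; the tests check invariance up to that
single global factor.

The log layer is log2(normalised + 1); the pseudocount is configurable but
1 keeps a variance threshold of 1 meaningful on this scale, which is why
the variance filter (strictly > 1) operates there.

The DE test is a deliberate, documented simplification of a full
DESeq2-style analysis: a per-gene NB Wald test with a **single pooled
dispersion** and no shrinkage. With group means q̂ = mean of normalised
counts (+ half a normalised count, so zero-mean genes stay finite),

Var(ln q̂) ≈ (1/n²) Σⱼ [ 1/(q̂ sⱼ) + α ],

and the Wald statistic is ln(q̂_B/q̂_A) over the combined standard error.
The pooled dispersion α is estimated by method of moments from replicated
groups as a ratio of sums, α̂ = Σ(v − c·m) / Σ m², because at n = 2 the
per-gene moment estimates have one degree of freedom and their median is
badly biased. Significance requires fold ≥ 2 (inclusive — "at least
two-fold") *and* BH-adjusted p < α; α defaults to 0.05 with 0.01 used for
the mature-vs-dried contrasts. The simplification is validated by
simulation (type-I error and power against planted effects) rather than
by equality with any particular external implementation.

Sample diagnostics: Pearson correlation between log-layer transcriptomes,
and PCA after per-gene **median** centring (computed by SVD directly,
since standard PCA routines mean-centre). Component signs are fixed by
making each component's largest-magnitude gene loading positive, so
coordinates are reproducible across runs.

## Network and gene significance

Edges connect variance-retained TF genes with pairwise PCC ≥ 0.97 across
libraries, positive correlations only; the cutoff is inclusive (the
boundary case is tested). Only genes with at least one qualifying edge
become nodes. Stage-of-max and gene significance both use **fresh-stage
means** (replicates averaged first, dried libraries excluded), so
replicate imbalance cannot weight the correlations and the dried sample —
which has no position on the developmental P50 trajectory — never enters
the trait correlation. GS = |PCC(stage-mean profile, P50 vector)| with the
underlying sign retained; fewer than three stages is refused as unstable.
The longevity module is the node set with GS > 0.9 (strict); its family
composition and induced edge density are reported. No layout is computed —
the graph is exported as GraphML for external viewers.

## Enrichment statistics

* **χ² family enrichment**: per-family 2×2 (in tail × in family), Pearson
  χ² with 1 df and no continuity correction (the tool-typical choice);
  zero expected cells raise.
* **Hypergeometric GO tests**: upper tail P(X ≥ k) for over- and lower
  tail P(X ≤ k) for under-representation, both reported. Annotations are
  consumed as already-propagated gene → term lists; the genome size
  defaults to the number of annotated genes supplied. Because the
  correction behind published "corrected p" columns is often unnamed, BH
  and Bonferroni are emitted side by side.
* **Bin-wise Wilcoxon**: each functional bin's per-gene statistic
  (typically a stage-wise log2 change) against all remaining genes,
  two-sided. Exact rank-sum p for tie-free bins smaller than 10,
  tie-corrected normal approximation otherwise; Bonferroni over bins;
  z = Φ⁻¹(1 − p_corr/2) signed by the bin's median shift (p = 0.05 maps
  to |z| = 1.96).

## Contrast algebra and qPCR

Venn overlaps report integer percentages rounded half-up (matching the
convention of printed figures). Heat-map selection takes genes with
|Δ log2 stage mean| strictly above a threshold (default 4, i.e. a 16-fold
ratio — the "intensity difference" reading of an ambiguous convention;
the threshold is configurable so the ratio reading is reachable too) and
GS > 0.85, returning a mean-centred log2 matrix. The 2^−ΔΔCt computation
aggregates the two reference genes by the arithmetic mean of their Ct
values (equivalent to a geometric mean of linear quantities) and assumes
an amplification efficiency of 2.0 per cycle; primer-efficiency
correction is out of scope and the assumption is recorded in the output
metadata. Platform agreement is the squared Pearson correlation of log2
profiles over shared stages, with the signed r reported separately.

## The synthetic-data generator

The generator reproduces the *statistical design* of a late-maturation
study: ten libraries over fresh stages 7.1 → 9 with nested duplicates at
7.2 and 9 plus two rapidly dried 7.2 libraries, and a P50 trajectory of
0, 28, 33, 38, 43, 48 d — the sharp rise at physiological maturity
followed by a near doubling to the dry seed. Planted cohorts, all on log2
stage-mean profiles with stage-level Gaussian noise (SD 0.2 by default):

* **Module** (27 TFs): affine in the P50 vector, amplitude ~5 log2 units;
* **Tail** (40 TFs): Gaussian bump at stages 7.2–7.3, family draws
  oversampling AP2/EREBP (0.20) and WRKY (0.11);
* **Chloroplast-like** (60 genes): monotone decay after 7.1, annotated to
  the chloroplast compartment and photosynthesis GO terms;
* **Reference genes** (20): constant means, counting noise only;
* **Background TFs** (150): transient bumps centred away from the final
  stage, plus flat/transient non-TF background to 2000 genes.

Counts are NB(mean = libsize × stage-mean, dispersion α); α defaults to
0.01 — duplicated libraries in this kind of bulk design are extremely
reproducible (correlations ≈ 0.97–0.98), which corresponds to a very low
biological dispersion. α = 0 gives the deterministic rounded-mean limit.
The dried-7.2 mean is a linear 60/40 mixture of the 7.3 and 8.1 means,
encoding that premature drying accelerates the maturation programme; the
weight is configurable. Viability assays draw Binomial(25, q(t)) per
replicate from the logistic decay with scale 3 d on a weekly 0–70 d grid;
sugar tables are deterministic smooth curves whose axis RFO/Suc ratio is
non-decreasing by construction. Gene identifiers follow a Glyma-like
synthetic pattern (`SYN.01G000100`); no real accessions are emitted.

What the generator does **not** emulate: read-level artefacts (GC/length
bias, mapping ambiguity), ontology structure beyond flat term lists,
batch effects, and biological variance between field replicates (the
stage-noise SD is a free knob because source studies pool seeds from many
plants and do not report it). Passing recovery tests therefore
demonstrates correctness of the estimators under the stated generative
model, not robustness to every artefact of real libraries.

## Study sizes and reproducibility

The seeded studies in `seedlong.validation` use: 200 replicate assays for
P50 recovery (targets 28 and 48 d), 20 datasets for module recovery and
for the PCA-interposition check, and 200 two-group simulations
(400 null + 100 effect genes at |log2FC| = 3, dispersion 0.05, 2 vs 2)
for DE calibration — sizes chosen to keep Monte-Carlo error well below
the effects being measured while the whole battery runs in seconds. All
randomness flows through `numpy.random.default_rng` seeded from a single
user seed; equal seeds give bit-identical outputs everywhere, including
the generator.

## Known limitations

* The NB Wald test is anti-conservative for very low counts and n = 1
  contrasts rely entirely on the pooled dispersion (as any
  no-replication analysis must).
* GS on six stage points is a coarse correlation; the module threshold
  0.9 is meaningful only because planted signal amplitudes dominate the
  stage noise.
* The P50 estimator assumes a monotone logistic loss of viability; lots
  with non-monotone germination (dormancy release during storage) would
  need a different model.
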