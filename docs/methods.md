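# Methods

This note documents the models and procedures implemented in `gbpscore`,
the defaults they ship with, and the choices made where the design was
genuinely open.

## Score construction

The GBPs-score condenses the seven-gene family (GBP1–GBP7) into one scalar
per sample. Genes are standardized across samples (center, unit variance,
sample sd with ddof = 1) and the gene–gene **correlation** matrix is
eigen-decomposed. A sample's score is the sum of its coordinates on the
first two principal components, `score_s = Σ_g (w¹_g + w²_g) · z_gs`.
Design choices:

* **Correlation rather than covariance PCA.** Standardizing first prevents
  the highest-variance family member from dominating the loadings; the two
  coincide only when all gene variances are equal.
* **Sign convention.** Eigenvectors are defined up to sign. Each retained
  component is flipped so its loading sum is strictly positive (tie broken
  by making the first gene's loading positive). This makes the score rise
  with family expression and makes the output independent of the
  eigen-solver's arbitrary sign choices — a tested invariance.
* **Missing family genes** are excluded (recorded on the model), never
  imputed; at least two must remain. Zero-variance genes are rejected by
  name, with a relative threshold (sd ≤ 1e-12·(|mean|+1)) so constant rows
  carrying float rounding noise are still caught.
* **Per-cohort fitting.** The model is fitted and the median split taken
  within each cohort; transferring a fitted model to another matrix is
  supported (`compute_scores` with any matrix containing the model genes)
  but is not the default workflow.
* **Ties at the cutoff go to the low group** (strict `>` defines "high"),
  a deterministic, documented rule.

## Stratification and survival

* **Median split** is the default. The **maximally-selected cutoff**
  evaluates every observed score value between the `min_prop` and
  `1 − min_prop` quantiles (default 0.1, half-open on the right) and keeps
  the cutoff maximizing the absolute standardized log-rank statistic
  |z| = |O − E|/√V. Because the maximum over many candidate splits inflates
  the test, the attached naive p-value carries an explicit
  `selection_corrected=False` flag; no improved-Bonferroni correction is
  applied, and a test demonstrates the inflation on null data (the reason
  the flag exists).
* **Kaplan–Meier and the cross-group log-rank test** are delegated to
  `lifelines`; a unit test pins the statistic to a hand-computed
  observed-vs-expected table.
* **Cox proportional hazards** uses `lifelines`' Newton–Raphson maximizer
  with **Efron tie handling** (better behaved than Breslow under the heavy
  ties integer-rounded times can produce). Missing covariates are handled
  complete-case with the dropped count logged. Note that exact invariance
  of β̂ under dataset duplication holds for the Breslow partial likelihood,
  not Efron's; the test suite checks the exact Breslow property against an
  independent Newton–Raphson oracle and near-invariance (≤2%) for the
  Efron fit.
* **Concordance**: Harrell's C via `scikit-survival` (tied risks 0.5),
  returned with the number of comparable pairs. The **time-dependent
  curve** C(t) is the truncated-pair estimator: pairs (i, j) with
  t_i < t_j, subject i an observed event and t_i ≤ t. With no censoring,
  C(max follow-up) equals Harrell's C exactly.
* Confidence level is fixed at 95%, all tests two-sided. Survival time
  units are cohort-supplied and never rescaled; the pipeline records a
  unit label for reporting only.

## Single-sample enrichment (ssGSEA)

Within one sample, genes receive ascending average ranks r (highest
expression → rank N) and are walked in descending expression order; the
enrichment score is the running-sum integral
`Σ_positions (weighted in-set ECDF − unweighted out-of-set ECDF)` with
in-set weights |r|^α. Defaults and conventions:

* **α = 0.25**, the original single-sample weighting.
* **normalize="range"** divides the whole signature × sample matrix by its
  max − min (making that span exactly 1); `"none"` returns raw integrals.
  Per-sample rankings are independent of the set list, so any one set's
  unnormalized scores do not change when other sets are added (tested).
* **Ties** get average ranks (equal weights) and are walked in matrix row
  order — fully deterministic. The statistic is rank-based, hence
  invariant to any strictly monotone per-sample transform (tested with
  exp and affine maps).
* A set covering **all** genes leaves the out-of-set ECDF undefined; the
  score is 0 by convention. Sets sharing fewer than `min_overlap` (2)
  genes with the matrix are skipped with a warning.
* Implementation equivalence to a literal loop transcription of the
  running sum is pinned to 1e-10 on random instances.

**Named signatures** (APM, CYT, 6-gene IFN-γ, 18-gene GEP,
cancer-immunity-cycle steps, immune-cell sets) ship as editable GMT files;
gene lists are configuration, not code. CYT is scored two ways: ssGSEA of
{GZMA, PRF1} (default) and the closed-form mean of log2 expression (the
log-scale geometric mean in which cytolytic activity was originally
defined); outputs name which was used.

**ESTIMATE-style scores**: immune and stromal scores are unnormalized
ssGSEA scores of the respective sets and `estimate_score` is exactly their
sum. The shipped immune/stromal lists are curated representative subsets
(the file is named `..._synthetic.gmt` to flag this); users should drop in
the published 141-gene lists for calibrated work. The purity map
`cos(0.6049872018 + 0.0001467884·estimate_score)` is the published cosine
fit; because its calibration is platform-specific it is **off by
default**, and values outside [0, 1] are clipped with a warning.

## Pre-ranked two-group GSEA

Genes are ranked by signal-to-noise (μ₁ − μ₂)/(σ₁ + σ₂) (denominator
floored at 1e-8); the enrichment score is the classic weighted
Kolmogorov–Smirnov maximum deviation with weight |metric|¹. The null is
**phenotype permutation** (seeded), appropriate at group sizes ≥ 3:
labels are permuted `n_perm` times (≥ 100 required; default 999), the ES
recomputed, and the p-value taken one-sided against same-sign null scores,
floored at 1/(n_perm + 1). NES divides ES by the mean same-sign null
magnitude; BH adjustment runs across the sets of one call. Null
calibration (random sets, label-free data) is checked in the acceptance
battery: the rejection rate at α = 0.05 stays within [0.01, 0.10].

## Descriptive statistics

Pearson correlation with pairwise-complete missingness and the two-sided
t-approximation p; Wilcoxon rank-sum as the default two-group test (exact
enumeration when both groups ≤ 25 and untied, normal approximation with
tie correction otherwise), Student's t on request; χ² for categorical
tables with Fisher's exact fallback on 2×2 tables when any expected count
is below 5. BH is applied within each analysis family (one correlation
heat map, one checkpoint panel) and both raw p and q are reported. The
checkpoint panel resolves common aliases (PD-L1 → CD274, PD-1 → PDCD1,
CTLA-4 → CTLA4) and logs the mapping.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes — a
single latent "immune-hot" factor driving family and immune-signature
co-expression, protective of survival, predictive of immunotherapy
response:

* **latent_s ~ N(0, 1)**, one factor (the simplest structure under which
  every downstream claim is testable);
* **expression** x_gs = loading_g·latent_s + ε, ε ~ N(0, noise_sd²);
  defaults: family loadings 1.0, immune-signature genes 0.8, stromal genes
  0.3, checkpoints 0.8, noise genes 0, noise_sd = 1 — giving family
  pairwise correlations of 0.5 and PC1+PC2 cumulative variance around
  60–65%;
* **survival** from an exponential proportional-hazards model,
  hazard = baseline·exp(β·latent) with baseline 0.05 per time unit and
  β = −0.8 (protective) by default; an optional step-hazard mode
  (`hazard_step_at`) replaces β·latent with β·1[latent > s] for
  cutoff-recovery experiments;
* **censoring** is an independent exponential whose rate is calibrated by
  log-scale bisection against the drawn event times so the realized
  censored fraction hits the target (default 0.30) to within sampling
  granularity — comfortably inside ±5 points at n ≥ 300 (tested over 10
  seeds);
* **responder labels** ~ Bernoulli(sigmoid(slope·latent)), slope 1.0;
* **mutations** are i.i.d. Bernoulli per family gene per sample at rate
  0.004 (≈ 2.8% of samples carrying any family hit, the order of the
  reported cohort frequency), independent of expression.

Default cohort size is 400 samples with 200 noise genes, the scale of the
mid-sized public HCC cohorts. All randomness flows from one integer seed;
identical configs are bit-identical. What the generator does **not**
emulate: FPKM count noise, batch effects, multi-factor immune biology,
covariate–outcome confounding (clinical covariates are drawn independent
of the latent factor), or single-cell dropout. Passing recovery tests
therefore demonstrates correctness of the estimators under the assumed
structure, not robustness to real-data pathologies.

## Pipeline

`run_pipeline` executes io → scoring → stratify → survival → enrichment →
association, writing TSVs plus `run_manifest.json` (config, config hash,
versions, per-stage row counts, updated as each stage completes so partial
output survives a failure). One global seed fans out to fixed per-stage
child seeds via `SeedSequence([seed, stage_index])`, so disabling one
stage never shifts another's randomness. Tables carry a header comment
with the config hash and seed; floats are written as `%.17g` and read back
with round-trip parsing, so write→read is exact. Re-running the same
config and seed reproduces the numeric payload byte for byte.

## Problem sizes in the test and acceptance batteries

Oracle equivalences run on 7 × 100 score matrices (20 seeds) and
50 × 10 × 5 ssGSEA instances; Cox coverage uses 100 seeds at n = 500 on
family-gene-only cohorts (the identical survival process without the
signature block); GSEA null calibration uses 200 random sets across 20
null datasets at 199 permutations; the PCA permutation calibration uses
50 seeds at n = 50 per group; maximally-selected-cutoff recovery uses 10
seeds at n = 400. These sizes keep the whole battery in the tens of
seconds while leaving the Monte-Carlo bands quoted above comfortably wide.

## Known limitations

* The maxsel p-value is selection-inflated by design and flagged, not
  corrected.
* The ESTIMATE purity constants are only meaningful with the original
  platform and gene lists; with the shipped stand-in lists the purity
  column is a monotone transform of the combined score, nothing more.
* The per-gene optimal-split survival report inherits the maxsel
  inflation; its HR directions are reliable under strong effects only.
* Pre-ranked GSEA supports exactly two phenotype groups.
* IHC scoring is the scalar composite (grade × positive rate) only; no
  image analysis.
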