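# gbpscore

Guanylate-binding proteins (GBP1–GBP7) are interferon-γ–inducible GTPases
whose coordinated expression marks an "immune-hot" tumor microenvironment.
`gbpscore` condenses the expression of this seven-gene family into a single
per-sample **GBPs-score** and provides the full downstream analysis a tumor
cohort study needs: survival stratification, Cox modelling, concordance
evaluation, and single-sample immune profiling. It is aimed at
computational oncologists working with bulk expression cohorts
(log2-transformed FPKM-like matrices plus a clinical table), and at anyone
who wants a fully tested, reproducible reference implementation of this
class of PCA-signature analysis.

## The score

Each family gene *g* is standardized across samples,
z<sub>gs</sub> = (x<sub>gs</sub> − μ<sub>g</sub>)/σ<sub>g</sub>, and the
gene–gene correlation matrix is eigen-decomposed. With w¹, w² the unit-norm
loading vectors of the first two principal components, a sample's score is
the sum of its coordinates on those components:

```
score_s = Σ_g (w¹_g + w²_g) · z_gs
```

Each component's sign is chosen so its loading sum is positive, anchoring
the score's polarity to rise with family expression. Cohorts are split into
high/low score groups at the median (ties to low) or at a maximally
selected log-rank cutoff.

Around the score sit:

* **survival** — Kaplan–Meier / log-rank (lifelines), Cox proportional
  hazards with Efron ties, Harrell's and time-dependent concordance,
  maximally-selected cutoff search (with an explicit "selection-inflated
  p" flag);
* **enrichment** — a from-scratch ssGSEA (rank-weighted running-sum
  integral), the named immune scores (APM, CYT, 6-gene IFN-γ, 18-gene
  T-cell-inflamed GEP, cancer-immunity-cycle steps, immune-cell sets, all
  shipped as editable GMT configuration), ESTIMATE-style immune/stromal
  scores, and pre-ranked two-group GSEA with phenotype permutation;
* **association** — Pearson correlations, Wilcoxon/t group comparisons,
  χ²/Fisher categorical tests, checkpoint-gene panel, all with BH
  adjustment per analysis family;
* **synthetic cohorts** — a generator that draws expression, survival,
  responder labels and mutations from a single latent "immune-hot" factor
  under an exponential proportional-hazards model, so every stage is
  testable end-to-end without downloading any cohort.

## Worked example

```python
import pandas as pd
from gbpscore import (SimulationConfig, generate_cohort, fit_score_model,
                      compute_scores, stratify, cox_fit, km_fit,
                      named_signature_scores, correlate)

cfg = SimulationConfig(n_samples=400, seed=1)          # default study conditions
expr, clin, mut, truth = generate_cohort(cfg)

model = fit_score_model(expr)                          # correlation-PCA on GBP1-GBP7
scores = compute_scores(model, expr)                   # per-sample GBPs-score
print(f"PC1+PC2 cumulative variance: {model.explained_variance_ratio_[:2].sum():.1%}")

groups = stratify(scores, rule="median").group         # median split, ties -> low
km = km_fit(clin.os_time, clin.os_event, groups)
print(f"log-rank chi2 = {km.logrank_statistic:.1f}, p = {km.logrank_p:.2e}")

fit = cox_fit(clin.os_time, clin.os_event,
              pd.DataFrame({"high_group": (groups == "high").astype(float)}))
row = fit.summary.loc["high_group"]
print(f"high vs low HR = {row.hr:.3f} (95% CI {row.ci_low:.3f}-{row.ci_high:.3f})")

ifng6 = named_signature_scores(expr).scores.loc["IFNG6"]
rep = correlate(scores, ifng6, name="score~IFNG6")
print(f"Pearson r(score, IFNG6) = {rep.r:.3f} (p = {rep.p:.1e}, n = {rep.n})")
```

prints

```
PC1+PC2 cumulative variance: 63.7%
log-rank chi2 = 58.9, p = 1.63e-14
high vs low HR = 0.393 (95% CI 0.308-0.503)
Pearson r(score, IFNG6) = 0.632 (p = 6.5e-46, n = 400)
```

The first two components carry ~64% of the family's variance, so summing
their projections preserves most of the coordinated GBP signal. The hazard
ratio below 1 with a confidence interval excluding 1 says high-score
patients die at well under half the rate of low-score patients in this
cohort — the latent immune-hot factor is wired protective
(`hazard_coef_latent = -0.8`) and the pipeline recovers that direction.
The positive correlation with the 6-gene IFN-γ signature reflects the
co-regulation of the family with interferon response.

There is also a CLI: `gbpscore demo --out ws` generates and analyses a
small cohort; `gbpscore run --config run.yaml` drives user data;
`gbpscore score / enrich / survive` expose the individual stages.

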