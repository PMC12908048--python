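# dysbiom

Gut-microbiome dysbiosis scoring, diversity statistics and prognostic
modelling for post-stroke infection cohorts.

After an acute ischemic stroke, roughly half of patients develop a systemic
infection within the first week, and the gut microbiome appears to be part
of the story: infected patients show enrichment of opportunistic
Enterobacteriaceae-type taxa, depletion of short-chain-fatty-acid (SCFA)
producers, and derangement of serum biomarkers of gut-barrier injury and
inflammation (NMDAR NR2B, butyrate, TMAO, RANKL, iFABP, LPS). `dysbiom`
packages the full analysis chain used to study this association as tested,
reusable code, together with a synthetic cohort generator so every stage can
be exercised and calibrated without access to patient data.

## What it computes

* **Dysbiosis indices.** The Microbial Dysbiosis Index
  `MDI = log10[(1 + Σ a_pathogenic) / (1 + Σ a_beneficial)]`
  over a panel of enriched/depleted taxa, and the Stroke Dysbiosis Index
  `SDI = log10[(ε + Σ w_i a_i) / (ε + Σ w_j a_j)]`, its weighted
  generalisation; with unit weights and ε = 1 the SDI reduces exactly to the
  MDI. Panels ship as JSON or are derived from labelled data
  (per-taxon Mann–Whitney + Benjamini–Hochberg FDR).
* **Diversity.** Per-sample Shannon, Pielou, Gini–Simpson and Chao1;
  Bray–Curtis distances; PCoA; one-factor PERMANOVA (exact enumeration on
  small designs, add-one Monte-Carlo p otherwise) and BETADISPER dispersion
  homogeneity.
* **Cohort statistics.** Group comparisons with an explicit test-selection
  policy (Shapiro screen → t vs Mann–Whitney; expected-cell rule → chi-square
  vs Fisher), Spearman/Pearson correlations, BH-FDR adjustment, and the
  platelet-to-lymphocyte ratio.
* **Prognosis.** Univariate logistic screening at p < 0.10, multivariable
  logistic regression (ridge fallback under separation), rank-based ROC AUC,
  and Harrell bootstrap optimism correction with the screening step repeated
  inside each of the (default 1,000) resamples:
  `AUC_corrected = AUC_apparent − mean(AUC_boot − AUC_test)`.
* **Co-occurrence networks.** Per-group taxon networks (prevalence filter,
  pairwise Spearman, BH-FDR, |r| threshold) with node/edge/degree/component
  summaries.

## Worked example

```python
from dysbiom import (CohortSpec, generate_cohort, bray_curtis, permanova,
                     compute_indices)

cohort = generate_cohort(CohortSpec(seed=1))       # 80 patients, 37 infected
labels = cohort.metadata.infection.to_numpy()

dm = bray_curtis(cohort.abundance)
res = permanova(dm, labels, n_perm=999, seed=1)
print(f"PERMANOVA R2 = {res.r_squared:.4f}, p = {res.p_value:.3f}")

idx = compute_indices(cohort.abundance, cohort.panel())
print(f"mean SDI infected     = {idx['sdi'][labels == 1].mean():+.4f}")
print(f"mean SDI non-infected = {idx['sdi'][labels == 0].mean():+.4f}")
```

prints

```
PERMANOVA R2 = 0.0343, p = 0.001
mean SDI infected     = +0.0158
mean SDI non-infected = -0.0378
```

i.e. the planted pathogen enrichment / SCFA-producer depletion produces a
significant compositional separation between groups (about 3.4% of distance
variance here) and an elevated dysbiosis index in the infected group.

The same pipeline is available from the shell:

```bash
dysbiom simulate --seed 1 --out cohort/           # write synthetic tables
dysbiom run --seed 1 --out results/               # full analysis, manifest
dysbiom report --out results/                     # one-screen summary
```

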