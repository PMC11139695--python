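# dietclust

Data-driven dietary-pattern discovery from ordinal diet-history
questionnaires, and association analysis of the discovered patterns with
incident hypertension.

`dietclust` is aimed at nutritional epidemiologists working with
brief-type self-administered diet history questionnaire (BDHQ) style
instruments: 79 ordinal variables covering food-intake frequency
(58 items), dietary behaviors (12), and cooking methods (9), collected
alongside clinical covariates in a prospective cohort. Instead of scoring
the diet against a hypothesis-driven index, the package extracts patterns
from the joint response structure and then quantifies their association
with new-onset hypertension.

## The method

1. **Encoding.** Ordinal responses are mapped to 1-based integer scale
   positions (raw, unstandardized).
2. **Embedding and clustering.** The n x 79 matrix is reduced to 2D with
   UMAP (Chebyshev metric, `n_neighbors = 10`, `min_dist = 0.1`) and
   partitioned with K-means (k-means++, 10 restarts). The number of
   clusters is selected jointly from the WCSS elbow, the mean silhouette,
   and the number of modes of a 2D Gaussian KDE over the embedding (the
   "contour-map" check); all three diagnostics are always reported.
3. **Trend scores.** Each cluster x variable cell is summarized by the
   trend score `sum_i w_i * pi_i`, where `w_i` are the instrument's
   integer category weights (1..L, increasing with frequency/intensity)
   and `pi_i` the within-cluster category proportions. The score equals
   the cluster mean of the mapped weights and is bounded by the extreme
   weights. Cross-cluster differences per variable are tested by one-way
   ANOVA on participant-level weights.
4. **Odds ratios.** With the largest / most-affected cluster as
   reference, crude odds ratios are cross-product ratios of the 2 x K
   case/non-case table with Wald 95% CIs,
   `exp(ln OR ± 1.96 * sqrt(1/a + 1/b + 1/c + 1/d))`; adjusted logistic
   models add, in stages, age + BMI; smoking, education, physical
   activity; dyslipidemia, diabetes; and salt intake. Each model's
   cluster-effect p-value is a likelihood-ratio test against the same
   model without the cluster indicators.
5. **Sensitivity and comparison.** An age-caliper matched re-analysis
   (±0 and ±2 years; a participant is kept only if every other cluster
   contains an age counterpart within the caliper) guards against age
   confounding, and a DASH diet-quality score (8 components scored 1-5 by
   cohort quintile, total 8-40) provides a hypothesis-driven comparator.

A synthetic cohort generator plants K latent patterns (Dirichlet-
around-a-modal-category response distributions with one separation knob),
study-like covariate imbalance, and logistic outcomes with known pattern
odds ratios, so the full pipeline is testable end to end without any
original data.

## Worked example

Crude odds ratios from a published-style 2 x 4 hypertension table
(cases / non-cases of 6/69, 17/113, 9/91, 32/110 across four pattern
clusters, reference D):

```python
import dietclust as dc
from dietclust.assoc import ContingencyTable2xK

table = ContingencyTable2xK(clusters=["A", "B", "C", "D"],
                            cases=[6, 17, 9, 32],
                            non_cases=[69, 113, 91, 110],
                            reference="D")
for r in dc.crude_or(table):
    print(f"cluster {r.contrast} vs {r.reference}: OR {r.odds_ratio:.3f} "
          f"(95% CI {r.ci_low:.3f}-{r.ci_high:.3f}), model LR p = {r.lr_p:.3f}")
```

```
cluster A vs D: OR 0.299 (95% CI 0.119-0.752), model LR p = 0.006
cluster B vs D: OR 0.517 (95% CI 0.272-0.985), model LR p = 0.006
cluster C vs D: OR 0.340 (95% CI 0.154-0.749), model LR p = 0.006
```

Clusters A-C each carry significantly lower odds of incident hypertension
than the reference pattern; the 3-df likelihood-ratio test of any cluster
effect gives p = 0.006.

Pattern discovery on a synthetic study-like cohort, via the
scikit-learn-style estimator:

```python
scenario = dc.study_like_preset(seed=0)       # 4 planted patterns, n = 447
cohort, latent = dc.generate_cohort(scenario)
est = dc.DietaryPatternClusterer(random_state=0)
labels = est.fit_predict(dc.encode_matrix(cohort))
d = est.diagnostics_
print(f"selected k = {est.k_} (silhouette optimum {d.silhouette_k}, "
      f"KDE modes {d.kde_peak_count}, elbow {d.elbow_k})")
```

```
selected k = 4 (silhouette optimum 4, KDE modes 4, elbow 4)
```

All three diagnostics agree on the planted four patterns; against the
withheld latent labels the K-means partition reaches an adjusted Rand
index of 0.968.

The same pipeline is scriptable from the shell:

```bash
dietclust run --out my_run --seed 0      # full pipeline on the preset
dietclust simulate --out cohort.csv --n 447 --seed 1
dietclust cluster --cohort cohort.csv --out clusters
```

A run directory contains the embedding, labels, selection diagnostics,
trend table, contingency and odds-ratio tables (crude, adjusted,
age-matched), DASH report, and a manifest with the config hash and
per-stage seeds; reruns with the same config are byte-identical.

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-data
generator and its limits, and the numerical design choices (cluster-number
decision rule, KDE bandwidth, quintile tie handling, separation
diagnostics).
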