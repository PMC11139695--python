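# Methods

## Scope and model

`dietclust` implements a data-driven dietary-pattern analysis for
male-cohort hypertension studies built on a BDHQ-style instrument. The
analysis chain is: exclusion cascade → ordinal encoding → 2D UMAP
embedding → K-means partition with principled cluster-number selection →
trend-score characterization → logistic odds-ratio models →
age-matched sensitivity analysis → DASH-score comparison. Every stage is
deterministic given its seed.

### Questionnaire schema

The packaged schema (`data/bdhq_schema.yaml`) defines 79 ordinal
variables: 58 food/beverage items, 12 dietary behaviors, 9 cooking
methods. Scales have 2, 5, 7, 8 or 9 ordered categories depending on the
item family (generic foods and cooking methods 7 points; non-alcoholic
beverages 8; miso soup, rice, breakfast and overall alcohol frequency 9;
specified alcoholic drinks 7; most behaviors 5; two binary behaviors).
Category weights are the consecutive integers 1..L in scale order —
strictly monotone with weight 1 at the lowest category. Responses are
stored as labels and encoded to integer positions only at analysis time,
so the weight maps remain auditable.

Two mappings the instrument leaves implicit were fixed here: seasonal
fruit items sit on the generic 7-point food row, and among behaviors only
breakfast uses the 9-point frequency row (supplements use the 7-point
frequency row; intentional habit change and dietary guidance are binary).

### Covariate rules

Diagnostic thresholds follow the usual clinical conventions, with the
comparison operators applied exactly as printed in the study protocols:
baseline hypertension SBP >= 140 mmHg or DBP >= 90 mmHg or
history/medication; diabetes FBG > 126 mg/dL (strict) or
history/medication; dyslipidemia LDL >= 140, HDL < 40 (strict),
TG >= 150 mg/dL, or medication; depressive symptoms SDS >= 40; typical
sleep 6-8 h inclusive. A rule whose inputs are missing yields an explicit
missing flag, never a silent negative; participants with missing
examinations leave the sample at the "incomplete health examination"
cascade step. Exclusion steps use first-step attribution (a participant
removable at several steps is counted at the first), which makes the
per-step counts disjoint and the flowchart arithmetic exact; permuting
steps can change per-step counts but never the final n.

### Clustering stage

The encoded matrix feeds UMAP with the study's tuned parameters
(`min_dist 0.1`, 2 components, `n_neighbors 10`, Chebyshev metric) and a
fixed `random_state`; K-means uses k-means++ with 10 restarts. Three
cluster-number diagnostics are always computed over k = 2..10:

- **WCSS elbow** — the k maximizing the second difference of the
  within-cluster sum of squares (the discrete curvature of the curve).
- **Silhouette** — the k maximizing the mean silhouette.
- **KDE mode count** — the number of local maxima of a 2D Gaussian kernel
  density estimate of the embedding on a 200 x 200 grid, counting strict
  3 x 3-neighbourhood maxima (flat plateaus merged by connected-component
  labeling) whose density is at least 5% of the global maximum.

Decision rule: the selected k is the KDE mode count whenever it agrees
with the elbow or the silhouette optimum (the density map confirms a
distance-based criterion, mirroring the contour-map confirmation step);
otherwise the silhouette optimum is returned with `agreed = False` as an
explicit flag for user override.

**KDE bandwidth.** The default is adaptive: 2.5 x the median distance to
the 10th nearest neighbour. Normal-reference rules such as Scott's are
derived for roughly unimodal targets; on the multi-island geometry UMAP
produces they oversmooth and merge adjacent modes, while fixed fractions
of them undersmooth flat unimodal clouds and manufacture spurious noise
modes. The nearest-neighbour rule tracks the finest populated data scale
in both regimes. `"scott"`, `"half-scott"` and explicit bandwidths remain
selectable in `ClusteringConfig`.

Ablations over variable categories ({all 79}, {food + behaviors},
{food + cooking}, {food only}, {behaviors only}) and item aggregation
(grouped columns as means of member columns) are first-class
configurations of `encode_matrix`; clusterings are compared by
`cluster_overlap`, which matches labels one-to-one by Hungarian
assignment on the contingency matrix (ties toward the lowest label) and
reports per-cluster agreement percentages.

### Trend scores

For cluster c and variable v with weights `w` and within-cluster category
proportions `pi`, the trend score is `sum_i w_i pi_i` — algebraically the
mean mapped weight over the cluster's participants, which the test suite
uses as an independent oracle. Scores are bounded by the extreme weights
and attain them only for degenerate distributions. The instrument does
not specify the cross-cluster test for trend differences; one-way ANOVA
on participant-level weights is used, consistent with the
ANOVA-for-continuous convention of the descriptive tables. Scores are
reported to 3 decimals.

### Association models

Crude odds ratios are cross-product ratios with Wald CIs on the log
scale. Zero cells raise an error by default; a Haldane continuity
correction (+0.5 to all four cells) is available behind an explicit flag.
The model-level p for the crude analysis is the G-test
(`G^2 = 2 sum O ln(O/E)`, K-1 df), identical to the deviance of the
cluster-only logistic model against the intercept-only model. Adjusted
models 1-5 nest covariate sets in the order: none; age, BMI; + smoking,
education, physical activity; + dyslipidemia, diabetes; + salt intake.
Smoking and physical activity enter as indicator sets, salt intake as a
continuous term; no interactions. Per-contrast CIs are Wald; the
likelihood-ratio construction is reserved for the model-level p (the two
agree on crude tables to the printed 2-3 decimals). The reference cluster
defaults to the largest cluster, ties broken by prevalence (the
plausibly aversive pattern), and is always overridable. Quasi-complete
separation is detected (non-finite estimates, |beta| > 30, or SE > 100)
and raised as a diagnostic error naming the offending column rather than
reported as a spurious OR.

### Age matching

The matched analysis uses caliper *filtering*: a participant is retained
iff every other cluster contains at least one member within the caliper
(0 or 2 years) of their age. This reading — rather than sampled 1:1
pairs — was chosen because the downstream reports are cluster-level odds
ratios, not pair-level strata, and it makes the matched subset
deterministic and monotone in the caliper (the ±0 subset is contained in
the ±2 subset). Exact (±0) matched runs drop age as a model covariate,
since the matched groups then share identical age support; ±2 runs keep
it. Whether a pair-sampling design would change the estimates cannot be
checked against published matched sample sizes, which are not reported.

### DASH score

Eight components — fruits, vegetables, nuts/legumes, low-fat dairy,
whole grains (favorable); sodium, sweetened beverages, red/processed
meats (restricted) — are scored 1-5 by cohort quintile of intake,
reversed for restricted components, and summed to 8-40. Quintiles are
rank-based (average ranks; `ceil(5r/n)`), so boundary ties fall to the
lower quintile deterministically; an all-constant component maps everyone
to the midpoint score 3 with a warning. Component intakes are direct
numeric inputs: they are not derivable from ordinal frequency categories
without a proprietary nutrient-estimation step, which is out of scope.
The pipeline's `synthetic_dash_components` constructs synthetic intakes
that load on thematically related questionnaire items, so cluster-wise
DASH contrasts are exercised end to end; it is a synthetic stand-in, not
a nutrient model.

## Synthetic-data generator

The generator emulates the structure of the study data, not its raw
values:

- **Patterns.** K = 4 latent patterns with mixing proportions
  75/130/100/142 out of 447. Per-(pattern, variable) response
  distributions are drawn once from
  `Dirichlet(alpha_j = 0.5 + 80 * s * 0.3^(|j - m|))`, where `m` is the
  pattern's modal category and `s in [0, 1]` a single separation knob
  (flat at 0, near-degenerate at 1; preset default 0.9). Signature
  variables sit at scale extremes per pattern — sweets/coffee high and
  protein/vegetables low for pattern 1; dairy/vegetables/fruit and daily
  breakfast for pattern 2; meats for pattern 3; seafood and alcohol for
  pattern 4 — mirroring the qualitative contrasts of the published trend
  table, with non-signature variables sharing a mid-scale mode.
- **Demographics.** Ages are truncated normals on [19, 70] with
  per-pattern means/SDs 40.25±8.27, 44.88±10.50, 43.74±8.86, 47.58±9.69
  years; BMI, blood pressure (truncated below the diagnostic cut — the
  sample is baseline-normotensive by design), lipids, fasting glucose,
  salt intake, smoking, education and physical-activity categories follow
  the published per-pattern summary statistics. Dyslipidemia and diabetes
  flags are then *derived* from the generated laboratory values by the
  covariate rules.
- **Outcomes.** Incident hypertension is Bernoulli with
  `logit p = intercept + log-OR[pattern]`; the preset intercept is
  `logit(32/142)` and the planted pattern odds ratios are the
  cross-product values of the published contingency table (0.2989,
  0.5171, 0.3400, 1), so expected prevalences are 8.0%, 13.1%, 9.0%,
  22.5%. Outcome draws use an RNG stream separated from the response
  stream.

The generator reproduces the *structure* a practitioner would meet —
ordinal scales, cluster-size imbalance, age confounding, realistic
prevalence — but not item-item correlations within a pattern
(conditional independence given the pattern), secular trends, item
non-response, or reporting bias. Passing recovery tests therefore shows
the pipeline is correct and well-calibrated under the planted model, not
that real BDHQ data contain four patterns.

A separate engineered roster (`enrollment_roster`) realizes the published
enrolment flowchart exactly: 1253 enrolled with per-step exclusion counts
99 (consent), 295 (female), 16 (missing diet), 52 (incomplete
examination), 9 (heart disease), 188 (SBP), 39 (DBP), 44 (hypertension
history), 64 (no follow-up), leaving 447.

## Numerical choices and degenerate inputs

- Proportion vectors must sum to 1 within 1e-12.
- Empty clusters, degenerate (all-identical) embeddings, non-positive
  bandwidths, off-scale responses, and unassigned participants raise
  errors naming the offending object.
- Constant variables yield undefined (NaN) p-values, reported as such,
  not p = 1.
- The KDE peak threshold is inclusive, so threshold 1.0 keeps exactly the
  global maximum.
- Caliper comparisons carry a 1e-9 absolute tolerance so float ages at
  the exact caliper boundary are retained.
- Per-stage seeds are derived from the global seed by SHA-256 of
  `"{seed}:{stage}"`, keeping stage results stable under pipeline
  reordering; all derived seeds are < 2^31.

## Problem sizes

Default study conditions are n = 447 participants and 20-seed replication
for recovery rates; generator calibration checks use a single n = 50,000
draw, where the Monte-Carlo standard error of a recovered odds ratio near
0.3 is about 0.013. These sizes are the package's reference conditions
for its own test suite and acceptance script.

## Known limitations

- The UMAP embedding is seed- and data-dependent; coordinates (and hence
  specific embeddings) are not comparable across library versions, only
  the recovered partition structure is.
- The trend-score ANOVA treats weights as interval-scaled, as the
  trend-score construction itself does.
- DASH component intakes must be supplied externally; the synthetic
  components are structural stand-ins.
- Logistic models assume complete covariates; there is no imputation by
  design (missingness is handled at the cascade).
- The matched analysis implements caliper filtering; pair-sampling
  designs are out of scope.
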