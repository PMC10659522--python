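# Methods

This note documents the models and procedures `metaboclock` implements,
the defaults it ships, the design choices made where the design was
genuinely open, and the limits of what the synthetic study can show.

## The synthetic study

The generator emulates the structure a multi-cohort metabolomic ageing
analysis must cope with, with every generating parameter recorded for
recovery tests.

**Population.** Each cohort draws subject ages uniformly within its age
range (a degenerate range models a birth cohort, flagged and excluded from
model training). Sex is Bernoulli per cohort; BMI is N(27, 4.5²) truncated
to [16, 50]; ethnicity is a two-level category (15% minority); smoking is
a 25% Bernoulli used as a generic binary exposure. Cohorts with nonempty
`visit_gaps` revisit every subject, advancing age by the gap; this yields
the repeat-visit subset used by the δ-age analyses. The default study has
five cohorts of 400 subjects with staggered ranges spanning 24–86 y, one
revisit cohort (6-y gap) and one single-sex cohort (which exercises the
rank-deficient-covariate handling in the association fits).

**Metabolites.** Concentrations follow
`x_m = batch_c × (base_m + s_m·age + c_m·(age−60)² + ε)` with ε Gaussian,
block-equicorrelated (blocks of 8, ρ = 0.3 by default) and floored at
zero (concentrations are non-negative; base means sit 5–12 SDs above
zero, so flooring is negligible). Uniform ages and block-equicorrelation
are idealizations chosen to keep every planted parameter identifiable —
they are not claims about real metabolite covariance, which the original
cohort data do not disclose.

**Signal scaling.** For `x = s·age + ε`, the best linear age predictor
attains `R² = q/(1+q)` with `q = var(age)·sᵀΣ⁻¹s` (Σ the noise
covariance, var(age) the pooled mixture variance over cohorts). The
default panel's slopes are scaled once, in closed form, so `R² = 0.5`;
out-of-fold performance of a well-specified clock should therefore
approach √0.5 ≈ 0.707. Curvature terms on four metabolites add mild
age-stratum heterogeneity (slope sign flips around age 60) without
materially moving this target.

**Mortality.** One Weibull-baseline proportional-hazards draw per subject
(shape 1.4, scale 40 y, administrative censoring at 15 y ⇒ ≈25% events),
linear predictor `Σ logHR_m·z_m + γ·(age − mean age)` with eight
metabolites carrying per-SD log hazard ratios of ±0.2–0.3 and γ = 0.05/y.
The draw is made at the subject's first visit and shared across visits,
so repeat samples stay coherent. Age is centred so the event rate is set
by the baseline, not the age origin.

**Contamination.** `inject_outliers` shifts a chosen fraction of rows
(default 2%) by a chosen magnitude (default 10 SD) along independent
random unit directions in metabolite space.

**Determinism.** All randomness flows from one integer seed; cohort- and
stage-local generators derive their seeds as
`(seed·1000003 + crc32(label)) mod (2³¹−1)`, so stages are independently
reproducible and identical inputs give byte-identical outputs.

## Pre-processing

**Variable QC** removes (in order) declared derived/ratio variables,
variables missing in ≥50% of any cohort, and variables whose paired
cross-protocol Pearson r falls below 0.7; each removal carries exactly one
reason code.

**Outlier weights.** Per cohort: centre and scale each metabolite by
median/MAD (1.4826 consistency factor), project onto principal components
retaining 99% of variance, re-robustify component scores by median/MAD,
and map the squared component-space distance d² linearly onto [0, 1]
between the χ² median and 99.9% point (k = number of retained
components): typical points get weight ≈ 1, and the flag threshold of 0.1
corresponds to a null false-flag rate of roughly 0.2%. The contract is
the flags, not the exact weight values; constant (zero-MAD) metabolites
are excluded from the distance with a logged warning. This is a
transparent robust-PCA scheme in the spirit of PCA-based outlier
detectors used in cohort metabolomics, not a re-implementation of any
specific one.

**Calibration.** One cohort (default the mixed-sex, mid-age-range
`whitegate`) is the reference. Target and reference samples are matched
cell-wise on 5-year age bands × sex × WHO BMI band × ethnicity; the
per-metabolite scale factor is the ratio of reference to target subset
medians over the matched cells (means available as a sensitivity switch),
applied multiplicatively to the whole target cohort. Medians were chosen
for robustness to residual outliers. Empty matched subsets and zero
medians are hard errors naming the cohort. Calibration is approximately
idempotent (factors within ±5% of 1 on re-run at n = 2000).

**Imputation.** k-NN (default k = 10) with neighbours ranked by Euclidean
distance over mutually observed, per-metabolite-standardized values;
distance ties break by sample-id order; a missing cell becomes the mean
of the metabolite over the k nearest samples in which it is observed.
Standardization prevents high-concentration metabolites from dominating
the metric. Needed only for externally supplied score panels with missing
biomarkers; the generator itself produces complete data.

## Association analyses

Age MWAS is per-cohort OLS of the metabolite on age + sex + BMI +
ethnicity (metabolite optionally z-scored; the choice moves only the
units). Age-band MWAS pools cohorts within bands 20–35, then 5-year bands
to 70, then >70, adding cohort as a categorical covariate. Mortality MWAS
is per-cohort Cox on the within-analysis standardized metabolite (log-HR
per SD) adjusted for age, sex, BMI; cohorts with <10 events are skipped
with a warning, as are constant-age cohorts in the age MWAS — skipped
strata are simply absent, and the pooled k reflects what was actually
pooled. Pooling is inverse-variance fixed-effect with Cochran's Q and I²
(heterogeneity called high above 0.75, low below 0.25); p-values are
large-sample normal; FDR is Benjamini–Hochberg across metabolites
(q < 0.05 is the significance default). No random-effects pooling is
offered.

## Collinearity pruning

VIFs are computed as the diagonal of the inverse empirical correlation
matrix (algebraically 1/(1−R²) from regressing each variable on the rest
with intercept); exact collinearity falls back to per-variable least
squares and reports +∞. Backward pruning removes the single largest-VIF
variable per step — ties broken by lexicographically first label, logged
— until all VIFs are below the threshold (default 5), and is performed
once on the pooled calibrated training data. The number of survivors is
data-dependent and is not a contract.

## Clock models

**Penalized fits.** The in-package coordinate-descent elastic net
minimizes `(1/2n)‖y − b0 − Xβ‖² + λ Σ f_j(α|β_j| + (1−α)β_j²/2)` with
predictors standardized internally and coefficients reported on the
original scale. Penalty factors are normalized to mean 1, making the fit
invariant to their overall scale; with all factors equal the phenotypic
construction reduces exactly to the plain elastic net. λ is selected by
k-fold (default 5) cross-validated MSE on a geometric grid of 60–80
points anchored at the uniform-factor λ_max and spanning four decades
down to an effectively unpenalized fit. The grid is deliberately
independent of the factors: p-value factors can be many orders of
magnitude below 1, no finite λ zeroes those variables, and a
factor-scaled grid would strand cross-validation in a regime where only
the low-penalty variables exist. α is fixed at 0.5 by convention.

**Penalty factors** for the phenotypic-age model are each metabolite's
pooled mortality p-value, replaced by 1 (maximal penalty) when the pooled
age and mortality estimates disagree in sign — protective metabolites
that rise with age should not be rewarded for tracking age.

**MARS.** Forward pass: greedily add reflected hinge pairs, optionally
multiplied into an existing term (max degree 2), choosing among
quantile-spaced candidate knots (default 12–16 per variable, extreme
values trimmed so knots stay interior); candidates are scored by exact
residual-SSE reduction against an orthonormalized running basis. Backward
pass: greedy deletion while GCV = MSE/(1 − C/N)² decreases, with
C = number of coefficients + d × number of distinct (variable, knot)
pairs and d = 3 for interaction-capable models. Default
`max_terms = min(2√n, 40)`: the cap keeps the forward pass quadratic cost
bounded at the panel sizes this pipeline targets, and the pruned models on
the default study plateau well below it.

**Mortality score.** Elastic-net-penalized Cox (α = 0.5) over the pruned,
standardized metabolites plus *unpenalized* age, sex, BMI, ethnicity and
cohort indicators (penalty factor 0), so metabolite shrinkage is not
distorted by covariate scale. λ maximizes the k-fold cross-validated test
partial likelihood, restricted to path points that retain at least one
metabolite: the metabolite-free model is degenerate as a score
(zero-variance), so when CV marginally prefers it — which happens on weak
survival signal — the best supported λ is used and a warning logged. The
score is the metabolite-only linear predictor, affinely rescaled to the
training-CA mean/SD so it reads in years (hazard-increasing = older).

**Published scores** are user-supplied TSV weight tables with a declared
transform: `raw` (direct linear combination, already in years) or
`log-then-cohort-z` (per cohort, z-score log concentrations, weighted
sum, rescale against the dataset's CA). A declared biomarker count (14
for the lifespan-score format) is validated; non-positive values under
log are an error pointing at the pseudocount config. The numeric weights
of published scores belong to their publications and are not shipped;
tests use synthetic tables.

## Evaluation

Subjects, not samples, are the cross-validation unit: all visits of a
subject share a fold, so repeat visits cannot leak between training and
test; LOCO folds are cohorts. Fold hygiene is asserted programmatically
on every run. Reported out-of-fold r under 7-fold CV is the quantity
comparable to the generator's √R² target; LOCO r is systematically lower
because each held-out cohort's age range forces extrapolation — that gap
is expected behaviour, not a defect, and mirrors how such clocks degrade
across cohorts.

δ-age compares consecutive-visit changes in predicted age with the years
elapsed, grouped by integer-rounded gap. Association estimators
deduplicate to one sample per subject (earliest visit — a deterministic
generic stand-in for per-cohort visit choices), z-score the clock (and a
continuous biomarker) so estimates read per SD, adjust for CA, sex and
ethnicity, and for incident events fit per-cohort Cox models on the score
in years, pooled by fixed-effect meta-analysis and reported as HR per
year of metabolomic age. Because CA is always adjusted, estimates read as
effects of age acceleration. A BMI-adjusted variant wraps any estimator.
A clock numerically collinear with CA (|r| > 0.999) is rejected as
unidentifiable.

## Numerical choices and degenerate inputs

- Coordinate descent: covariance updates, warm starts along the path,
  convergence at max coefficient change < 1e−10 (1e−12/1e−14 where tests
  compare against closed forms).
- Meta-analysis with k = 1 returns the input estimate unchanged; Q = 0
  defines I² = 0.
- Constant covariates within a stratum (e.g. sex in a single-sex cohort)
  are dropped from that stratum's design with a log entry.
- Constant response in MARS returns the intercept-only model; hinge
  factors evaluate to exactly 0 at their knot.
- Score scaling errors on zero source SD rather than emitting a constant
  "age".

## Pipeline problem sizes

The default end-to-end configuration (5 × 400 subjects, 40 metabolites,
7-fold + LOCO validation of three CA clocks plus the mortality score)
completes in about two minutes on one CPU; the orchestration tests use a
reduced configuration (120 subjects per cohort, 12 metabolites) whose
artifacts and checksums exercise the same contracts. These sizes are the
package's chosen defaults for a reproducible desk-scale study; all are
config-exposed.

## What passing tests do and do not show

The synthetic study shows that each stage recovers what was planted under
the generator's assumptions: linear(+quadratic) age effects, Gaussian
block-equicorrelated noise, multiplicative batch structure,
proportional-hazards mortality, point-mass contamination. Real NMR data
violate several of these (skewed concentrations, non-block covariance,
batch effects that are not purely multiplicative, informative censoring,
cohort-specific assay drift), so green tests certify the statistical
machinery and its bookkeeping — not that a clock trained on real cohorts
will reach any particular accuracy. Accuracy figures published for
clocks trained on restricted cohort data are properties of those data
and are not reproduction targets for this package.

## Known limitations

- Fixed-effect pooling only; heterogeneity is reported, not modelled.
- The MARS forward pass scores hinge pairs jointly but adds both columns
  of a pair even when one is later pruned; minspan-style knot spacing is
  approximated by quantile candidates rather than Friedman's run-length
  rule.
- Calibration assumes a purely multiplicative cohort effect; additive
  shifts would need a different estimator.
- k-NN imputation is O(n²) in samples; adequate for panel-sized studies,
  not for biobank-scale matrices.
- The CLI's stage commands share one artifact directory and re-read
  intermediate CSVs; there is no workflow-engine integration.
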