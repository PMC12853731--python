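# Methods

This note documents the models, defaults and numerical choices behind
`riskaudit`, and what the synthetic studies do and do not establish about
real registry data.

## Synthetic cohort generator

The generator emulates a national surgical-registry total-joint-arthroplasty
extract. Its defaults are the published summary statistics of such a
cohort and are treated as fixed study conditions, not tuning knobs.

**Marginals.** Twenty predictors: continuous features are normal draws with
the published mean/SD, clipped to the physiologic range (the bounds sit
several SD out, so moments are essentially unchanged; clipping age at 90
reproduces the registry's "90+" top-coded mass). Binary features are
Bernoulli at the published prevalence; ASA class and diabetes severity are
multinomial with published (or, for the diabetes severity split, a chosen
11.5%/4.9% non-insulin/insulin) level probabilities. Features are drawn
independently — the registry publishes marginals only, so any dependence
structure would be invented; the consequence is that multicollinearity
diagnostics (VIF) sit near 1 on synthetic data, unlike real registries
where correlated features and their interaction products push VIFs into
the tens or hundreds.

**Outcome.** A logistic model on the complete (pre-degradation) values:
main effects in log-odds per SD (continuous) or per level (binary/ordinal),
interactions in log-odds per SD-product `γ · z(a) · z(b)` with `z`
standardized by the generating marginal. Default main-effect signs follow
the published partial-dependence directions; magnitudes are chosen so ASA
class, hematocrit, age and operative time dominate, mirroring the
published importance ranking. The default planted interactions are the
five pairs that dominate the published influence decomposition
(age×ASA 0.50, operative-time×ASA 0.35, operative-time×age 0.30,
hematocrit×ASA −0.30, hematocrit×diabetes −0.30). The intercept is
calibrated by monotone root search (Brent) on a 100,000-row probe so the
expected prevalence equals the 6.7% target; outcomes are then Bernoulli
draws.

**Degradation.** Missingness is injected completely at random at the
published per-feature rates, encoded as sentinel codes (−99/−1) for
continuous registry variables and empty cells otherwise; the outcome never
depends on the degradation. Implausible values (default 0.5% of rows,
spread over the five range-filtered variables, strictly outside the
plausible range on alternating sides) exercise the filters. Raw files
write ages ≥ 90 as the literal token `90+` to exercise the recoding path.

**Monotone study generator.** The concordance-recovery studies use a
variant with *no* interactions and every main effect at ≥ 0.3 log-odds per
SD in the feature's expected direction; per-level coefficients for
discrete features are scaled by the level distribution's SD (capped at 2.0
per level) so every effect is equally detectable on the z scale. This is a
detectability convention, chosen once: without it, a 0.1%-prevalence
comorbidity with a 0.3-per-level effect is unlearnable at any realistic n
and the study would measure sample size rather than concordance.

## Preprocessing

* **Boundary semantics.** "Less than 10 or greater than 80" is read as
  strict inequality: values exactly at a bound are retained. Missing
  values never trigger removal, and rows are never removed for
  missingness. Filters run in spec order; each report counts rows first
  removed by that rule, so counts sum to the total removed. Filters are
  idempotent.
* **Median imputation** is fitted on training rows only (the source
  procedure is silent on leakage; this is the conservative choice).
  Categorical missingness becomes an explicit category (level
  `max(levels)+1`, i.e. 2 for binaries), which matters chiefly for the two
  60.7%-missing categoricals (elective status, weight loss).
* **Chained equations** run 10 sweeps in descending-missing-rate order
  from a median/mode start: linear regression with a Gaussian residual
  draw for continuous targets, logistic with a Bernoulli draw for binary,
  linear-then-round for ordinal. A singular conditional regression falls
  back to the median and is recorded in provenance. m seeded datasets are
  returned; the pipeline's default path uses median imputation (matching
  the audited study's final choice).
* **Stratified split** allocates a round-half-up share of each outcome
  class to training. At n = 50,000 and 6.7% prevalence the train/test
  outcome-rate gap is below 0.01 percentage points.

## Models

The ensemble learner is an off-the-shelf scikit-learn backend (random
forest default, gradient boosting optional) behind a `PredictiveModel`
contract: deterministic `predict_risk`, probabilities clipped to
[1e−6, 1−1e−6] before any log-odds transform. Interaction features are
`z(a)·z(b)` products standardized by training-set statistics stored in an
`InteractionSpec`; the default 24-pair list combines six clinically named
pairs, the five dominant published pairs and declared fillers (the
published supplementary list is not available; the set is configurable).
Grid-search tuning takes each range's endpoints and midpoint (3⁴ = 81
combinations for the published ranges), scores by mean 5-fold CV AUC on an
outcome-rate-preserving subsample (default 12.1% of training rows, capped
at 50,000), and refits the winner on all training rows. AUC is the
Mann–Whitney statistic with ties counted one-half; its CI is a percentile
bootstrap. Fitted estimators are kept in memory with a JSON-style metadata
sidecar persisted by the pipeline; no binary model artifact is written.

## Permutation importance and influence decomposition

"Repetition" means independent within-column shuffles of the fixed
evaluation set (no row resampling), default 30. Relative influence
normalizes positive mean AUC drops to 1; negative drops are kept in the
records but carry zero influence (the source does not define the
normalization; this choice is documented rather than inferred). Threshold
selection keeps features with relative influence strictly above the
threshold (default 5%) and reports five shares: interaction/main/selected
as percentages of total influence mass and interaction/main within the
selected mass. VIF is 1/(1−R²) from an OLS of each design column on the
others plus intercept (statsmodels); perfect collinearity is reported as
+inf, never raised.

## Partial dependence

Grids span the 5th–95th percentile of the background (per feature, not
globally), default 50 points; binary and ordinal features are evaluated at
their levels only. When the central 90% collapses to a point — which
happens for heavily imputed features whose median dominates — the grid
falls back to the background min–max rather than failing, so a direction
is still defined for every predictor. On the log-odds scale each clamped
prediction is logit-transformed *before* averaging (mean per-patient
log-odds), not the logit of the mean probability; both scales are exposed
because published figures use both conventions. 2D surfaces subsample the
background without replacement (seeded, default 5,000 rows; `None` uses
every row, and a request larger than the background uses every row).
Bootstrap bands are percentile intervals over B = 50 resamples of
m = 2,000 rows at 95%. Trend direction is the least-squares slope sign
with a dead zone: total rise below 1e−4 on the curve's scale counts as
flat (sign 0).

## Shapley attribution

Model-agnostic Monte-Carlo permutation sampling (default 200 orderings,
1,000-row seeded background) rather than a tree-path-specific algorithm,
so the audit stays backend-independent. Completion is marginal
(interventional): unrevealed features come from the paired background row,
ignoring dependence — deliberately matching the behaviour of
marginal-distribution SHAP estimators that the concordance statistic is
meant to audit. Attributions are in log-odds; the base value is the mean
background log-odds. After averaging, the Monte-Carlo residual is
redistributed proportionally to |φ| (equally if all φ are zero) so
efficiency holds exactly per patient; symmetry and dummy hold within
Monte-Carlo error, and the estimator's spread shrinks as 1/√(orderings).

## Concordance

Spearman ρ uses mid-rank ties and the two-tailed t approximation on n−2
degrees of freedom (scipy). A flat PDP (sign 0) counts as disagreement and
is flagged; a constant feature or attribution column yields ρ = NaN and
counts as disagreement rather than aborting the report. Weights are the
permutation relative influences of the baseline model (negative-drop
features weigh 0); weighted agreement is invariant to weight rescaling and
reduces to the unweighted proportion under equal weights. Ordinal
features enter the correlation with their declared level coding.

## Orchestration

`CohortAudit.fit()` runs recode → filter → split → impute → baseline fit →
interaction fit → importance/threshold → PDP directions → Shapley on
sampled test patients → concordance → archetypes → VIF, deriving every
stage seed from the master seed through `SeedSequence([master, stage])`,
so runs are exactly repeatable and stages re-runnable in isolation.
Archetypes use the nearest-rank percentile definition (10th/50th/90th of
uncalibrated predicted risk) with a lowest-row-id tie-break.

## Problem sizes

Recovery studies run at n = 50,000 patients over 10 generator seeds with
fixed forest hyperparameters (50–60 trees, depth 10), permutation
importance at 5 repeats on a 5,000-row evaluation subsample, PDP
directions from a 1,000-row background, and Shapley over 20 orderings for
400 sampled patients; the end-to-end demonstration audit uses n = 20,000
with 50 orderings over 500 patients. These sizes give stable sign and
threshold recovery (binomial noise on a 6.7% outcome is the limiting
factor) while keeping a full run in tens of seconds on one core; the
audit of a real cohort would raise the repetition counts to the defaults
(30 repeats, 200 orderings, 5,000 patients).

## What passing tests show — and don't

Planted-structure recovery on this generator shows the audit machinery is
correct and adequately powered under independence, MCAR missingness and a
correctly specified logistic ground truth. Real registry data violate all
three: features are correlated (so marginal-completion Shapley can weight
implausible feature combinations), missingness is informative, and the
true risk surface is not logistic. The directional-concordance statistic
is exactly the tool for detecting when those violations make the
population and individual views diverge — but a passing synthetic suite
does not certify any particular registry model. Other known limitations:
no ICE curves or accumulated local effects, no conditional/grouped
permutation importance, no interaction Shapley values, no probability
calibration, and no missing-not-at-random modelling.
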