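# Methods

## Model and estimation

The package estimates recursive composite latent-variable path models.  A
model is a set of constructs, each with an ordered indicator block and a
measurement mode, plus a directed acyclic set of structural paths.  The
packaged default is the five-construct subhealth model: four reflective
blocks — routine blood test (HGB, MCHC, RBC, HCT), lipid metabolism (TC,
TG, LDL), liver function (AKP, ALT, AST, GGT), SV characteristics (SV-L,
SV-a, SV-b) — one formative block (obesity: BMI, WHR), and five paths
(blood → SV, blood → lipid, obesity → SV, lipid → obesity, liver → SV).
All five hypothesised paths ship in the default spec, including the
blood → SV link that the structural test does not support: rejecting it
is part of the analysis, not of the model declaration.

Estimation follows the classical iterative PLS-PM scheme.  Indicators are
standardized (mean 0, unit variance, n−1 denominator).  Outer weights are
initialised to +1 within each block and scaled so every composite has
unit variance.  Each iteration forms inner proxies under the selected
scheme — *path* (default): predecessors weighted by the regression
coefficients of the construct's score on the predecessor scores,
successors by correlations; *centroid*: correlation signs; *factorial*:
correlations — then updates outer weights (Mode A: covariance of the
indicators with the proxy; Mode B: regression of the proxy on the block)
and rescales.  Convergence is declared when the maximum absolute weight
change drops below `tol` (default 1e−7, `max_iter` 300; non-convergence
is flagged, not raised).  Loadings are indicator–score correlations; path
coefficients are per-equation OLS of each endogenous score on its
predecessors' scores.  A construct with no structural neighbours keeps
its initial equal-weight composite, so measurement-only specs remain
estimable.

Composite scores are sign-indeterminate.  After convergence each
construct is oriented so the sum of its loadings is positive; weights,
scores and path coefficients are flipped consistently.  The orientation
is idempotent.

Defaults that the reference software leaves unstated — path weighting
scheme, unit initialisation, the 1e−7 stop criterion, and the n−1
standardization denominator — are declared choices of this package, not
inferences.

## Measurement-model battery

* Cronbach's α: standardized-item form K·r̄/(1 + (K−1)·r̄) by default
  (the engine standardizes anyway); the covariance form is available via
  `standardized=False`.  Undefined (NaN, printed "–") for single-indicator
  and formative blocks.
* AVE = mean squared loading; CR = (Σλ)² / ((Σλ)² + Σ(1−λ²)).
* VIF per formative indicator: 1/(1−R²) against the rest of the block,
  from the inverse correlation matrix; a singular block yields an
  infinite-VIF marker.  Two-indicator blocks always give equal VIFs.
* HTMT: mean absolute between-block correlation over the geometric mean
  of the two mean absolute within-block off-diagonal correlations —
  absolute correlations throughout, undefined against single-indicator
  blocks.
* Decision rules: α ≥ 0.70, outer weight > 0.20, AVE ≥ 0.50, CR ≥ 0.70,
  VIF < 5, HTMT < 0.85, |score correlation| < 0.70 — all strict where the
  rule states an open bound (HTMT exactly 0.85 fails).

## Bootstrap inference

Subjects are resampled with replacement B times (default 5000); each
resample is re-standardized and re-estimated.  A resample that leaves an
indicator constant is discarded and redrawn (counted in the result).
Before aggregation every resample's constructs are re-oriented at the
construct level to maximise agreement with the original loadings —
without this, sign indeterminacy inflates the bootstrap SD.  For each
path t = |β̂|/sd(β*), two-sided p from Student t with B−1 degrees of
freedom (indistinguishable from normal at B = 5000), Supported iff
p < α (strict), default α = 0.05.

## Synthetic population

The generator implements a *composite* population: the data-generating
process matches the composite model the estimator assumes, so recovery
experiments isolate implementation error from factor-model bias.

* Construct scores: exogenous constructs jointly normal with the
  configured correlations (default: blood–liver 0.468); endogenous scores
  follow the structural equations with normal disturbances scaled for
  unit variance.  Inadmissible configurations (explained variance ≥ 1,
  |λ| > 1, marginals not summing to 1) fail at construction.
* Reflective blocks: x = λη + u with residual covariance
  D^{1/2} M D^{1/2}, D = diag(1−λ²), M the singular equicorrelation
  matrix at −1/(K−1).  The singularity makes η an exact linear function
  of the block while corr(x_k, η) = λ_k exactly.  Consequence: within a
  block the residuals are negatively correlated, so the within-block
  indicator correlation is λ_kλ_l − sqrt(d_k d_l)/(K−1), not the factor
  value λ_kλ_l; for K = 2 the residual correlation is −1.  Exactness and
  factor-form within-block correlations are mutually incompatible unless
  a loading is 1 — when a block contains a unit loading (HGB) or a single
  indicator, or when the construct is unrecoverable (all-zero loadings),
  independent residuals are used instead.
* Formative block: indicators equicorrelated (default 0.43) and the
  construct defined as the standardized weighted composite (weights
  0.71/0.46).  The implied indicator–construct correlations, ≈(0.91,
  0.77), and the two-indicator VIF ≈ 1.23 then match the published
  assessment table.
* Grades: independent latent normals thresholded at the cumulative grade
  marginals (defaults are the subhealthy-group proportions, e.g. 68.1%
  L1).  Grades are independent of the construct scores — the generator
  emulates marginal distributions, not a grade–construct coupling.
* Symptoms: Bernoulli positives per symptom at the configured prevalence;
  half of the positives (floor) are escalated to severity 2.  This 50%
  rule is an arbitrary convention; every analysis in the package only
  uses severity ≥ 1.  The four published prevalences (limb soreness
  37.6%, fatigue 31.6%, shoulder and neck pain 30.5%, dry eyes 29.2%) are
  defaults; the remaining catalogue entries carry one-time realistic
  prevalences (6–25%) chosen to cover all 11 symptom clusters.
* Determinism: `numpy.random.default_rng` (PCG64); a cohort is
  bit-reproducible from (population, n, seed).

`implied_covariance` computes the exact model-implied indicator
covariance (within-block λλ'+S; between blocks λ_j Φ_jk λ_k' with Φ from
the reduced-form recursion) and serves as the sampler's analytic oracle.

What the generator does **not** emulate: demographic structure (age, sex,
education), non-normal indicator marginals, grade–construct dependence,
symptom co-occurrence structure, and a healthy comparison group.  Tests
passing on this population therefore validate the estimation machinery
and its calibration, not distributional robustness on real cohorts.

## SV quantification

Colour: sRGB decompanding → XYZ → CIELAB via scikit-image; reference
white D65 by default (`white="D50"` available — the instrument's D50 lamp
concerns capture, not encoding, so D65 sRGB is the sensible default).
Region colour is the per-pixel Lab mean over a mask.  Greys map to
a = b ≈ 0 (within 0.005, the rounding of the standard sRGB matrix).

Morphology: pixel measurements convert to mm at 1/177.171 mm/px.  Trunk
grade compares the mean of the two trunk lengths with 3/5 of the
caruncle-to-tip distance; "approximately 3/5" is a ±0.02 band on the
ratio (configurable).  Width: W1 < 3 mm, W2 = [3, 4] mm (closed
interval), W3 > 4 mm.  Tortuosity is never computed from images: it is
expert-coded, two primary raters with a third gold-standard rater
consulted only on disagreement.

## Cohort statistics

Imputation: single imputation per column, mean if Shapiro–Wilk does not
reject normality at 0.05, median otherwise.  Group comparison: pooled
two-sample t test (Welch by flag), with a summary-statistic entry point
so printed mean ± SD tables are directly checkable.  Count tables:
Pearson chi-square, Yates-corrected for 2×2.  Ordinal grade tables: the
tie-corrected Kruskal–Wallis H computed directly from the counts via
mid-ranks, with correction 1 − Σ(t³−t)/(N³−N) and a χ²(groups−1)
reference; for two groups this equals the squared standardized
Mann–Whitney statistic and reproduces the published grade-table
statistics (25.114, 37.304, 0.611) exactly.  Symptom prevalence counts a
subject once per symptom at severity ≥ 1 (the threshold is recorded in
the output metadata); ties rank alphabetically.  The cluster × grade
table sums positive symptom occurrences per cluster over subjects holding
each grade level; unmapped symptoms go to an explicit "unmapped" bucket.

## Problem sizes used in validation

Engine-vs-oracle agreement is checked at n = 200 against an independent
loop-based reference implementation (tolerance 1e−6); sampler covariance
against the analytic oracle at n = 10⁵ (max deviation < 0.02); path
recovery at the study size n = 627 over 100 replicate cohorts (|bias| <
0.05); bootstrap type-I error over 200 replicate null cohorts of
n = 1000 with B = 500 (5% ± 4 points).  These sizes are the package's
validation conditions and are reused by `scripts/acceptance.py`.

## Known limitations

* No consistent-PLS disattenuation, higher-order constructs, moderation,
  or multi-group analysis; no BCa/percentile bootstrap intervals.
* The assessment battery reports Fornell–Larcker-style diagnostics only
  through AVE; cross-loading tables and Q² are out of scope.
* Automatic SV segmentation is out of scope; the region mask is an
  input.
* The exact colour transform of the original acquisition software is
  unpublished; colour features rest on the standard sRGB/CIELAB
  transform.
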