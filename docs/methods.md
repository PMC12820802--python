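# Methods notes

## Data model and conventions

A feature table holds one recording per row: covariates (`subject_id`,
`study`, `age` in years, `sex` coded F=0/M=1, `condition` coded
eyes-closed=0/eyes-open=1) and one column per parcel of relative spectral
power on its native (0, 1) scale — no logit or other transform is applied
before harmonization. Bands are processed as independent tables. Tables are
tab-delimited UTF-8 text so fixtures diff cleanly. Study (not site) is the
batch variable throughout. When one recording per subject is needed
(site-effect and age analyses), the preferred condition is kept for
dual-condition subjects; harmonization itself always runs on the full
recording set.

## ComBat and the mean models

Standardization fits, per parcel, batch intercepts jointly with covariates
by least squares under the usual identification constraint: the grand
intercept `α_v` is the sample-size-weighted mean of the batch intercepts.
The pooled residual variance `σ_v²` divides by N (not N−1); this matters in
small toys and is stated here because conventions differ. Batch effects are
then estimated from standardized data: `γ̂_iv` as within-study means and
`δ̂_iv²` as within-study (n−1) variances — a small-n consequence is that a
single-study table is *not* bit-identical after harmonization: residuals
shrink by exactly `sqrt((N−1)/N)`, which the tests assert sharply.

Empirical Bayes hyperparameters come from across-parcel moments per study:
`γ̄_i = mean(γ̂_iv)`, `τ̄_i² = var(γ̂_iv)`, and inverse-gamma
`λ̂_i = (m² + 2s²)/s²`, `θ̂_i = (m³ + m s²)/s²` from the mean and variance of
`δ̂_iv²`. The conditional posterior means are iterated to a fixed point
(tolerance 1e-4 on the iterates, max 1,000 iterations; non-convergence is an
error). Degenerate cases: zero across-parcel spread falls back to no
shrinkage with a warning; zero within-study variance is floored at 1e-12.
Shrinkage is parametric only, applied per study across parcels.

The GAM mean model is a P-spline: cubic B-splines, 10 basis functions,
interior knots at age quantiles, second-divided-difference penalty evaluated
at the Greville abscissae — that choice makes the penalty null space exactly
the linear-in-age functions, so penalty → ∞ recovers the least-squares line
(a property the tests check). Because B-splines form a partition of unity,
the centered basis has a null direction along the constant coefficient
vector; the fit absorbs the sum-to-zero identifiability constraint by
reparametrizing into its orthogonal complement. The penalty weight is chosen
by GCV on the parcel-mean response and held fixed across parcels (per-parcel
selection is available behind a flag but off by default — with 68 well-scaled
parcels a shared smoothness is both faster and more stable). Ages outside
the training range are clamped, never extrapolated. Sex and condition stay
linear; no interaction or tensor smooths.

## CovBat

Stage 1 is GAM-ComBat. Residuals (stage-1 output minus the fitted mean
surface) are centered per parcel and decomposed by SVD; the covariance
normalization is by N, and each eigenvector's largest-magnitude loading is
made positive so signs are deterministic. `K` is the smallest number of
leading components whose cumulative explained variance reaches the
threshold (ties resolve to the smaller K; threshold 0 means no adjustment
and returns the stage-1 output exactly). Scores 1..K get an intercept-only
ComBat location/scale adjustment by study — no covariates appear at the
score stage, matching the score model `ξ = μ_ik + ρ_ik ε`. Empirical Bayes
at the score stage is on by default and can be disabled; with a single
adjusted component shrinkage is skipped (across-feature moments need ≥ 2
features). PCA is fit on pooled residuals (a single eigenbasis), not per
study.

## RELIEF-style decomposition

The published description specifies the model and a two-stage regression
but not the iterative estimator; this implementation adopts a documented,
testable scheme: alternating truncated SVDs for the shared term `R` (full
matrix) and each study-latent block `I_m`, with rank set by a
Marchenko–Pastur singular-value edge `σ̂(√n + √p)` times a 5% finite-size
buffer. The noise scale `σ̂` comes from the median singular value against
the median of the MP law — robust to a few large signal components. Variance
scaling is one scalar per study (`δ̂_m` = the square root of the study's mean
residual variance relative to the pooled value); a per-feature mode exists
behind a flag. By default no covariates enter the model: nonlinear and
unknown covariate structure rides in `R` (or, below the detection edge, in
the retained noise `E`) and survives harmonization, which is why the default
reassembly keeps `A + R + E` and discards `Γ` and `I`.

Two deliberate exposures of ambiguity in the printed model: the final
equation multiplies the shared blocks by the study-specific `δ̂_m`, which
re-introduces mild scale heterogeneity through `R`; this as-printed behavior
is the default, and `pooled_shared_scale=True` applies the common scale
instead (that mode is an exact fixed point of re-harmonization, which the
tests exploit). Second, the per-study/per-parcel multiplicative effects the
ComBat-style generator produces violate RELIEF's block-scale noise model;
under such anisotropy the MP rule can flag spurious study-latent components
and delete real variance. The location/scale recovery tests therefore use
block-level multiplicative effects, and this mismatch is a documented
limitation of the method, not of the implementation.

## Evaluation battery

Residualization is a pooled per-parcel OLS on intercept + sex + condition +
age + age² + age³ (covariates with a single observed level are dropped).
Levene's statistic uses the classic mean-centered form by default
(Brown–Forsythe median-centering behind a flag). logVR uses natural logs,
(n−1) variance denominators, and a pooled variance computed on the
concatenated residual vector; the mean of *absolute* log ratios is taken
over studies, so its null expectation is the sampling floor
`≈ 0.8·sqrt(2/(n_i−1))` — about 0.11 at 100 recordings per study — not zero.
Out-of-sample R² in the cross-validated comparison is computed about the
test-fold mean and may be negative (kept; informative about overfitting);
folds are stratified by study and identical for both tables being compared.
ICC(3,k) uses the consistency form `(MS_targets − MS_error)/MS_targets`
with parcels as targets and studies as raters (the absolute-agreement
variant is available by flag; the two differ whenever rater means differ,
and "(3,k)" conventionally denotes consistency). Lin's CCC uses 1/n moment
conventions. Age-binned site maps use the half-open interval [lo, hi) and
require ≥ 30 qualifying recordings per study by default.

## Synthetic generator

The generator draws from exactly the generative structure the
location/scale harmonizers assume — `y = α_v + f_v(age) + β_sex·sex +
β_cond·cond + γ_iv + δ_iv ε`, Gaussian noise — so empirical-Bayes parameter
recovery is a well-posed test; a heavy-tailed mode (t₃ effects and noise)
exists for robustness experiments. Sixteen fixed study profiles emulate a
heterogeneous consortium: one 600-subject lifespan study, several narrow
young-adult studies, an adolescent study, and six studies recording both
conditions (enabling paired condition contrasts). Ages are truncated-normal
for lifespan studies and uniform for narrow ones. Defaults: additive study
effects with overall SD 0.05 on the power scale (split evenly between
between-study mean shifts and within-study across-parcel spread);
multiplicative effects inverse-gamma with shape 21 and mean 1.5; noise SD
0.018 per parcel; a cubic age surface declining over the lifespan whose
amplitude puts the strongest parcel's raw cubic-fit R² near one half; a
−0.02 eyes-open effect in the four occipital ROIs sized to give paired
t-statistics in the low teens at ~330 dual-condition subjects; a +0.008 sex
effect. Values are clipped into (0, 1) with margin 1e-4 and the clip count
recorded (< 1% under defaults, asserted). Randomness splits one root seed
into per-study streams (`SeedSequence.spawn`, profile order) with a fixed
draw order — noise, additive, multiplicative — so zeroing the site effects
under the same seed leaves the noise field intact; that is how ground-truth
tables are paired with affected ones.

Two scale conventions matter when comparing harmonized data to ground
truth. First, ComBat-family methods equalize residual variance at the
*pooled* scale: if multiplicative effects average 1.5, harmonized noise
variance is ~1.5× the δ=1 ground truth's and the cubic-fit R² is structurally
depressed by that factor. The nonlinearity-retention experiment therefore
draws multiplicative effects with mean 1.0 (fluctuation around the common
scale), the only configuration in which "harmonized R² equals ground-truth
R²" is a well-posed target; the site-effect-removal experiment keeps mean
1.5. Second, the null-calibration experiment gives all 16 studies identical
demographics: when covariates are confounded with study (disjoint age
ranges, study-specific condition policies), pooled residualization absorbs
between-study degrees of freedom and deflates ANOVA/Levene below nominal —
a property of the residualize-then-test procedure itself. Under the
exchangeable null both tests sit at ~0.050.

## What the synthetic results do and do not show

Passing tests show the estimators are correct implementations of their
models and behave as theory predicts under that generative structure. Real
MEG power tables differ in ways the generator deliberately omits: residual
non-Gaussianity, spatially correlated noise (beyond the optional
equicorrelation used in the CovBat tests), imperfect parcel registration,
and mean-model misspecification. That last point is why the real-data
finding that polynomial ComBat degrades age fits does not reproduce here:
with an exactly cubic generating surface, the cubic mean model is
well-specified and performs on par with the GAM. The synthetic benchmark
ranks methods on effect *removal* faithfully but cannot adjudicate
robustness to misspecification it does not generate.

## Problem sizes

Defaults were chosen so the whole cycle runs comfortably on a laptop: the
consortium simulation is ~2,400 recordings × 68 parcels; null calibration
uses 20–30 replicates of 16 × 100; the cross-validated comparison uses 800
recordings × 68 parcels × 10 folds × 50 repeats. The full test suite runs
in well under a minute; the acceptance script in a few seconds.
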