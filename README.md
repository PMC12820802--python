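# megharm

Multi-study harmonization of MEG relative spectral power, with the full
diagnostic battery needed to judge whether harmonization worked.

## The problem

Pooling resting-state MEG recordings across studies and platforms introduces
*study effects*: additive shifts in the mean of each feature and
multiplicative inflation of its variance, entangled with real covariate
effects (age, sex, eyes-open vs eyes-closed recording condition) whose
distributions differ sharply between studies. The features here are tables of
relative spectral power — band-limited power divided by total power — in the
68 Desikan–Killiany cortical parcels, one table per canonical band (delta,
theta, alpha, beta, gamma). Age effects on spectral power are strongly
nonlinear (often cubic), so a harmonizer must remove study structure without
flattening those curves.

## Methods implemented

All four harmonizers operate on a recordings × parcels matrix `Y` with
study labels and covariates:

- **ComBat** — location/scale model per parcel `v`, study `i`, recording `j`:
  `y_ijv = α_v + x_ij'β_v + γ_iv + δ_iv ε_ijv`. After removing the fitted
  mean surface and scaling by the pooled residual SD, study effects
  `γ_iv` (additive) and `δ_iv²` (multiplicative) are estimated and shrunk
  toward across-parcel priors — normal for `γ`, inverse-gamma for `δ²` — by
  the standard empirical-Bayes conditional-posterior iteration. The linear
  mean model uses age, age², age³, sex, and condition.
- **GAM-ComBat** — identical machinery with the polynomial age terms replaced
  by a penalized cubic B-spline (P-spline, 10 basis functions, knots at age
  quantiles, GCV-selected penalty), fitted jointly with study intercepts
  under the ComBat identification constraint.
- **GAM-CovBat** — GAM-ComBat followed by a second pass on the *covariance*:
  PCA of the stage-1 residuals, ComBat-style location/scale adjustment of the
  leading principal-component scores per study (the smallest set explaining
  ≥ `pct_var` of residual variance, configurable at 90/95/100%), reprojection,
  and add-back of the mean surface.
- **RELIEF-style** — structured matrix decomposition
  `Y = A + βX' + Γ + R + I + δE` into intercepts, optional covariate term,
  study means, shared low-rank variation, study-specific latent low-rank
  blocks, and scaled noise, estimated by alternating truncated SVDs with a
  Marchenko–Pastur singular-value edge rule. Harmonization keeps `A`, `βX'`,
  `R` and the homogenized noise, discarding the study-specific terms.

The evaluation battery mirrors how such methods are judged: per-parcel ANOVA
and Levene tests on residualized data, the study partial R²
(`(SSE_reduced − SSE_full)/SSE_reduced`), the mean absolute log variance
ratio, paired/independent eyes-open vs eyes-closed t-tests in occipital ROIs,
quadratic/cubic age-fit R², repeated stratified 10-fold cross-validated
ΔR² with paired t-tests and Benjamini–Hochberg FDR across parcels, and
age-binned between-study map concordance (median pairwise Pearson r, median
Lin CCC, ICC(3,k), median coefficient of variation).

Because the real 16-study consortium data cannot ship with a package, a
synthetic generator (`megharm.synthetic`) produces tables from the same
generative structure with known ground truth: 16 studies of unequal size,
study-specific age ranges and condition policies, parcel-wise cubic age
effects, additive study offsets drawn `Normal(γ_i, τ_i²)` and multiplicative
effects drawn inverse-gamma, so every stage is testable end to end.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data: `01` simulates the consortium, `02` harmonizes with every method,
`03`–`05` evaluate. Running `python analysis/03_site_effect_removal.py`
after `01` and `02` prints:

```
           mean_anova_F  mean_levene_W  median_partial_r2  median_log_vr
method
raw            393.9058         4.7698             0.8157         1.4570
combat           0.1549         0.4274             0.0011         0.0743
gamcombat        0.1812         0.4289             0.0014         0.0742
covbat90         0.1807         0.4281             0.0014         0.0752
covbat95         0.1809         0.4289             0.0014         0.0750
covbat100        0.1802         0.4301             0.0014         0.0753
relief           5.2326         3.4578             0.0588         0.2165
```

Read: the raw pooled table carries massive study structure (a median 82% of
residual variance per parcel is attributable to study; variance ratios far
from 1). Every ComBat-family method removes essentially all of it (partial
R² ≈ 0.001, |logVR| ≈ 0.07 — the sampling floor at these study sizes), while
the matrix-factorization method leaves an order of magnitude more residual
study structure, matching its weaker performance on this kind of data.
`analysis/05_map_concordance.py` shows the same story spatially: the median
between-study Pearson correlation of 20–30-year-old delta power maps rises
from 0.70 (raw) to 0.99 after GAM-ComBat, and the median parcel coefficient
of variation falls from 0.15 to 0.01.

A thin CLI wraps the same pipeline:
`megharm simulate|harmonize|evaluate|benchmark --help`.

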