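# Methods

## Problem setting

Point observations `z(x₁) … z(x_n)` of a soil contaminant (mg/kg) on a
survey grid are interpolated to a map by ordinary kriging (OK). OK is the
best linear unbiased predictor under second-order stationarity, but both the
variogram fit and the prediction weights are sensitive to heavy right skew:
a few hotspot samples dominate every squared difference in the empirical
semivariance and every residual in cross-validation. The package therefore
normalizes first (Box-Cox, Johnson, or normal score), kriges the transformed
values, and back-transforms for maps — and quantifies, per dataset, which
normalization interpolates most accurately.

## Transformations

**Box-Cox.** `y = (x^λ − 1)/λ` for `λ ≠ 0`, `y = ln x` at `λ = 0`; defined
for strictly positive data only. `λ` maximizes the normal profile
log-likelihood over `[−5, 5]`: a 0.01-resolution grid scan followed by
bounded scalar refinement in the bracketing interval; `|λ| < 10⁻³` snaps to
the exact log branch. The transform is computed as `expm1(λ·ln x)/λ`, which
is numerically stable down to arbitrarily small `λ`. For low-CV (nearly
normal) data the profile likelihood is flat and `λ̂` has large sampling
variance; this is a property of the estimator, not a defect of the search.

**Johnson system.** `Z = γ + δ·f((X − ξ)/λ)` with `f = ln` (SL, support
`X > ξ`), `f = ln(u/(1−u))` (SB, support `ξ < X < ξ + λ`) and `f = asinh`
(SU, unbounded). Fitting uses the Slifker–Shapiro percentile method: at a
selection point `z`, the four sample quantiles at normal fractions
`Φ(±z), Φ(±3z)` give spreads `m, n, p`, and the ratio `mn/p²` picks the
family (> 1 SU, < 1 SB, within ±0.1 of 1 SL) with closed-form parameter
estimates per family. Candidates are computed over the z-grid
{0.25, 0.524, 0.6, 0.75, 1.0} (0.524 is the classical default and wins
ties); invalid candidates (support violations, non-finite parameters) are
discarded and the candidate whose transformed data attain the highest
Lilliefors K-S p-value is kept. Moment-matching fits are not implemented.

**Normal score.** Values are ranked (average rank on ties, so ties share a
score) and ranks mapped through the Blom plotting position
`(r − 3/8)/(n + 1/4)` to standard-normal quantiles. Blom is the default of
the mainstream statistics packages and makes the score set a pure function
of `n` on untied data — at n = 60 the score skewness is exactly 0 and the
bias-corrected excess kurtosis is −0.2329. Van der Waerden and Hazen rules
are selectable. The inverse interpolates piecewise-linearly between stored
(score, value) nodes; scores beyond the stored extremes clamp to the
observed min/max rather than invent concentrations outside the data support.
No Gaussian-anamorphosis tail correction is applied to kriged scores before
back-transformation; this conservatively bounds mapped concentrations by the
observed range and is the main known bias of the normal-score maps.

## Diagnostics

Skewness and excess kurtosis use the bias-corrected (adjusted
Fisher–Pearson) sample formulas; CV = SD/mean with the n−1 SD. Constant
input reports 0 for both shape moments rather than NaN. Normality is tested
by the Lilliefors-corrected Kolmogorov–Smirnov test (mean and SD are
estimated from the data, so the plain K-S p-value would be inflated);
verdict "Normal" iff p ≥ 0.05.

## Variograms

The empirical semivariogram bins pairwise half squared differences into 12
uniform lags up to half the maximum pairwise distance by default (standard
practice when the survey itself does not dictate a lag structure); empty
bins are dropped. Theoretical models are spherical, exponential and
Gaussian, all parameterized by the *effective* range `A₀` — the spherical
model reaches its sill exactly there, the asymptotic families at ~95% via
the `−3h/A₀` forms — so fitted ranges are comparable across families. The
raw-parameter convention is not exposed; comparability across families was
judged more valuable.

Fitting is weighted least squares with weights `N_k / γ̂(h_k)²` (pair count
over model value squared, the convention of classic geostatistics packages;
plain `N_k` selectable), bounds `C₀ ≥ 0`, `C ≥ 0`, `A₀ ∈ (0, 3·max_lag]`,
and 8 multistart initializations seeded from data quantiles plus a
deterministic RNG — variogram WLS has genuine local minima and a single
start is not trustworthy. Reported per fit: weighted r², unweighted residual
SS (used for across-family model selection), and the nugget/sill proportion
`100·C₀/(C₀+C)`, classified <25% strong / 25–75% moderate / >75% weak
spatial dependence. Isotropy is assumed throughout.

## Kriging

The OK system is assembled in semivariance form (usable even for unbounded
models) over the `m` nearest samples, default `m = 16` — effectively global
for survey-scale n ≤ 64 — with the Lagrange row enforcing `Σλᵢ = 1`. The
kriging variance is `Σλᵢ γ(xᵢ, x₀) + μ`; round-off negatives above −10⁻¹⁰
clamp to zero, anything larger raises. Targets within 1 nm of a sample
return that sample's value with zero variance, bypassing the solve. Grids
are cell-center sampled, row-major from the north-west corner, and serialize
to ESRI ASCII (.asc) and CSV.

## Cross-validation

Leave-one-out: each sample is predicted from the remaining n−1 using the
variogram fitted once on the full transformed dataset (matching how GIS
cross-validation reuses the analyst's model; per-fold refitting would score
a different model per fold and is deliberately not the default). Metrics:
ME (bias), RMSE (accuracy), ASE (mean predicted SE), RMSSE (calibration,
ideal 1). Methods are scored on the transformed scale — each in its own
Gaussian space — because that is the scale on which the kriging model is
actually specified and its standard errors live; back-transformed-scale
scoring (ME/RMSE in mg/kg, ASE/RMSSE undefined and reported as NaN, label
suffixed `[raw scale]`) is available for apples-to-apples comparison.
Ranking is by RMSE with |ME| as tiebreak.

## Synthetic sites

The generator composes: (1) a zero-mean unit-variance Gaussian field with a
configurable variogram, drawn by dense Cholesky factorization of the
covariance `sill − γ(h)` (exact, deterministic per seed; capped at 3000
locations, ample for survey-scale work); (2) a lognormal marginal
`exp(μ + σ·Z)`; (3) multiplicative hotspot bumps
`1 + (A−1)·exp(−d²/2r²)`, which preserve positivity and mimic point-source
leakage; (4) systematic grid sampling on the near-square factorization of
`n` (6×10 for 60 samples on 1000×1500 m), with optional jitter clipped so
points stay distinct.

Defaults — exponential variogram (nugget 0.05, sill 1, effective range
150 m), `μ = −0.7`, `σ = 1.5`, two hotspots of amplitude 50 (radii 90 and
70 m) — were chosen so sampled marginals fall in the regime reported for
coking-plant PAH surveys: median sample skewness ≈ 5, median CV ≈ 2.9,
concentrations from ~0.01 to thousands of mg/kg, raw data failing the K-S
normality test in ≈ 95% of seeds. What the generator does **not** emulate:
anisotropic plumes, censoring at detection limits, multi-source mixture
populations, and measurement error beyond the nugget. Passing tests
therefore demonstrate correctness of the machinery and the expected method
ranking under lognormal-plus-hotspot conditions, not performance on any
particular real site.

## Study sizes used by the automated checks

The test suite and `scripts/acceptance.py` use 20 seeds × 60-sample sites
for the method comparison, 18×18 dense fields for variogram recovery, and
10×10 fields for LOOCV calibration — sizes at which the Monte-Carlo medians
are stable while a full run stays in the tens of seconds on one CPU.

## Known limitations

* Normal-score back-transformation clamps to the observed extremes, so
  mapped maxima cannot exceed the sampled maximum.
* Transformed-scale RMSE comparisons across methods compare different
  spaces; the Box-Cox space in particular is not variance-standardized, so
  its RMSE magnitudes are only comparable through the rank, not the value.
  Raw-scale scoring exists for direct mg/kg comparisons.
* No anisotropy, nested structures, censored-data likelihoods, or kriging
  variants beyond ordinary kriging.
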