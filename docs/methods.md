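# Methods

`growthmap` implements a three-stage longitudinal analysis: measurement-
invariance testing of a multi-item scale, a second-order latent growth
curve model (LGCM) of change in the measured trait, and a massively
univariate voxelwise stage predicting the latent slope from baseline
brain volumes. This note documents the statistical model, the estimation
machinery, the synthetic cohort the pipeline is exercised on, and the
numerical and design choices that were genuinely open.

## Model

All models are mean-and-covariance-structure SEMs in the all-y form

    y   = τ + Λη + ε,   ε ~ N(0, Θ)
    η   = α + Bη + ζ,   ζ ~ N(0, Ψ)

with implied moments μ = τ + Λ(I−B)⁻¹α and
Σ = Λ(I−B)⁻¹Ψ(I−B)⁻ᵀΛᵀ + Θ. Every matrix cell is an affine expression in
named free parameters, which uniformly encodes fixed values, equality
constraints (shared labels) and the effects-coding identification
(loadings per factor average 1, intercepts sum to 0, each enforced by
eliminating one cell). Effects coding leaves all latent means and
variances free, which is what makes the invariance ladder and the
second-order growth model well-defined on the same metric.

**Measurement ladder.** One latent trait factor per occasion, 12 Likert
items treated as continuous. Configural: occasion-specific loadings and
intercepts (effects-coded per occasion). Weak: loadings share labels
across occasions. Strong: intercepts too. Partial strong: selected items
get free intercept deviations at occasions 2..T (2 df per item at 3
occasions). Item-specific residual covariances across occasions are free
by default (standard longitudinal practice; configurable off). The df
arithmetic is closed-form: each step constrains (n_items − 1) ×
(n_occasions − 1) parameters, hence 22 per step at 12 items / 3 occasions.

**Growth stage.** Intercept and slope factors load on the occasion
factors; first-order latent intercepts are fixed at 0 so occasion means
flow through the growth factors. Default slope basis is [0, 0.5, 1] — the
three occasions roughly equally spaced on a 0–1 study-window scale; a
latent-basis variant [0, free, 1] is available and nests the linear model
(1 df). Time-invariant covariates enter as observed exogenous variables
with an identity measurement block and free means/variances/covariances,
regressing on both growth factors regardless of significance; categorical
covariates are dummy-coded against a declared reference. The voxel
predictor is the same mechanism with a reserved variable name.

**Voxelwise stage.** Per in-mask voxel: voxel values standardized across
participants (β comparability), inserted into the predictor slot, model
refit warm-started from the voxel-free base fit; z = β/SE with SE from
the observed information; two-sided normal p. Cluster-extent thresholding
binarizes p < 0.001 within the converged mask, labels components
(default 18-connectivity, faces+edges; all three options exposed) and
keeps components strictly larger than 50 voxels. No multiple-comparison
correction is applied anywhere — the run metadata states this loudly.

## Estimation

Full-information ML over each participant's observed subvector.
Participants are grouped by missingness pattern and each pattern enters
through its count, mean and biased scatter, so one likelihood or gradient
evaluation costs O(Σ_p k_p³) independent of N. The gradient is analytic:
per-pattern dℓ/dΣ and dℓ/dμ are accumulated into full moment space and
chained through the SEM structure (every pattern matrix is affine in θ).

* Optimizer: L-BFGS on the unconstrained parameter vector. Variances are
  deliberately not log-transformed so Heywood cases (negative variance
  estimates) remain representable; they are retained and flagged, never
  clipped. Points where a pattern submatrix loses positive definiteness
  return a large barrier value with zero gradient, which the line search
  backs away from.
* Restarts: up to 3 jittered restarts, attempted only when the incumbent
  start fails to converge. Data-informed starts (occasion means into
  latent means, item deviations into intercepts) make restarts rare.
* Saturated log-likelihood (for T = 2(ℓ_sat − ℓ_model)): EM for the
  unstructured (μ, Σ) under the missingness pattern; closed form in one
  step for complete data. Independence baseline for the CFI (free means
  and variances, zero covariances — including across occasions)
  factorizes per variable and is closed-form even under missingness.
* Standard errors: inverse observed information (central differences of
  the analytic gradient). Singular information ⇒ SEs reported as
  not-available with a flag, never as zero.
* χ² convention: T uses the likelihood-ratio form (multiplier N); RMSEA
  uses N−1 in its denominator. Both reproduce the published values this
  design emulates; both conventions are exposed as options.
* Robust ("MLR-style") machinery, optional and off by default: sandwich
  SEs from casewise score outer products, and a trace-difference scaling
  factor c = [tr(A_sat⁻¹B_sat) − tr(A_mod⁻¹B_mod)]/df. Plain ML (c = 1)
  is the default because the published fit indices reproduce from the
  plain statistic and the published scaling constants are not available.
* Modification indices: multi-parameter score tests
  s′(I_cc − I_cθ I_θθ⁻¹ I_θc)⁻¹ s at the restricted optimum, all
  candidates evaluated from one extended information matrix. The partial
  search frees the top-MI item's intercepts, refits, and stops when the
  acceptance rules pass, with a hard floor of one invariant intercept.
  A standardized-residual report accompanies the search output for human
  inspection but does not drive the automation.

**Invariance decision rule.** A level is accepted when ΔCFI ≤ 0.01 *and*
the new RMSEA does not exceed the upper bound of the previous level's 90%
CI (improvement below the lower bound counts as acceptable). The scaled
χ²-difference is computed and reported but is not decisive — the design
this package emulates accepted weak invariance despite a significant
difference test.

**RMSEA CI.** Endpoints invert the noncentral χ² distribution:
P(χ²_df(λ) ≥ T) = 0.05 for the lower and 0.95 for the upper noncentrality
at 90% coverage, λ clipped at zero, mapped through √(λ/(df·(N−1))).

**Voxelwise modes.** `fixed_measurement` (default) pins
loadings/intercepts/residuals at the base fit and re-estimates only the
structural block per voxel; `full_refit` re-estimates everything. The two
agree in β sign and in z within ~10% on well-separated effects (tested);
the default exists because a whole-brain scan at ~40 ms/voxel would be
~20× slower under full refits for practically identical maps.

## Synthetic cohort

The generator produces the study conditions the pipeline assumes, with
every generating value recorded in a truth object.

* Sample: 1808 participants at baseline, 1414 and 1282 at follow-ups;
  dropout completely at random within occasion, in four patterns
  (completers, baseline-only, dropout after occasion 2, and intermittent
  return). The intermittent count is not published; fixed at 100, giving
  1182/232/294/100.
* Measurement: generating loadings follow a published 12-item
  standardized loading profile rescaled to mean 1 (effects-coding
  metric); residual SDs chosen so occasion-1 standardized loadings match
  that profile. Intercepts are a fixed sum-to-zero scatter (SD 0.15).
* Growth: latent intercept mean 2.8, SD 0.8 (1–5 Likert metric); slope
  mean −0.20, SD 0.30 over the [0,1] study window; intercept-slope
  correlation −0.2; occasion disturbance SD 0.15. Sex (coded 1 = female)
  adds +0.3 to the intercept and +0.1 to the slope; sites add small
  offsets (SD 0.08).
* Non-invariance: five items drift by ±0.4 raw units at the final
  occasion (0.6 of that at occasion 2), alternating sign — about 0.5
  latent-intercept SDs, chosen as a clearly detectable but not absurd
  violation.
* Volumes: per-participant Gaussian random fields smoothed at FWHM 8 mm
  on 2 mm isotropic voxels (σ ≈ 1.70 voxels; normalized kernel with
  reflective boundary, so the volume sum is preserved), supported on a
  brain-like ellipsoid (~3100 of 20³ voxels) that defines the mask. A
  radius-4 sphere (~250 voxels) adds coupling × latent slope + local
  noise (SD 0.3). Default coupling 1.0: voxel units are arbitrary, and
  the value was sized at design time so the planted effect is clearly
  suprathreshold (in-region z ≈ 3.5–4) at the desk-scale n = 200 — a
  weaker coupling would leave the planted cluster hovering at the
  50-voxel extent threshold and turn the localization check into a coin
  flip.
* Likert discretization is available but off by default, so the
  continuous-data estimator is exactly correctly specified in unit tests;
  switching it on exercises the (mild) misspecification of rounding.

What the generator does *not* emulate: real brain anatomy or atlas
geometry, scanner-specific artifacts, non-normal item distributions
(beyond optional discretization), informative dropout, and age/puberty/
depression covariates with realistic dependence structure. Passing tests
therefore demonstrate that the machinery is correct under its assumed
model, not that those assumptions hold in any particular cohort.

## Problem sizes in the checks

The Monte-Carlo acceptance checks run at: growth-parameter recovery, 200
replicates at N = 1000 (dropout scaled proportionally); invariance
operating characteristics, 100 replicates at the full cohort size for
both the null and the planted-drift condition; voxelwise calibration and
localization, one 200-participant cohort on the full 20³ grid
(~3100 in-mask voxels) for the null and the planted condition. Spread
parameters are assessed on the variance/covariance scale because the
square root of a noisy variance estimate is downward-biased by Jensen's
inequality regardless of estimator correctness; replicates with negative
variance estimates carry Heywood flags and are excluded from the
correlation summary rather than silently used.

## Known limitations

* Continuous-ML treatment of 5-point Likert items (no categorical
  estimator); adequate here, not a general endorsement.
* The robust scaling factor uses a trace-difference form; mean-and-
  variance-adjusted statistics are out of scope.
* The greedy MI-driven partial search stops at the first acceptable
  model, so with many mild violations it intentionally frees a subset,
  not necessarily all planted items.
* Wald z/p per voxel rely on asymptotic normality; at n ≈ 200 the
  empirical null is very slightly conservative at the 0.001 tail (tested)
  — convenient for false-positive control, but p-values near the
  threshold should not be over-read.
* First-order disturbances are uncorrelated by assumption in the growth
  stage; cross-occasion residual dependence is carried by the item-level
  lag covariances instead.
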