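# Methods

## Model and assumptions

The observed data are an N×T panel of daily emotion relative frequencies
`E_it` (fraction of day-t documents labeled with emotion i; multi-label, so
columns need not sum to one) plus M permanent 0/1 step dummies for known
platform changes. Dynamics are first-order linear-Gaussian:

    E_t = α + Γ E_{t−1} + B X_t + ε_t,   ε_t ~ iid N(0, Σ), Σ full.

Assumptions worth stating explicitly:

- **Linearity on the unconstrained scale.** Frequencies live in [0,1] but
  the model is linear-Gaussian; no logit transform or truncation is
  applied. This matches the estimation target and is adequate when the
  series sit well inside the unit interval, as daily emotion shares do.
- **Order one.** Lag selection (BIC on a common sample) is run as a
  diagnostic, not baked in; the structured estimator assumes p = 1.
- **Stationarity.** Estimation and all IRF analytics require the spectral
  radius of Γ to be below one. Stationarity is checked per series with ADF
  tests; see "Numerical choices" for the break adjustment.
- **Structured coefficients.** α and Γ are exact linear functions of the
  emotions' mean-centered appraisal-dimension scores, dictionary sizes, and
  asymmetric pairwise distances (see README for the three equations). This
  reduces N + N² autoregressive coefficients to 4K+6 shared parameters and
  is the substantive hypothesis of the analysis, not a convenience.

## Estimation

Substituting the coefficient equations into the VARX and stacking equations
destination-major gives a single regression with 4K+6 shared columns plus
N·M equation-specific exogenous columns. The estimator is two-step FGLS:

1. pooled OLS on the stacked system;
2. Σ̂ = R'R / (T−1) from the OLS residual matrix R ((T−1)×N; denominator is
   the per-equation observation count after lagging, no df correction);
3. GLS with weight Σ̂⁻¹ ⊗ I, implemented by whitening each equation block
   with the inverse Cholesky factor of Σ̂. Standard errors come from
   (X̃'X̃)⁻¹; the joint covariance of the shared block is retained for Wald
   tests (e.g. τ_k⁺ = τ_k⁻ transition symmetry, χ²(1)).

An `iterate` flag re-estimates Σ̂ from GLS residuals to convergence but
defaults off; two-step is the reference procedure. A known-Σ override turns
the estimator into plain GLS (used for the spherical-error equivalence
check against OLS). Two degenerate cases are handled deliberately: an
exactly rank-deficient design raises with the names of the offending
columns, and a numerically exact OLS fit (noiseless data) returns the OLS
solution directly, since Σ̂ is then identically zero and GLS reweighting is
a no-op.

Estimated this way, the shared parameters are identified exactly from
noiseless data, and on noisy study-sized panels the Monte-Carlo SD of every
parameter matches its reported SE to within a few percent. One calibration
caveat is intrinsic rather than implementational: the pooled carryover
intercept λ0 inherits the classic dynamic-bias of least-squares
autoregression, of order −(1+3λ)/T ≈ −0.004 at λ ≈ 0.85 and T = 790. That
is roughly one pooled standard error, so confidence intervals for λ0 alone
under-cover (≈70–80% instead of 95%) while the other seventeen shared
parameters are near-nominal. Any analysis pooling hundreds of persistent
daily series shares this property; duration intervals derived from λ0 are
correspondingly biased slightly downward.

## Post-estimation analytics

- **Duration.** The P% duration interval is ln(1−P/100)/ln(λ) − 1 days, the
  continuous solution of 1 − λ^(x+1) = P/100. It is reported per emotion
  (λ = γ_ii) and for ±1 SD profiles per dimension (λ = λ0 ± λ_k·SD_k, with
  SD_k the sample standard deviation of the K factor scores across
  emotions). Default P = 90.
- **Shock vectors.** A shock of δ to emotion i moves emotion j by
  δ·σ_ij/σ_ii on day 0 — the conditional expectation of a joint normal.
  δ defaults to 10% of the emotion's model-implied stationary mean
  (I − Γ)⁻¹(α + B x̄) with x̄ the sample mean of the dummies; the base of
  the percentage is genuinely underdetermined, so sample-mean and absolute
  modes are provided as alternatives. All reported effects are linear in δ.
- **IRF / CIRF.** Responses propagate as r_0 = shock, r_t = Γ r_{t−1};
  intercepts and exogenous terms cancel because responses are differences
  between shocked and unshocked paths (verified against that brute-force
  oracle to 1e−10). Long-term transition is the cumulative response over
  days 1–29, requiring a horizon of at least 30.
- **Distance regressions.** Off-diagonal CE and CIRF entries (N(N−1) pairs)
  are regressed by OLS on a constant, the K upward and K downward
  distances, and the destination's centered dictionary size (toggleable).
  SEs are conventional OLS; no generated-regressor correction is attempted,
  since the effects are themselves estimates — the regressions are
  descriptive summaries of the fitted system, as in the source analysis.

## Synthetic data generator

The generator emulates the study conditions end to end: N = 24 emotions,
T = 790 days, K = 3 dimensions, M = 2 step dummies switching on at 75% and
87% of the sample, 200-day burn-in from the deterministic fixed point, all
randomness from one seeded generator (bit-identical reruns).

Choices where the emulated study pins nothing down, fixed once:

- **Dimension scores** are unit-variance standard normals (the scale of
  rotated factor scores); **dictionary sizes** are log-uniform integers in
  [10, 500], so the size controls are exercised over a realistic range.
- **Shared-parameter draws** center on magnitudes typical of daily emotion
  shares: μ0 ≈ 0.05, λ0 ≈ 0.85 (strong persistence), τ0 ≈ −0.011 (small
  next-day cross-suppression), slopes an order of magnitude smaller, with
  per-emotion error SDs near 0.004.
- **Error covariance** is distance-structured: correlation is a 0.6/0.4
  blend of a Gaussian kernel in the appraisal space and a random
  correlation matrix, both PSD. Emotions close in the space therefore
  co-occur more — the qualitative co-occurrence structure the analysis is
  designed to detect; a fully unstructured Σ would leave the CE/CIRF
  distance regressions with nothing to find.
- **Stationarity** is enforced by rescaling the carryover/transition block
  uniformly until the spectral radius of Γ meets the target (0.9). Γ is
  linear and homogeneous in that block, so the returned structural truth
  re-expands to the simulated Γ exactly.
- Simulated frequencies may leave [0,1] under Gaussian noise; clipping is
  available but off by default, and the clip rate is logged when used,
  because estimation is linear-Gaussian.
- **Toy corpora** plant one dictionary term per emotion per document with
  probability equal to that day's rate, inside filler text drawn from a
  vocabulary disjoint from all dictionary tokens, recording ground truth.

What the generator does **not** emulate: morphology or realistic token
distributions, diurnal/weekly structure, heavy-tailed or heteroskedastic
noise, volume variation across days, and any nonlinearity near the [0,1]
boundaries. Passing tests therefore certify the estimator and analytics
under the model's own assumptions — not robustness of the pipeline to the
ways real social-media text violates them.

## Numerical choices

- Shared parameters are ordered (μ0, μ_1..K, μ_S, λ0, λ_1..K, λ_S, τ0,
  τ⁺_1..K, τ⁻_1..K, τ_S); equations stack destination-major. This ordering
  is fixed and is the index convention for the joint covariance.
- ADF tests use a constant, AIC lag selection, and the 5% MacKinnon
  critical value. Known step dummies are partialled out by OLS before
  testing: a permanent level shift left in a series mimics a unit root and
  collapses the test's power (measured: ~60% rejection on raw simulated
  series with breaks vs 100% after adjustment).
- Lag-order criteria (AIC/BIC/HQC, Lütkepohl forms with total parameter
  count) are computed on a common sample (first p_max observations dropped
  for every candidate order); BIC is the headline selector.
- Granger tests are per-pair Wald tests of the single cross-lag coefficient
  in the unrestricted VAR(1) with exog; diagonal entries are NaN.
- Factor reduction is principal-axis factoring on the appraisal correlation
  matrix with varimax rotation and regression-method scores. When K = 3 and
  the survey contains the valence/arousal/dominance columns, factors are
  assigned one-to-one to those anchors by maximal absolute loading
  (Hungarian assignment) and signed so the anchor loads positively.
  Externally supplied dimension scores bypass this step entirely, so the
  extraction choice is not load-bearing for the rest of the pipeline.
- The Σ factor used for simulation comes from an eigendecomposition with
  negative eigenvalues clipped at zero, so exactly singular (including
  zero) covariances simulate cleanly.

## Problem sizes

Monte-Carlo suites use sizes chosen to make their statistical point
crisply: CI calibration runs 100 study-sized panels (24×790); diagnostic
size/power checks use 100–200 replications at T = 300–790 with 5–8 series;
the end-to-end sign-recovery study runs 50 study-sized replications. All
are seeded and deterministic.

## Known limitations

- Single lag, constant parameters, Gaussian errors; no bootstrap bands on
  IRFs and no orthogonalized (Cholesky-ordered) IRFs — shock vectors come
  from conditional normal expectations instead.
- The λ0 dynamic bias discussed above.
- Dictionary matching is exact string equality after case-folding;
  lemmatization and dictionary construction are upstream concerns.
- CE/CIRF regression SEs ignore estimation error in the effects.
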