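# emovar

Aggregate emotion dynamics in online-social-network conversations, modelled
with a dimension-structured vector autoregression.

## The problem

Daily time series of emotion expression — the fraction of a day's posts
carrying each of N discrete emotions, obtained by dictionary matching — rise
and fall together: an exogenous event boosts anger, anger lingers for days,
and as it fades other emotions flourish or wither. `emovar` is for
researchers who want to quantify three components of that flow:

- **frequency** — which emotions occupy the conversation more on average,
- **duration** — how long an emotion takes to return to its normal level
  after a shock,
- **transition** — which emotions co-occur with, follow, or are suppressed
  by a boosted emotion, over horizons from the same day to a month,

and to explain all three as functions of where emotions sit in a
K-dimensional appraisal space (valence, arousal, dominance).

## The model

The daily frequencies follow a first-order VARX,

```
E_t = α + Γ E_{t−1} + B X_t + ε_t ,   ε_t ~ N(0, Σ),
```

with step dummies `X_t` controlling for known platform changes and a full
error covariance Σ capturing same-day co-occurrence. Rather than estimating
the N + N² free coefficients, they are restricted to functions of the
emotions' mean-centered appraisal scores `DIM̄_ik` and dictionary sizes `S̄_i`:

```
α_i  = μ0 + Σ_k μ_k DIM̄_ik + μ_S S̄_i                       (base level)
γ_ii = λ0 + Σ_k λ_k DIM̄_ik + λ_S S̄_i                       (carryover)
γ_ij = τ0 + Σ_k τ_k⁺ DIST⁺_ijk + Σ_k τ_k⁻ DIST⁻_ijk + τ_S S̄_i   (i ≠ j)
```

where `DIST⁺_ijk = max(DIM_ik − DIM_jk, 0)` and `DIST⁻` is its mirror — the
asymmetric distances that let an upward move on a dimension differ from a
downward one. Substituting these into the VARX yields one stacked regression
with 4K+6 shared parameters (18 when K = 3) plus N·M free exogenous
coefficients, estimated by two-step feasible generalized least squares.

Post-estimation analytics follow from the fitted system:

- the P% duration interval `ln(1 − P/100)/ln(λ) − 1` in days;
- shock vectors with day-0 entries `δ·σ_ij/σ_ii` (conditional-normal
  co-occurrence), propagated by `Γ` into impulse-response paths;
- the cumulative IRF over days 1–29 as the long-term transition measure;
- OLS regressions of day-0 and cumulative effects on the asymmetric
  distances between emotion pairs.

A seeded synthetic-data module generates appraisal scores, structural truth,
stationary panels and toy labeled corpora, so every stage is testable
without access to a social-media corpus.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data. Generating a 24-emotion, 790-day panel and fitting it:

```
$ python analysis/01_simulate_study.py --seed 1
simulated 790 days x 24 emotions (seed 1); spectral radius 0.900; daily
frequencies span 0.023-0.332 on average
truth carryover baseline lam0 = 0.812882

$ python analysis/03_fit_model.py
stacked design: 18936 rows x 66 columns (18 shared)
carryover baseline lam0 = 0.809243 (SE 0.003649)
...
dimension 1 up/down transition symmetry: chi2(1) = 0.112, P = 0.738 -> symmetric

$ python analysis/04_durations.py
average-profile carryover 0.809243 -> 90% duration interval 9.9 days
  dim_1_+1sd         carryover 0.8378 -> 12.0 days
  dim_1_-1sd         carryover 0.7807 -> 8.3 days
  ...
```

The fitted λ0 lands within one standard error of the generating truth; the
duration rows read as "an emotion one standard deviation above average on
dimension 1 needs 12.0 days for 90% of a shock's effect to play out, versus
8.3 days one standard deviation below". `analysis/05_shock_analysis.py`
then shocks each emotion by 10% of its stationary mean and regresses the
resulting co-occurrence (CE) and long-term transition (CIRF) matrices on
the pairwise appraisal distances — in the synthetic study, both fall with
distance on every dimension, i.e. nearby emotions co-occur and succeed each
other more.

The same stages are available as a CLI (`emovar simulate | label | fit |
diagnose | irf | report`) for file-based workflows.

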