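# Methods

This note records the statistical model the package implements, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate.

## The estimation problem

Two surveys observe the same county-level prevalences with complementary
defects.  The in-person survey reaches households of every telephone status
(landline, cell-only, no phone) and is treated as unbiased, but by design it
samples only ~25% of counties, with small per-county samples.  The
telephone survey samples every county and is roughly ten times larger per
county, but covers only landline households and carries an unknown
multiplicative bias (noncoverage, nonresponse).  Telephone status matters
because the strata differ sharply in behavior — e.g. smoking runs
landline < cell-only < no-phone — so landline-only data misrepresent the
county mean, increasingly so where cell-only households are common.

## Model

Direct survey estimates are computed per county × stratum as
Horvitz–Thompson weighted proportions with a Kish design-effect variance
(deff = n·Σw²/(Σw)², n_eff = n/deff, var = deff·p̂(1−p̂)/n).  The full
Taylor-linearized stratified-PSU variance estimator is intentionally not
implemented: the model consumes only (p̂, n_eff), and the design labels are
carried through the data structures so a linearized estimator could be
added without format changes.

Estimates are mapped to the arcsine-root scale, y = arcsin(√p̂), whose
sampling variance 1/(4·n_eff) is free of the unknown p — the
variance-stabilization that lets an area-level model treat level-1
variances as known.  Boundary estimates (p̂ ∈ {0,1}) are first shrunk
toward ½ by 1/(4n) (Anscombe-style guard), and a variance floor
1/(4·n_eff·n) replaces the zero binomial variance there.  Stratum estimates
based on fewer than 2 respondents are dropped from level 1 (point estimate
unstable in variance); the threshold is an argument of `assemble_level1`.

The hierarchical model is the one in the package README:
y_is ~ N(θ_is, v_is) for in-person components, z_i ~ N(λθ_iL, w_i) for the
telephone component, θ_i = Bx_i + u_i, u_i ~ MVN(0, Σ).  Key modeling
decisions:

* **Bias factor λ acts multiplicatively on the transformed scale** (the
  level-1 telephone mean is λ·θ_iL).  "Proportionate bias" is read as
  proportionality of the level-1 mean; this is the single place to change
  if an alternative reading (e.g. proportionality on the prevalence scale)
  is wanted.
* **One global λ per outcome**, not county-specific: the bias is a property
  of the survey instrument, and a county-specific factor would be
  unidentifiable from single-county data.
* **Full 3×3 Σ** so that a county observed only through its telephone
  component still receives posterior information about its cell-only and
  no-phone strata via the between-stratum correlations (a diagonal-Σ
  restriction can be expressed by passing a diagonal `sigma_scale` and
  large `sigma_df`, but the full matrix is the default and the recommended
  setting).
* **Level-1 covariance diagonal**: stratum estimates are computed from
  disjoint respondent sets and the two surveys are independent; this is the
  minimal assumption and it is isolated in the transform module.
* **Missing components are masked in the likelihood**, never imputed.

## Priors

Diffuse but proper: vec(B) ~ N(0, 100·I); λ ~ N(1, 1) truncated to (0, ∞)
(centering at 1 encodes "no bias" as the default belief); Σ ~
Inverse-Wishart(df = 5, scale = 0.01·I), whose prior mean 0.01·I is of the
order of the between-county variance seen on the arcsine scale.  All are
exposed in `Priors`.

## Gibbs sampler

All full conditionals are conjugate: θ_i multivariate normal (3×3, batched
across counties), B normal, λ normal truncated positive, Σ
inverse-Wishart.  Two implementation choices matter:

* **Collapsed B update.**  The textbook sweep (B | θ, then θ | B) mixes
  arbitrarily slowly for the intercepts when most counties carry little
  stratum-level data, because θ regenerates near Bx each sweep and B then
  shadows θ.  `fit(collapsed=True)` (default) instead draws B from its
  conditional given (Σ, λ) with θ integrated out — marginally
  y_i ~ N(A·Bx_i, AΣA′ + V_i) with A = [I₃; λe_L′], still conjugate
  normal — and then θ | B.  This is a valid blocked Gibbs step and raised
  the worst-parameter effective sample size by two orders of magnitude in
  our checks.  The plain conditional kernel is kept (`update_beta`) and
  unit-tested against the OLS-based conjugate posterior.
* **θ truncation.**  θ draws are restricted to [0, π/2] by rejection (100
  attempts, then clipping) so the back-transform sin²θ is always defined.
  The truncation can be disabled (`truncate_theta=False`); the
  prior-sampling diagnostic requires this, since truncation would distort
  the prior being checked.

Initialization: B by least squares of observed components on covariates
(telephone component standing in for missing landline values), θ at
observed values where present else Bx, λ ≈ 1, Σ = 0.01·I, with small seeded
jitter so chains are not identical.  Chains are seeded independently via
`SeedSequence(seed, spawn_key=(chain,))`.

Convergence is monitored with split-R̂ and bulk ESS (via arviz) over β, λ
and Σ; the run is flagged non-converged (a `RuntimeWarning`, never a silent
success) if max R̂ > 1.1 or min ESS < 400.  The slowest direction is the
λ–θ_L–intercept ridge (λ is identified only by the ~25% of counties
observed by both surveys); reaching ESS ≥ 400 there needs on the order of
30–40k sweeps at 200 counties, which is the setting used in the acceptance
battery (2 chains × 20,000 iterations, 4,000 burn-in, thin 4 — about three
minutes on one CPU).  Defaults (`n_iter=4000`) are meant for interactive
use; production runs should scale up and watch the flag.

## Composition and back-transform

County estimates are combined per posterior draw,
π_i^(g) = Σ_s φ_is·sin²(θ_is^(g)), then summarized (mean, equal-tailed
2.5/97.5 percentiles).  Applying the composition and back-transform at the
draw level, not to posterior means, is deliberate: sin² is nonlinear and
the draw-level computation propagates posterior uncertainty correctly.

φ weights are household shares (the quantity the phone-composition data
measure); they are treated as fixed and known at composition time, so their
own estimation error is not propagated — a stated limitation.

Compositions are estimated from the in-person survey's county phone-status
counts by empirical-Bayes smoothing: log-odds (cell-only vs landline,
no-phone vs landline, with a +0.5 continuity correction) are shrunk toward
a weighted least-squares covariate regression, with the between-county
variance estimated by a Fay–Herriot-style moment matcher; counties without
sample receive the pure regression prediction, and the result is mapped
back to a simplex by softmax.  No installed library offers this smoothing
directly; the regression step uses statsmodels WLS.

## Synthetic-data generator

The generator is the package's study-conditions definition, not a tuning
knob.  Defaults:

| parameter | default | rationale |
|---|---|---|
| m_counties | 300 (200 in the acceptance study) | enough counties for stable coverage/recovery statistics |
| stratum intercepts | arcsin√(0.177, 0.273, 0.309) | the landline/cell-only/no-phone smoking gradient magnitude |
| Σ_true | 0.002·(0.5I + 0.5J) | between-county SD ≈ 4.5% on the arcsine scale with cross-stratum correlation 0.5 |
| λ_true | 0.9 | a clearly biased telephone survey, prevalence-scale bias of a few points |
| nhis_county_fraction | 0.25 | ~three-quarters of counties have no in-person sample |
| nhis_mean_n / brfss_mean_n | 12 / 120 | the ~10× per-county size ratio of the two surveys, scaled down |
| weight_cv | 0.7 | lognormal weights, Kish deff ≈ 1 + CV² ≈ 1.5 |
| phi center / logit SD | (0.750, 0.232, 0.018) / 0.4 | national phone shares; SD chosen so the county mean stays within 0.01 of the center while no-phone shares span roughly 0.3–6% |
| θ clip | [0.02, π/2 − 0.02] | excludes degenerate 0/1 prevalences |

Telephone-survey county sample sizes are Poisson with mean proportional to
county population (`brfss_mean_n` × population / mean population, truncated
at 2): county telephone samples scale with population, which is what
spreads counties across the effective-sample-size range the funnel
diagnostic needs.  County populations are lognormal (median ≈ 22k adults,
log-SD 1.2).  In-person counties are chosen uniformly at random — the real
multistage PSU selection is out of scope — with Poisson(12) samples
allocated to strata multinomially by φ_i and grouped into PSUs of 5.

φ_i is logistic-normal rather than Dirichlet so that composition could be
regressed on covariates later; how the original phone-composition estimates
were modeled is not documented anywhere we know of, so the logistic-normal
is an explicit stand-in.

What the generator does **not** emulate: the real multistage area frame and
its PSU selection probabilities, state-level telephone stratification, item
and unit nonresponse, raking of weights, demographic denominators (the 11
shipped outcome definitions carry sex/age filters that apply when microdata
have `sex`/`age` columns, but the generator produces a single generic
outcome), and spatial correlation between neighboring counties.  Passing
tests therefore demonstrate internal validity — the estimator recovers the
model's own truth under realistic sparsity, bias and weighting — not
robustness to design features the generator omits.

## Validation battery

* **Funnel**: ratios sin²(z_i/λ̂)/modeled landline estimate against
  telephone n_eff, summarized as mean |log ratio| in bins (≤25, 25–100,
  >100) so tests can assert the funnel shape numerically; both sides are
  back-transformed to the prevalence scale before the ratio (computing the
  ratio on the transformed scale is the noted alternative).
* **Aggregation**: population-weighted mean of county estimates compared
  with both national direct estimates; it should track the in-person
  (unbiased) one whenever λ ≠ 1.
* **Summaries**: per-outcome min/q25/median/q75/max/mean/SD on the percent
  scale; quantiles use linear interpolation between order statistics.
* **External correlation**: weighted Pearson correlation (weighted means
  and variances) against any external county rate table, e.g. registry
  mortality, weighted by inverse rate variance.  With real data this is the
  external-validity check; the test suite exercises it on synthetic rates
  only.

## Problem sizes and numerical checks used by the test battery

The conjugate-oracle check fixes B, Σ, λ (a testing hook in the model
constructor) so the θ draws are iid from a known normal posterior; it uses
200,000 draws so that Monte-Carlo noise (relative SD √(2/N) for the
variance) sits well inside the 1% agreement it asserts, at ~20 s of
runtime.  The recovery study uses 200 counties, 3 covariates, λ_true = 0.9.
The prior-sampling (Geweke-style) check masks all data and compares chain
moments of β, λ, Σ with the exact prior means, using moderate proper priors
(β variance 0.25, Σ scale 0.5·I with df 6, λ ~ N(1, 0.25)⁺): with the
diffuse defaults the no-data chain mixes arbitrarily slowly over β and the
check would be vacuous.  Assertion thresholds are 4 ESS-based Monte-Carlo
standard errors.

## Known limitations

* φ uncertainty is not propagated into county credible intervals.
* The Kish approximation ignores clustering; design effects here come only
  from weight variation.
* The delta-method variance 1/(4 n_eff) degrades for stratum cells with a
  handful of respondents; cells with n < 2 are dropped, n of 2–5 are kept
  with approximate variances (interval calibration in the acceptance study
  absorbs this: coverage stays in the low-to-mid 90s).
* Outcomes are modeled one at a time; joint multivariate modeling of
  several outcomes is out of scope.
* No spatial (e.g. CAR) structure among counties; exchangeability given
  covariates.
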