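# Methods

## The model

`ghqlong` analyses three-wave longitudinal responses to a 12-item ordinal
distress questionnaire (GHQ-12, categories 0-3 per item) with a Bayesian
multilevel graded-response model (GRM). Person `p`'s latent distress when
answering item `i` at a given wave is

```
eta_pi = theta_p + sum_j beta_j x_jpi
```

with `theta_p ~ Normal(0, 1)` a person-level intercept and `x` the design
covariates: sex (women vs. men as reference), standardized age, wave dummies
(wave 0, before the trip, as reference), season-of-year terms
`cos(2*pi*t/360)` and `sin(2*pi*t/360)` where `t` counts days from the first
trip-return date in the study (2018-08-12), diarrhoea-during-trip and
diarrhoea-after-trip flags, and optionally wave-by-season interactions. The
measurement model is cumulative-logit:

```
Pr(y_pi <= k) = logistic(exp(log_disc_i) * (tau_ik - eta_pi)),   k = 0,1,2
```

with ordered item thresholds `tau_i1 < tau_i2 < tau_i3` and item
discrimination on the log scale (hence always positive). Negative wave
coefficients mean less distress at that wave.

**Identification.** The person effect is fixed to unit variance
(`theta_p ~ N(0,1)`); the latent scale is carried by the discriminations.
This matches reporting a discrimination intercept rather than a person SD.

**Model ladder.**

| variant | thresholds | covariates |
|---|---|---|
| m1 | 3 shared + per-item scalar shift (random effect, correlated with the log-discrimination random effect) | sex, age, waves |
| m3 | 3 x 12 item-specific, fixed | sex, age, waves |
| m4 | as m3 | + season cos/sin, diarrhoea flags |
| m5 | as m3 | + wave x cos and wave x sin interactions |

In all variants the log discrimination is hierarchical:
`log_disc_i = disc_intercept + sd_disc * z_i`. In m1 the threshold shift and
discrimination random effects are a correlated bivariate pair
(`cor(disc, thr)`), sampled non-centered.

**Season convention.** The annual cycle is encoded as `cos(2*pi*t/360)` /
`sin(2*pi*t/360)` — a 360-day period. An annual cycle is the only reading
under which "time of year" is meaningful for trip-return dates spanning
August to March.

**Priors.** Coefficients `beta ~ Normal(0, 5)`. Thresholds and the
discrimination intercept: Student-t(3, 0, 2.5). Random-effect SDs:
half-Student-t(3, 0, 2.5) sampled on the log scale. The m1 random-effect
correlation is uniform on (-1, 1) via a tanh transform. All location-type
t priors carry an additional very weak Gaussian containment component
(scale 30): the GRM likelihood is nearly invariant under
`disc -> disc/c, tau -> c*tau, beta -> c*beta`, and pure t tails leave that
plateau without restoring force, occasionally trapping short-warmup chains
at `disc ~ e^-30`. The containment costs under 0.06 log-units anywhere in
the scientifically plausible region (|x| < 10) and eliminates the plateau;
in a 40-seed stress test it removed all trapped chains.

## Posterior computation

Sampling is Hamiltonian Monte Carlo with hand-derived analytic gradients of
the joint log posterior (all parameters sampled jointly, ordered-threshold
and log-scale transforms with their Jacobians, non-centered random
effects). The sampler uses dual-averaging step-size adaptation (target
acceptance 0.8), a diagonal mass matrix re-estimated from the middle 50% of
warmup, uniformly jittered trajectory lengths (nominal integration time 6.0,
at most 128 leapfrog steps), and divergence rejection at an energy error of
1000. Warmup includes a rescue step: if at the mass re-estimation point the
chain sits far (>50 log-units) below the best log posterior seen, it is
reset there. The gradient hot loop is a compiled (numba) single pass over
observations; the pure-numpy path remains as fallback and as the reference
in gradient tests. Gradients are verified against central finite differences
in the test suite.

Defaults: 4 chains, 1000 warmup + 1000 retained draws (full profile); the
test and acceptance profile uses 2 chains and 250-300/250-300, which the
recovery and convergence checks show is sufficient at these sample sizes.
Convergence is gated on rank-normalized split R-hat < 1.05 (strict; arviz
implementation), with effective sample sizes reported per parameter. Fits
failing the gate are flagged, never silently returned as converged.

## Synthetic cohort generator

The generator emulates the study cohort: N=174 persons, 27% men, ages
uniform on 18-65 (the uniform reproduces the reported age SD of ~16.5 given
only mean/SD/range; no extra shape is invented), 16 equally spaced
trip-return dates from 2018-08-12 to 2019-03-10 assigned uniformly,
diarrhoea-during-trip at 71% and after-trip at 13%, drawn independently of
each other and of the latent trait (no joint distribution is reported; a
distress-dependent attrition hook exists for stress tests). Default
latent-scale effects: wave1 -0.63, wave2 -0.21, diarrhoea-after +0.53,
diarrhoea-during -0.24, sex -0.06, age -0.05, season cos +0.01 / sin -0.18
— the scale of effects the analysis is designed to detect. Item structure:
shared thresholds (-1.5, 2.7, 6.2), log-discrimination intercept 0.06, item
random-effect SDs 0.32 (discrimination) and 1.29 (threshold shift) with
correlation 0.35. These produce wave-0 Likert-sum means near 11 and
caseness rates near 20-25%, matching the cohort being emulated.

Attrition targets per-wave item-response coverage of 98% / 76% / 72% and is
imposed person-wave-first: whole person-waves are deleted to the nearest
whole person, and at most `max_partial_responders` (default 2) persons lose
only some items — mirroring the observation that missingness was almost
entirely person-level. Deletion is missing-completely-at-random by default;
`distress_weight > 0` gives a missing-not-at-random variant. Attrition only
deletes records; it never alters a response.

The option `threshold_gap_jitter_sd` perturbs each item's threshold *gaps*
on the log scale, producing threshold patterns that differ between items
beyond a common shift. This is the generating condition under which the
shared-threshold model (m1) is genuinely misspecified and the
item-specific-threshold model (m3) should win the LOO comparison; with the
default shift-only structure, m1 is exactly correctly specified and no
preference is expected.

What the generator does not emulate: correlation between diarrhoea and
distress, non-uniform assignment of trip dates, informative missingness
(unless enabled), and any item-content structure (items are abstract
indices). Passing tests therefore demonstrate correctness of the machinery
and recoverability under the assumed structure, not robustness to
violations of it.

## Scoring and classical tests

Likert scoring sums raw categories (0-36); interpreted 0-0-1-1 scoring
counts items with category >= 2 (0-12); caseness is interpreted score >= 3.
Scoring is complete-case: any missing item makes the person-wave's scores
missing (the reported respondent denominators fall below N accordingly; no
proration rule is invented). Display percentages round half-up; raw
proportions are kept in machine output.

The "complete-data linear model" across waves is a one-way fixed-effects
ANOVA on person-wave Likert sums treating person-waves as independent —
an interpretive reading supported by the denominator degrees of freedom
matching the summed respondent counts minus 3. Paired comparisons are
two-sided paired t-tests on within-person differences, Likert sums by
default (a flag switches to interpreted scores); no multiplicity
correction is applied, as none is reported for these tests.

## Multiple imputation

Chained equations with predictive mean matching (statsmodels MICEData),
item-level in wide format (one column per wave-item), donor pool 5, 10
sweeps per completed dataset by default, m=100 by default (tests and the
acceptance script use smaller m). Each item's imputation model regresses on
the fully observed person covariates plus the same item at the other waves:
missingness is person-wave structured, so within-wave items are missing
together and carry no donor signal, while a full all-column model is
ill-conditioned at N~174. Imputed values are always observed donor
categories; observed cells are never altered (asserted at runtime). Pooled
fitting runs the GRM per completed dataset and concatenates draws with
equal weight; convergence is assessed per dataset and any failure flags the
pooled result. Covariates are fully observed and are not imputed.

## LOO model comparison

The observation unit is a single item response (person-wave-item), matching
the pointwise likelihood factorization. PSIS-LOO (arviz) yields elpd, its
SE and per-observation Pareto-k diagnostics; the share of k > 0.7 is
reported as a reliability warning. LOOIC = -2 elpd. Model differences are
`looic(a) - looic(b)` with an SE from paired pointwise elpd differences;
negative values favour the first-listed model, stated in output headers.

## Posterior-predictive reporting

`predict_wave_sums` simulates item responses per posterior draw for the
completely observed person-waves (matching the complete-case convention of
the observed summaries), sums to the 0-36 score, and reports the posterior
mean of the within-wave mean and SD next to the observed values.
`seasonal_effect_curve` summarizes, per unique trip-return date, the total
wave coefficient `b_wave + b_wave_cos*cos + b_wave_sin*sin` by posterior
mean and equal-tailed 95% interval; the sine interaction can be excluded
via the m5 configuration switch. Credible intervals are equal-tailed
posterior quantiles throughout. The canonical artifacts are numeric
per-date tables; plots are rendered from them optionally.

## Problem sizes used in tests and the acceptance script

Parameter recovery runs 10 replicates at N=90 with the reduced sampler
profile; the model-selection direction check runs 20 replicates at N=90;
imputation robustness uses the full N=174 with m=5-8 completed datasets;
the main acceptance analysis runs the full ladder at N=174 with 2 chains of
300+300. These sizes keep the full analysis reproducible on a single CPU
while leaving the checked properties (interval coverage, bias below 0.1,
LOO direction, pooled-vs-direct agreement within one SD) at their stated
strengths.

## Known limitations

- The sampler is a fixed-length jittered HMC, not NUTS; very high
  posterior correlations would mix more slowly than in Stan. The R-hat gate
  guards against undetected failures.
- PSIS-LOO at the item-response level treats responses as exchangeable
  units; leave-one-person-out would be a stricter (and costlier) check.
- The m1 threshold random effect is a scalar shift per item; cross-item
  differences in threshold spacing are only representable from m3 upward.
- MICE-PMM assumes the missingness is ignorable given the predictors; the
  MNAR generator mode exists precisely to probe where that fails.
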