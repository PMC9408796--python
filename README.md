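# ghqlong

Bayesian multilevel graded-response modelling of longitudinal GHQ-12
psychological-distress data.

## What this is for

Cohort studies sometimes measure psychological well-being with the 12-item
General Health Questionnaire (GHQ-12) repeatedly — for example before a
trip, at return, and a month later — and ask how distress changes across
occasions, whether covariates such as sex, age, time of year or an illness
episode shift it, and whether conclusions survive the attrition that
longitudinal questionnaires always suffer. Sum scores discard item
information and handle missing items awkwardly; `ghqlong` instead treats
the 12 ordinal items (categories 0-3) directly with an ordinal item
response model and regresses the latent distress on covariates.

The core model is a multilevel Bayesian graded response model: person `p`'s
latent distress answering item `i` is

    eta_pi = theta_p + sum_j beta_j x_jpi,     theta_p ~ N(0, 1)

with the cumulative-logit measurement model

    Pr(y_pi <= k) = logistic(exp(log a_i) * (tau_ik - eta_pi)),

where each item carries ordered thresholds `tau_i1 < tau_i2 < tau_i3` and a
log-scale discrimination `a_i`. A ladder of variants (shared thresholds
with item random effects; item-specific thresholds; season and illness
covariates; wave-by-season interactions) is compared with PSIS-LOO.
Posterior sampling is Hamiltonian Monte Carlo with analytic gradients,
gated on rank-normalized split R-hat < 1.05.

The package also provides: a synthetic cohort generator (latent-trait
responses, wave effects, seasonal structure, person-wave attrition) so the
whole pipeline is testable without restricted participant data; both
classical GHQ-12 scorings (0-36 Likert sum; 0-0-1-1 score with caseness at
3+) and descriptive tables; wave ANOVA and paired t-tests; multiple
imputation by chained equations with predictive mean matching and pooled
fitting; posterior-predictive checks in sum-score units; and seasonal
effect curves. See `docs/methods.md` for the full model account.

## Worked example

```python
from ghqlong import simulate, scoring, classical
from ghqlong.grm import GradedResponseModel

cfg = simulate.CohortConfig(seed=1)          # N=174, study-like conditions
persons, items, complete, observed = simulate.simulate_study(cfg)

scored = scoring.score_waves(observed)
summary = scoring.descriptive_summary(scored, persons, observed)
print(summary["waves"][["wave", "n_respondents", "n_cases", "case_percent",
                        "likert_mean", "likert_sd"]].round(2))

anova = classical.wave_anova(scored)
print(f"wave ANOVA: F={anova.statistic:.2f}, "
      f"df=({anova.df1:.0f}, {anova.df2:.0f}), p={anova.p_value:.2g}")

model = GradedResponseModel(variant="m4", chains=2, warmup=300, draws=300, seed=2)
model.fit(observed, persons)
print("converged:", model.converged_)
s = model.summary()
print(s[s.parameter.isin(["b_wave1", "b_wave2", "b_diarrhoea_after"])]
      [["parameter", "mean", "sd", "q2.5", "q97.5"]].round(2))
```

Output:

```
 wave  n_respondents  n_cases  case_percent  likert_mean  likert_sd
    0            170       36            21        10.22       3.63
    1            132       12             9         8.27       3.20
    2            125       20            16         9.17       3.38
wave ANOVA: F=12.17, df=(2, 424), p=7.3e-06
converged: True
        parameter  mean   sd  q2.5  q97.5
          b_wave1 -0.71 0.09 -0.88  -0.55
          b_wave2 -0.35 0.08 -0.53  -0.19
b_diarrhoea_after  0.32 0.31 -0.26   0.91
```

Reading this: the synthetic cohort loses respondents across waves (170 to
125 complete person-waves) the way the emulated study did; caseness (0-0-1-1
score of 3 or more) drops from 21% before the trip to 9% at return and
partially rebounds to 16%. The classical F-test confirms the wave means
differ. On the latent scale the model recovers the generating structure:
wave 1 lowers distress by about 0.7 latent units (95% CI excludes zero),
wave 2 retains about half the improvement, and the diarrhoea-after-return
coefficient is positive (more distress) but uncertain at this sample size.
A negative wave coefficient means less distress than at baseline.

The same stages are scriptable from the shell:

```bash
ghqlong simulate --seed 1 --out-dir out
ghqlong score --responses out/responses.csv --out-dir out
ghqlong test-waves --scored out/scored.csv --out-dir out
ghqlong fit --responses out/responses.csv --persons out/persons.csv --model m4
```

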