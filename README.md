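# pm25life

Direct small-area estimation of the mortality and life-expectancy burden of
fine particulate air pollution (PM2.5) from county death-rate panels.

Instead of transporting hazard ratios from prospective cohorts, the *direct*
approach regresses county-level cardiorespiratory death rates on county
annual PM2.5 concentrations across many small areas and years, adjusting for
other determinants of mortality, and then converts the fitted concentration–
response into counterfactual deaths and life expectancy. `pm25life`
implements that full pipeline for county-by-year-by-sex-by-age panels
(1999–2015-style, 18 age groups from 0–4 to 85+), together with a synthetic
panel generator with known ground truth, so every stage is testable without
restricted vital-registration data.

## The models

For one sex and age group, deaths in county *c* and year *t* follow

```
D_ct ~ Poisson(rate_ct · P_ct)
```

with four nested log-linear specifications of the rate:

| model                | log rate_ct =                                                              |
|----------------------|----------------------------------------------------------------------------|
| Unadjusted           | α₀ + β₀·t + ν_t + γ·PM_ct + ε_ct                                           |
| Covariate            | … + Σᵢ θᵢ·X_ict                                                            |
| Covariate-and-county | … + Σᵢ θᵢ·X_ict + α_c                                                      |
| Restrictive          | … + Σᵢ θᵢ·X_ict + α_c + β_c·t                                              |

where ν_t is a first-order random walk (nonlinear time trend), α_c and β_c
are county random intercepts/slopes with an intrinsic conditional
autoregressive (CAR) prior over the county adjacency graph, ε_ct is iid
Gaussian overdispersion, and the nine covariates X are log income, poverty %,
Black/African-American %, high-school completion %, urbanicity %,
unemployment %, a log age-standardised lung-cancer death rate (cumulative
smoking proxy), mean temperature and relative humidity. γ is the log rate
ratio per 1 μg/m³ PM2.5; random-effect log-precisions carry logGamma(1,
0.001) hyperpriors. Models are fitted independently for each of the 36
sex-age strata by an empirical-Bayes Laplace approximation over the latent
Gaussian field (the same model family nested Laplace approximation software
targets); see `docs/methods.md`.

Downstream, the fitted γ per stratum yields averted deaths under a
counterfactual concentration field,

```
averted = D_obs · (1 − exp(γ · (PM_cf − PM_obs)))
```

propagated per posterior draw, and abridged lifetables with a
Kannisto–Thatcher expansion of the 85+ group convert averted deaths into
life-expectancy loss. A quintile regression quantifies how the loss varies
across county sociodemographic strata after accounting for exposure.

## Worked example

```python
import numpy as np
import pm25life as pl

cfg = pl.GeneratorConfig(n_counties=100, n_states=4, seed=7)
panel = pl.generate_panel(cfg)
merged, plan = pl.merge_small_counties(panel, threshold=25_000)

fits = pl.fit_all_strata(merged, model="covariate_county")
rr = fits[("F", "60-64")].rate_ratio(delta_pm=10.0)

att = pl.scenario_attribution(merged, fits, pl.floor_scenario(merged, floor=2.8),
                              n_draws=500, rng=np.random.default_rng(7))
loss = pl.le_loss(merged, att, unit="national", sex="F")
```

prints (via the obvious `print` statements):

```
100 counties -> 89 analysis units
population-weighted PM2.5: 13.5 (1999) -> 8.0 (2015) ug/m3
RR per 10 ug/m3, women 60-64: 1.218 (95% CrI 0.996-1.490)
sex  averted_mean  averted_q2.5  averted_q97.5
  F         973.4         532.1         1463.6
  M        1701.9         900.4         2323.3
F: e0 = 81.18 y, LE loss = 0.316 (0.163-0.471) y
M: e0 = 76.10 y, LE loss = 0.307 (0.191-0.410) y
```

Reading this: counties whose sex-specific population dips below 25,000 in
any year were merged with same-state, same-urbanicity neighbours (100 → 89
units). The main (Covariate-and-county) model estimates that a 10 μg/m³
higher concentration multiplies the cardiorespiratory death rate of women
aged 60–64 by ≈1.22. Had every county been at the 2.8 μg/m³ floor in 2015,
≈970 female and ≈1,700 male cardiorespiratory deaths would have been averted
in this synthetic population, worth ≈0.3 years of life expectancy at birth.

A thin CLI mirrors the pipeline stage by stage
(`pm25life simulate|merge|fit|attribute|lifetable|inequality`); each stage
reads and writes plain-text tables.

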