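# Methods

This note documents the statistical models, the synthetic data they are
exercised on, the numerical choices behind the inference backend, and the
limits of what the test suite demonstrates.

## 1. Panel structure and unit construction

The unit of analysis is a county-year-sex-age cell carrying a population, a
cardiorespiratory death count, an all-cause death count, an annual mean
PM2.5 concentration (μg/m³, shared across sex/age within a county-year) and
nine time-varying covariates. Age is discretised into eighteen 5-year groups
0–4 … 80–84 plus 85+. Income and the lung-cancer smoking proxy are stored
log-transformed; the remaining covariates are percentages or means on their
natural scale.

Small counties make age-specific death rates incomputable (zero population
cells). Counties whose *sex-specific* population falls below 25,000 in any
year are therefore merged recursively with neighbours, never crossing state
lines and never mixing urban with rural counties. The merge order — not
fixed by any external constraint — is deterministic: repeatedly take the
deficient unit with the smallest minimum sex-year population and merge it
with its smallest-population eligible neighbour, breaking ties by lowest
county id. Deaths and populations are summed; PM2.5 and covariates become
population-weighted means, with log-scale covariates aggregated on the
natural scale and re-logged (weighting belongs on the measurement scale).
Units with no eligible neighbour stay below threshold and are flagged
`unmergeable` rather than silently passed. Merged units are connected by
construction (each merge joins adjacent units), and merging is idempotent.

## 2. The four spatiotemporal Poisson models

Deaths are Poisson with mean `population × exp(η)`. The linear predictor
adds, per specification: a common intercept α₀ and linear year slope β₀
(year centred at the panel mid-year, 2007 for 1999–2015, which decorrelates
intercept and slope); a first-order random-walk ν over years for nonlinear
trend; the PM2.5 coefficient γ (log rate ratio per μg/m³); nine covariate
slopes θ; county random intercepts α_c and slopes β_c with intrinsic CAR
priors over the county adjacency graph; and iid Gaussian overdispersion ε
per county-year. Each of the 36 sex-age strata is fitted fully
independently.

Priors and identification:

- Fixed effects (α₀, β₀, γ, θ): zero-mean Gaussian, precision 0.001.
- Random-term precisions: logGamma(1, 0.001) on the log precision — i.e.
  τ ~ Gamma(1, 0.001), weakly informative.
- ν: sum-to-zero *and* orthogonal-to-year constraints, so the linear part
  of the trend belongs to β₀ and ν carries only curvature.
- α_c, β_c: intrinsic CAR (pairwise-difference prior over adjacency) with a
  sum-to-zero constraint per field, the standard disease-mapping choice;
  counties isolated in the graph (possible after merging) receive an
  exchangeable unit-precision diagonal entry, since the intrinsic prior is
  undefined at degree zero.
- PM and covariates are centred in the design; γ is unaffected.

A panel with constant PM2.5 has no identifying variation and raises a
degenerate-design error rather than returning a prior-driven answer.

## 3. Inference: empirical-Bayes Laplace approximation

The model is a latent Gaussian field with a Poisson likelihood — the family
that nested Laplace approximation methods target. The backend here is the
empirical-Bayes core of that strategy:

1. For candidate log-precisions θ, the latent posterior mode is found by
   damped Newton iteration. The overdispersion coordinates (one per
   observation, diagonal Hessian block) are eliminated exactly at each
   step, leaving a dense symmetric system over the structured coordinates
   (fixed effects + years + county fields; ≲ a few thousand), factorised
   by Cholesky. When the structured dimension is small (models without
   county fields) the design products run through dense BLAS.
2. The Laplace approximation of the log marginal likelihood — joint density
   at the mode minus half the log-determinant of the negative Hessian, with
   generalised (rank-aware) prior determinants for the intrinsic blocks —
   is maximised over the 2–4 log-precisions by Nelder-Mead, warm-starting
   each mode search from the previous one.
3. At the optimum, the reported posterior is the Gaussian approximation at
   the mode. Sum-to-zero/orthogonality constraints are imposed two ways
   that compose exactly: a soft quadratic penalty during optimisation
   (regularising the otherwise near-flat intercept-versus-field
   directions), and conditioning-by-kriging on the final Gaussian — the
   conditional law given Cu = 0 is invariant to the added prior mass along
   Cᵀ, so the reported constrained posterior is exact for the penalised
   Gaussian family.

Posterior uncertainty in the hyperparameters is *not* propagated into the
latent marginals; the credible intervals are empirical-Bayes intervals.
The calibration consequences are measured, not assumed: across 50 synthetic
replicates the 95% interval for γ covers the generating value at the
nominal rate at 100 counties, with mild undercoverage appearing at very
small panels (~40 counties). Convergence (Newton gradient norms) is checked
and surfaced as a flag; non-convergence is never silent. Reported rate
ratios are `exp(γ·Δ)` summarised over the Gaussian posterior of γ.

An MCMC backend was considered and rejected: the latent field has ~10³–10⁴
dimensions per stratum and 36 strata per model, and correctness here is
defined by parameter-recovery and calibration properties, which the Laplace
backend satisfies at a small fraction of the cost — it is also the method
family used in the analyses this pipeline is designed for.

## 4. Counterfactual attribution

Under the log-linear model, moving a county-year from PM_obs to PM_cf
rescales the death rate by `exp(γ·(PM_cf − PM_obs))`, so averted deaths are
`D_obs · (1 − exp(γ·(PM_cf − PM_obs)))` — the exact counterfactual-rate
form, not an attributable-fraction table. Two scenarios are built in: the
*floor* scenario (every county at the lowest observed concentration,
2.8 μg/m³, in the final year) and the *reduction* scenario (final-year
concentrations applied to first-year deaths). Observed deaths are treated
as fixed; uncertainty is propagated by applying each posterior draw of γ
(drawn independently across the independently fitted strata) cell-wise and
summing draws to county and national totals, so interval endpoints are
percentiles of draw-level totals. Negative averted deaths are valid output
(dirtier counterfactuals produce excess deaths).

## 5. Lifetables and life-expectancy loss

Abridged lifetables use `q = n·m/(1 + (n − a)·m)` with n = 5, a = 2.5 for
all intervals except the first (0–4), where a = 2.0 reflects the
concentration of early-childhood deaths (the age structure has no separate
infant interval). The open 85+ group is expanded by the Kannisto–Thatcher
method: a logistic hazard `μ(x) = a·e^{bx}/(1 + a·e^{bx})` is fitted by
logit-linear regression to the rates at ages 60–84 (five intervals — a
conventional old-age fitting window), then its level parameter is rescaled
(keeping the 1/year asymptote) so that the extension reproduces the
observed 85+ rate under its own stationary population; the extension spans
85–89 … 105–109 plus an open 110+ interval closed with `L = l/m`.
Non-increasing old-age rates defeat the logistic fit; the extension then
falls back, flagged, to a flat hazard at the open-interval rate.

Counterfactual life expectancy subtracts averted *cardiorespiratory* deaths
from *all-cause* deaths age by age, leaving the non-cardiorespiratory
stream untouched; a pathological draw implying more averted deaths than
observed cardiorespiratory deaths is clipped and counted. Because e₀ is
nonlinear in the rates, the loss (counterfactual minus observed e₀) is
computed per posterior draw and then summarised. County-level runs cap the
number of draws (default in the CLI: 150–500) since they build ~100× more
lifetables than the national run.

Accuracy: against a brute-force single-year lifetable with
piecewise-constant hazards, the abridged e₀ is within 0.5 years across
random hazard schedules, and a constant hazard of 0.02/year returns
e₀ = 50 ± 0.5.

## 6. Inequality analysis

County LE loss in the final year is regressed (OLS, conventional standard
errors; county-count weighting) on the county's PM2.5 excess over the
2.8 μg/m³ floor plus quintile indicators of a sociodemographic covariate,
quintiles being county-count quintiles with ties broken by county id. The
reported quantity is the Q5 indicator coefficient (Q1 reference) with its
95% confidence interval. Population weighting and robust (HC1) errors are
options, not defaults.

## 7. The synthetic generator

The generator produces panels with the statistical structure the models
assume, with known ground truth:

- **Geometry.** Counties tile a near-square grid (rook adjacency); states
  are contiguous column strips; urbanicity is "urban" for counties above
  median population. County populations are lognormal (median 10⁵, log-sd
  0.7 by default), split by a fixed age pyramid and an even sex ratio.
- **Exposure.** County PM2.5 follows a declining national mean (13.6 →
  8.0 μg/m³ over 1999–2015, the observed national trajectory) plus a
  spatially smoothed Gaussian anomaly (sd 3.0 μg/m³ in 1999) whose
  amplitude shrinks to 0.45 by 2015 — so reductions are largest where
  pollution is highest — plus small iid year noise (sd 0.3 μg/m³, a free
  parameter: within-county year-to-year variance net of trend is not
  identified by the emulated sources), truncated at a 2.8 μg/m³ floor.
- **Covariates.** Each covariate is a smooth spatial field plus year noise,
  scaled to plausible US county distributions. Confounded covariates mix in
  the standardised PM field at weight λ (default 0.3) after in-sample
  orthogonalisation of their idiosyncratic part, so the realised PM
  correlation equals λ exactly rather than ±0.15 around it. Optionally the
  county intercepts themselves correlate with the static PM anomaly
  (`county_intercept_corr_pm`), creating *unobserved* confounding that only
  county random intercepts can absorb — the mechanism that separates the
  Covariate from the Covariate-and-county model.
- **Deaths.** Cardiorespiratory counts are Poisson draws from the
  Covariate-and-county-style predictor (baseline log rates by sex-age at a
  reference exposure, a common trend of −1.2%/year, γ per stratum with a
  hump-shaped rate-ratio profile peaking at RR₁₀ ≈ 1.15 in middle age,
  covariate effects, spatial county intercepts of sd 0.10, overdispersion
  sd 0.05). Non-cardiorespiratory deaths are an independent Poisson stream
  with age-specific rates calibrated so the cardiorespiratory share of
  all-cause mortality lands in the ~40–50% range; all-cause = sum of the
  two streams, so the cause ordering holds cell by cell.
- **Reproducibility.** All randomness derives from one seed through a
  splittable generator: one stream for geography/exposure/covariates, one
  per sex-age stratum for deaths. The truth record regenerates the latent
  structure deterministically and reports the generating γ, θ, county
  effects and exact expected deaths per cell (including the lognormal
  overdispersion mean correction e^{σ²/2}), from which exact expected
  averted deaths follow for any counterfactual.

What the generator does *not* emulate: exposure measurement error (the
kriged concentration surface is taken as truth), cause-of-death
miscoding, county boundary changes over time, migration, and correlation
between the overdispersion of neighbouring strata. Passing tests therefore
demonstrate that the pipeline recovers the data-generating process it
assumes — not that the assumptions hold in real vital-registration data.

## 8. Problem sizes and numerical tolerances

Test-suite problem sizes are the package's own reduced study conditions:
parameter recovery at 400 counties × 17 years (one stratum); calibration
over 50 replicates at 100 counties; confounding-ordering at 150 counties;
the end-to-end truth check over 20 replicates at 100 counties; the
end-to-end null on a noise-free 150-county panel with large exposure — the
±0.005-year null band is tighter than the γ sampling noise induced by the
default overdispersion at any county count, so the clean null is only
meaningful without extra-Poisson noise, while the noisy regime is covered
by the calibration test. The acceptance script runs 300 counties with all
36 strata. Key tolerances: Newton relative-objective tolerance 1e-9–1e-11
with gradient checks; Nelder-Mead xatol 0.05 on log-precisions (γ is
insensitive to finer hyperparameter resolution); Kannisto–Thatcher level
calibration solved by Brent to 1e-14; lifetable oracle agreement 0.5 years;
attribution closed form exact to 1e-12.

## 9. Known limitations

- Empirical-Bayes intervals ignore hyperparameter uncertainty; at very
  small panels the γ intervals run slightly anti-conservative.
- The CAR fields use the intrinsic parameterisation with sum-to-zero
  constraints; proper-CAR or BYM parameterisations are not offered.
- Draw-level attribution with weakly-identified strata (few deaths) is
  biased negative by convexity (E[1 − e^{γΔ}] < 0 under symmetric γ draws
  centred at 0); the bias vanishes as stratum information grows and is a
  property of the estimand definition, not of the implementation.
- National intervals assume independence of γ across strata (they are
  fitted independently); any real-world cross-stratum correlation would
  widen them.
- The inequality regression ignores spatial autocorrelation of county LE
  losses; its confidence intervals are conventional OLS intervals.
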