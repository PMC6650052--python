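"""Spatiotemporal Poisson model: design construction, recovery against
the generator truth, and agreement with a maximum-likelihood oracle."""

import numpy as np
import pytest
import statsmodels.api as sm

from pm25life import (
    AGE_GROUPS,
    SEXES,
    DegenerateDesignError,
    GeneratorConfig,
    ModelSpec,
    SpatiotemporalPoissonRegression,
    build_design,
    fit,
    generate_panel,
)
from pm25life.panel import COVARIATE_COLUMNS


def _flat_gamma(value):
    return {(s, a): value for s in SEXES for a in AGE_GROUPS}


def test_model_spec_flags_match_the_four_named_models():
    assert ModelSpec.from_name("unadjusted") == ModelSpec("unadjusted", False, False, False)
    assert ModelSpec.from_name("covariate") == ModelSpec("covariate", True, False, False)
    assert ModelSpec.from_name("Covariate-and-county") == ModelSpec(
        "covariate_county", True, True, False
    )
    assert ModelSpec.from_name("restrictive") == ModelSpec("restrictive", True, True, True)
    with pytest.raises(ValueError):
        ModelSpec.from_name("bogus")


def test_build_design_centres_years_and_honours_spec(default_panel_small):
    _, panel = default_panel_small
    d = build_design(panel, "covariate", "F", "60-64")
    t = d["X"]["year_index"]
    assert t.min() == -8 and t.max() == 8  # 1999-2015 centred at 2007
    assert set(COVARIATE_COLUMNS) <= set(d["X"].columns)
    d0 = build_design(panel, "unadjusted", "F", "60-64")
    assert not (set(COVARIATE_COLUMNS) & set(d0["X"].columns))


def test_all_36_strata_produce_independent_design_tasks(default_panel_small):
    _, panel = default_panel_small
    tasks = [(s, a) for s in SEXES for a in AGE_GROUPS]
    assert len(tasks) == 36
    for s, a in tasks[:3] + tasks[-3:]:
        d = build_design(panel, "unadjusted", s, a)
        assert len(d["y"]) == len(panel.county_ids) * len(panel.years)


def test_constant_pm_raises_degenerate_design_error():
    from conftest import build_toy_panel

    panel = build_toy_panel([600_000] * 4, [7.0] * 4, edges=[(0, 1), (2, 3)])
    with pytest.raises(DegenerateDesignError):
        build_design(panel, "unadjusted", "F", "50-54")


def test_fixed_effects_posterior_matches_mle_poisson_oracle():
    """With all random effects off, the Gaussian-approximation posterior
    means must agree with maximum-likelihood Poisson regression."""
    cfg = GeneratorConfig(
        n_counties=225, seed=17, county_intercept_sd=0.0, overdispersion_sd=0.0,
        pop_median=3e5,
    )
    panel = generate_panel(cfg)
    d = build_design(panel, "covariate", "M", "70-74")
    est = SpatiotemporalPoissonRegression(
        model="covariate", include_time_rw=False, include_overdispersion=False
    ).fit(d)

    X = d["X"]
    cols = [np.ones(len(X)), X["year_index"], X["pm"] - X["pm"].mean()]
    for c in COVARIATE_COLUMNS:
        cols.append(X[c] - X[c].mean())
    design = np.column_stack(cols)
    glm = sm.GLM(
        d["y"], design, family=sm.families.Poisson(), offset=np.log(d["exposure"])
    ).fit()
    for i in range(len(est.coef_)):
        assert abs(est.coef_[i] - glm.params[i]) <= 3 * est.coef_sd_[i] + 1e-8


def test_covariate_model_recovers_generating_gamma():
    gamma = float(np.log(1.15) / 10)
    cfg = GeneratorConfig(
        n_counties=100, seed=31, county_intercept_sd=0.0,
        true_gamma_by_age_sex=_flat_gamma(gamma),
    )
    panel = generate_panel(cfg)
    est = fit(build_design(panel, "covariate", "F", "65-69"))
    assert est.converged_
    assert abs(est.gamma_ - gamma) <= 2.0 * est.gamma_sd_


def test_unadjusted_exceeds_covariate_under_positive_confounding():
    """A covariate correlated with PM and mortality inflates the
    unadjusted gamma; the MLE oracle on the same data shows the same
    ordering."""
    gamma = float(np.log(1.10) / 10)
    theta = np.zeros(9)
    theta[1], theta[6] = 0.02, 0.3  # poverty, smoking proxy raise mortality
    cfg = GeneratorConfig(
        n_counties=120, seed=23, true_gamma_by_age_sex=_flat_gamma(gamma),
        true_theta=theta, confounding_strength=0.6,
        confounded_covariates=("poverty_pct", "log_lung_cancer_rate"),
        county_intercept_sd=0.0,
    )
    panel = generate_panel(cfg)
    d_un = build_design(panel, "unadjusted", "M", "65-69")
    d_cov = build_design(panel, "covariate", "M", "65-69")
    g_un = fit(d_un).gamma_
    g_cov = fit(d_cov).gamma_
    assert g_un > g_cov

    def mle_gamma(d, with_covs):
        X = d["X"]
        cols = [np.ones(len(X)), X["year_index"], X["pm"]]
        if with_covs:
            cols += [X[c] for c in COVARIATE_COLUMNS]
        res = sm.GLM(d["y"], np.column_stack(cols),
                     family=sm.families.Poisson(),
                     offset=np.log(d["exposure"])).fit()
        return res.params[2]

    assert mle_gamma(d_un, False) > mle_gamma(d_cov, True)


def test_county_intercepts_are_harmless_without_county_heterogeneity():
    """Nesting: on a panel generated without county effects the
    Covariate-and-county gamma stays within one posterior sd of the
    Covariate gamma."""
    cfg = GeneratorConfig(n_counties=80, seed=41, county_intercept_sd=0.0)
    panel = generate_panel(cfg)
    g_cov = fit(build_design(panel, "covariate", "F", "70-74"))
    g_cc = fit(build_design(panel, "covariate_county", "F", "70-74"))
    assert abs(g_cc.gamma_ - g_cov.gamma_) <= max(g_cc.gamma_sd_, g_cov.gamma_sd_)


def test_restrictive_model_absorbs_shared_trend_association():
    """When mortality merely trends in parallel with the national PM
    decline, the Restrictive model concentrates gamma near zero."""
    cfg = GeneratorConfig(
        n_counties=100, seed=51, true_gamma_by_age_sex=_flat_gamma(0.0),
        trend_slope=-0.03,          # mimics a pollution-driven mortality trend
        pm_shrink_end=1.0,          # county anomalies persist
        county_intercept_sd=0.0,
    )
    panel = generate_panel(cfg)
    est = fit(build_design(panel, "restrictive", "M", "75-79"))
    assert abs(est.gamma_) <= 3.0 * est.gamma_sd_
    assert abs(est.gamma_) < 0.005


def test_rate_ratio_closed_forms():
    est = SpatiotemporalPoissonRegression()
    est.gamma_, est.gamma_sd_ = 0.0, 0.0
    assert est.rate_ratio(5.0)["median"] == pytest.approx(1.0)
    est.gamma_ = float(np.log(1.1) / 10)
    assert est.rate_ratio(10.0)["median"] == pytest.approx(1.1)
    rr1 = est.rate_ratio(1.0)
    assert rr1["median"] == pytest.approx(float(np.exp(est.gamma_)))


def test_posterior_summary_is_ordered_and_complete():
    cfg = GeneratorConfig(n_counties=36, seed=61)
    panel = generate_panel(cfg)
    est = fit(build_design(panel, "covariate_county", "F", "80-84"),
              optimizer_maxiter=30)
    s = est.summary_
    assert (s["q2.5"] <= s["q50"]).all() and (s["q50"] <= s["q97.5"]).all()
    assert set(s["term"][:3]) == {"alpha0", "beta0", "gamma"}
    assert sum(t.startswith("theta_") for t in s["term"]) == 9
    assert sum(t.startswith("nu_") for t in s["term"]) == 17
    # identifiability constraints hold
    assert est.nu_.sum() == pytest.approx(0.0, abs=1e-9)
    assert est.county_intercepts_.sum() == pytest.approx(0.0, abs=1e-8)
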