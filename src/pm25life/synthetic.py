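"""Synthetic county-panel generator with known ground truth.

Emulates the statistical structure of a US county mortality panel,
1999-2015: counties on a rectangular grid (rook adjacency) partitioned
into contiguous states; declining, spatially autocorrelated PM2.5
trajectories; nine time-varying covariates partially confounded with
PM2.5; and Poisson death counts whose log rates follow the same
log-linear model family the estimation stage fits

    log rate = baseline(sex, age) + slope * year + alpha_county
               + gamma * PM + sum_i theta_i * X_i + epsilon

so that every downstream stage (merging, model fitting, attribution,
lifetables, inequality) can be tested against an exact truth record.

Baseline log rates are interpreted at reference exposure ``pm_ref`` (the
midpoint of the start and end PM means) and at the covariate means, so
that realised death rates stay in the demographically plausible range
regardless of the configured effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .panel import AGE_GROUPS, COVARIATE_COLUMNS, SEXES, CountyPanel


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


# --------------------------------------------------------------------- #
# demographic defaults
# --------------------------------------------------------------------- #

#: all-cause death rates per person-year by 5-year age group (both sexes,
#: roughly the contemporary US schedule; the 0-4 value averages infant and
#: early-childhood mortality over the interval)
_ALLCAUSE_M = np.array(
    [0.0015, 0.00013, 0.00016, 0.0006, 0.0010, 0.0010, 0.0011, 0.0015,
     0.0020, 0.0031, 0.0048, 0.0070, 0.0105, 0.0160, 0.0250, 0.0400,
     0.0700, 0.1500]
)

#: cardiorespiratory share of all-cause mortality by age, rising with age
#: (overall share lands in the ~40-50% range typical of US county data)
_CARDIO_SHARE = np.array(
    [0.10, 0.10, 0.10, 0.10, 0.12, 0.14, 0.17, 0.20, 0.24, 0.28, 0.32,
     0.36, 0.40, 0.44, 0.48, 0.52, 0.55, 0.58]
)

#: male/female all-cause rate multipliers
_SEX_MULT = {"F": 0.85, "M": 1.25}

#: stationary-ish age pyramid (fractions of county population)
_AGE_PYRAMID = np.array(
    [0.066, 0.066, 0.067, 0.070, 0.070, 0.068, 0.066, 0.066, 0.072,
     0.072, 0.065, 0.057, 0.047, 0.037, 0.030, 0.026, 0.019, 0.016]
)
_AGE_PYRAMID = _AGE_PYRAMID / _AGE_PYRAMID.sum()

#: rate ratio per 10 ug/m3 by age group: hump-shaped, largest in middle
#: age and declining at the oldest ages
_RR10_BY_AGE = np.array(
    [1.05, 1.05, 1.05, 1.06, 1.07, 1.08, 1.10, 1.12, 1.14, 1.15, 1.15,
     1.14, 1.12, 1.10, 1.08, 1.06, 1.04, 1.03]
)


def default_true_gamma() -> dict[tuple[str, str], float]:
    """Age/sex map of log rate ratio per ug/m3 (same for both sexes)."""
    return {
        (sex, age): float(np.log(_RR10_BY_AGE[i]) / 10.0)
        for sex in SEXES
        for i, age in enumerate(AGE_GROUPS)
    }


def default_baseline_log_rates() -> dict[tuple[str, str], float]:
    """Cardiorespiratory log death rates at reference exposure."""
    return {
        (sex, age): float(np.log(_ALLCAUSE_M[i] * _CARDIO_SHARE[i] * _SEX_MULT[sex]))
        for sex in SEXES
        for i, age in enumerate(AGE_GROUPS)
    }


def default_noncardio_fraction() -> dict[str, float]:
    """Fraction of all-cause deaths that are non-cardiorespiratory, by age."""
    return {age: float(1.0 - _CARDIO_SHARE[i]) for i, age in enumerate(AGE_GROUPS)}


#: (mean, sd) of each covariate on its stored scale, loosely matched to the
#: observed distribution of US county characteristics
_COVARIATE_SCALES: dict[str, tuple[float, float]] = {
    "log_income": (np.log(24000.0), 0.25),
    "poverty_pct": (13.0, 4.0),
    "black_pct": (9.0, 10.0),
    "hs_grad_pct": (82.0, 6.0),
    "urban_pct": (57.0, 25.0),
    "unemployment_pct": (4.7, 1.5),
    "log_lung_cancer_rate": (np.log(60.0), 0.35),
    "temperature": (13.0, 4.0),
    "humidity": (69.0, 6.0),
}

#: covariates bounded to [0, 100] on the stored scale
_PCT_COVARIATES = ("poverty_pct", "black_pct", "hs_grad_pct", "urban_pct",
                   "unemployment_pct", "humidity")


def default_true_theta() -> np.ndarray:
    """Covariate log-rate effects on the stored covariate scales."""
    return np.array([-0.10, 0.005, 0.001, -0.003, 0.0002, 0.004,
                     0.15, 0.002, 0.001])


@dataclass
class GeneratorConfig:
    """Ground-truth configuration of the synthetic county panel.

    Attributes
    ----------
    n_counties, n_states : int
        Counties laid out row-major on a near-square grid; states are
        contiguous column strips of grid cells.
    years : tuple[int, int]
        Inclusive year range.
    true_gamma_by_age_sex : mapping (sex, age_group) -> float
        Generating log rate ratio per ug/m3 PM2.5.
    true_theta : array of 9 floats
        Generating covariate effects, in :data:`COVARIATE_COLUMNS` order.
    baseline_log_rates : mapping (sex, age_group) -> float
        Cardiorespiratory log death rate at reference exposure.
    trend_slope : float
        Common log-linear time trend per year (mortality decline).
    county_intercept_sd : float
        SD of spatially correlated county log-rate intercepts; 0 gives a
        panel with no unobserved county heterogeneity.
    county_intercept_corr_pm : float
        Correlation between the county intercepts and the static PM2.5
        anomaly — unobserved confounding that covariate adjustment
        cannot remove but county random intercepts absorb.
    pm_start_mean, pm_end_mean : float
        National mean PM2.5 (ug/m3) in the first and last year.
    pm_spatial_sd : float
        Cross-county SD of the PM2.5 field in the first year.
    pm_shrink_end : float
        Fraction of the spatial anomaly remaining in the last year
        (< 1 makes reductions largest where pollution is highest).
    pm_year_sd : float
        SD of iid year-to-year PM noise net of trend (not identified by
        the emulated data sources; free parameter).
    pm_floor : float
        Truncation floor for generated concentrations (ug/m3).
    confounding_strength : float
        Target correlation between PM2.5 and each confounded covariate.
    confounded_covariates : tuple of str
        Covariates receiving the PM-correlated component.
    overdispersion_sd : float
        SD of iid log-rate noise per county-year within each stratum.
    noncardio_fraction_by_age : mapping age_group -> float
        Non-cardiorespiratory fraction of all-cause deaths.
    pop_median, pop_log_sd : float
        Lognormal county population size distribution.
    seed : int
        Master seed; all randomness derives from it.
    """

    n_counties: int = 400
    n_states: int = 8
    years: tuple[int, int] = (1999, 2015)
    age_groups: tuple[str, ...] = AGE_GROUPS
    true_gamma_by_age_sex: Mapping[tuple[str, str], float] = field(
        default_factory=default_true_gamma
    )
    true_theta: np.ndarray = field(default_factory=default_true_theta)
    baseline_log_rates: Mapping[tuple[str, str], float] = field(
        default_factory=default_baseline_log_rates
    )
    trend_slope: float = -0.012
    county_intercept_sd: float = 0.10
    county_intercept_corr_pm: float = 0.0
    pm_start_mean: float = 13.6
    pm_end_mean: float = 8.0
    pm_spatial_sd: float = 3.0
    pm_shrink_end: float = 0.45
    pm_year_sd: float = 0.3
    pm_floor: float = 2.8
    confounding_strength: float = 0.3
    confounded_covariates: tuple[str, ...] = (
        "log_income", "poverty_pct", "log_lung_cancer_rate", "urban_pct"
    )
    overdispersion_sd: float = 0.05
    noncardio_fraction_by_age: Mapping[str, float] = field(
        default_factory=default_noncardio_fraction
    )
    pop_median: float = 1.0e5
    pop_log_sd: float = 0.7
    seed: int = 0

    # ------------------------------------------------------------------ #
    def __post_init__(self) -> None:
        if self.n_counties < 1:
            raise ConfigurationError("n_counties must be positive")
        if not (1 <= self.n_states <= self.n_counties):
            raise ConfigurationError("n_states must be in [1, n_counties]")
        if self.years[1] < self.years[0]:
            raise ConfigurationError("years range is empty")
        if tuple(self.age_groups) != AGE_GROUPS:
            raise ConfigurationError("exactly the 18 canonical age groups are required")
        if self.pm_floor < 0:
            raise ConfigurationError("pm_floor must be >= 0")
        if self.pop_median <= 0:
            raise ConfigurationError("pop_median must be positive")
        theta = np.asarray(self.true_theta, dtype=float)
        if theta.shape != (9,):
            raise ConfigurationError("true_theta must have 9 entries")
        object.__setattr__(self, "true_theta", theta)
        if not (-1.0 < self.confounding_strength < 1.0):
            raise ConfigurationError("confounding_strength must be in (-1, 1)")
        if not (-1.0 <= self.county_intercept_corr_pm <= 1.0):
            raise ConfigurationError("county_intercept_corr_pm must be in [-1, 1]")
        missing = [
            (s, a) for s in SEXES for a in AGE_GROUPS
            if (s, a) not in self.true_gamma_by_age_sex
            or (s, a) not in self.baseline_log_rates
        ]
        if missing:
            raise ConfigurationError(f"missing stratum parameters: {missing[:3]}...")

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) of the county grid; the last row may be partial."""
        ncols = int(np.ceil(np.sqrt(self.n_counties)))
        nrows = int(np.ceil(self.n_counties / ncols))
        return nrows, ncols

    @property
    def year_list(self) -> np.ndarray:
        return np.arange(self.years[0], self.years[1] + 1)

    @property
    def pm_ref(self) -> float:
        """Reference exposure at which baseline log rates apply."""
        return 0.5 * (self.pm_start_mean + self.pm_end_mean)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        """Load a config from a declarative key-value file.

        Scalar fields only; mapping-valued fields keep their defaults
        unless given as ``{"SEX age": value}`` entries.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key, value in raw.items():
            if key == "years":
                kwargs["years"] = tuple(value)
            elif key == "true_gamma_by_age_sex":
                kwargs[key] = {
                    tuple(k.split(" ", 1)): float(v) for k, v in value.items()
                }
            elif key == "true_theta":
                kwargs[key] = np.asarray(value, dtype=float)
            elif key == "confounded_covariates":
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


# --------------------------------------------------------------------- #
# generation
# --------------------------------------------------------------------- #

def _spatial_field(rng: np.random.Generator, nrows: int, ncols: int,
                   n: int, smooth: float = 1.5) -> np.ndarray:
    """Unit-variance Gaussian field with short-range grid correlation."""
    z = rng.standard_normal((nrows, ncols))
    z = gaussian_filter(z, sigma=smooth, mode="nearest")
    z = z.ravel()[:n]
    sd = z.std()
    if sd < 1e-12:  # degenerate only for 1-county grids
        return np.zeros(n)
    return (z - z.mean()) / sd


def _grid_geography(config: GeneratorConfig) -> tuple[pd.DataFrame, list[tuple[int, int]]]:
    """Counties on a grid: rook adjacency, contiguous column-strip states."""
    nrows, ncols = config.grid_shape
    n = config.n_counties
    ids = np.arange(n)
    rows, cols = ids // ncols, ids % ncols
    # states: contiguous strips of columns with near-equal cell counts
    state = (cols * config.n_states) // ncols
    edges: list[tuple[int, int]] = []
    for i in ids:
        r, c = rows[i], cols[i]
        if c + 1 < ncols and i + 1 < n and rows[i + 1] == r:
            edges.append((int(i), int(i + 1)))
        if i + ncols < n:
            edges.append((int(i), int(i + ncols)))
    counties = pd.DataFrame({"state": state.astype(int)}, index=pd.Index(ids, name="county"))
    return counties, edges


def _generate_latents(config: GeneratorConfig) -> dict:
    """Deterministic latent structure shared by panel and truth record.

    Draws geography, populations, the PM2.5 field, covariates and county
    intercepts from the geography stream of the seed, leaving the
    per-stratum death streams untouched.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(1 + 2 * len(AGE_GROUPS))
    geo_rng = np.random.default_rng(children[0])

    nrows, ncols = config.grid_shape
    n = config.n_counties
    years = config.year_list
    T = len(years)
    counties, edges = _grid_geography(config)

    # populations: lognormal county sizes, fixed pyramid, even sex split
    pop_total = config.pop_median * np.exp(
        config.pop_log_sd * geo_rng.standard_normal(n)
    )
    counties["urbanicity"] = np.where(
        pop_total > np.median(pop_total), "urban", "rural"
    )

    # PM2.5: declining national mean, shrinking spatial anomaly, year noise
    anomaly = _spatial_field(geo_rng, nrows, ncols, n) * config.pm_spatial_sd
    # centre the anomaly in the population weighting so the national
    # population-weighted mean tracks the configured trajectory
    w = pop_total / pop_total.sum()
    anomaly = anomaly - float(anomaly @ w)
    frac = (years - years[0]) / max(T - 1, 1)
    mean_t = config.pm_start_mean + frac * (config.pm_end_mean - config.pm_start_mean)
    shrink_t = 1.0 + frac * (config.pm_shrink_end - 1.0)
    pm = (mean_t[None, :]
          + anomaly[:, None] * shrink_t[None, :]
          + config.pm_year_sd * geo_rng.standard_normal((n, T)))
    pm = np.maximum(pm, config.pm_floor)

    # covariates: PM-correlated component for the confounded ones
    pm_z = (pm - pm.mean()) / pm.std()
    lam = config.confounding_strength
    x_means = np.empty(9)
    covariates = {}
    for j, name in enumerate(COVARIATE_COLUMNS):
        mu, sd = _COVARIATE_SCALES[name]
        own = (_spatial_field(geo_rng, nrows, ncols, n)[:, None]
               + 0.15 * geo_rng.standard_normal((n, T)))
        own = (own - own.mean()) / own.std()
        if name in config.confounded_covariates:
            # orthogonalise the idiosyncratic part in-sample so the
            # realised PM correlation equals the configured strength
            # (both fields are spatially smooth, so raw mixing would
            # leave a large chance component in the correlation)
            own = own - (own * pm_z).mean() * pm_z
            own = (own - own.mean()) / own.std()
            z = lam * pm_z + np.sqrt(1.0 - lam ** 2) * own
        else:
            z = own
        x = mu + sd * z
        if name in _PCT_COVARIATES:
            x = np.clip(x, 0.0, 100.0)
        x_means[j] = x.mean()
        covariates[name] = x

    # county intercepts: spatially correlated log-rate shifts, optionally
    # correlated with the static PM anomaly (unobserved confounding that
    # only county random intercepts can absorb)
    if config.county_intercept_sd > 0:
        own_a = _spatial_field(geo_rng, nrows, ncols, n)
        rho = config.county_intercept_corr_pm
        if rho != 0.0 and anomaly.std() > 0:
            a_z = (anomaly - anomaly.mean()) / anomaly.std()
            own_a = own_a - (own_a * a_z).mean() * a_z
            sd = own_a.std()
            if sd > 1e-12:
                own_a = (own_a - own_a.mean()) / sd
            alpha_z = rho * a_z + np.sqrt(1.0 - rho**2) * own_a
        else:
            alpha_z = own_a
        alpha_c = alpha_z * config.county_intercept_sd
    else:
        alpha_c = np.zeros(n)

    X = np.stack([covariates[name] for name in COVARIATE_COLUMNS], axis=-1)
    theta_term = (X - x_means[None, None, :]) @ config.true_theta
    return {
        "counties": counties,
        "edges": edges,
        "pop_total": pop_total,
        "pm": pm,
        "covariates": covariates,
        "alpha_c": alpha_c,
        "theta_term": theta_term,
        "death_streams": children[1:],
    }


def generate_panel(config: GeneratorConfig) -> CountyPanel:
    """Draw a complete synthetic county panel from the configuration.

    Randomness is split off a single :class:`numpy.random.SeedSequence`:
    one stream for geography, exposure and covariates, then one stream
    per (sex, age group) stratum for death counts, so panels are
    reproducible stratum by stratum.
    """
    latents = _generate_latents(config)
    n = config.n_counties
    years = config.year_list
    T = len(years)
    counties, edges = latents["counties"], latents["edges"]
    pop_total, pm = latents["pop_total"], latents["pm"]
    alpha_c, theta_term = latents["alpha_c"], latents["theta_term"]

    exposure_rows = {
        "county": np.repeat(np.arange(n), T),
        "year": np.tile(years, n),
        "pm": pm.ravel(),
    }
    for name in COVARIATE_COLUMNS:
        exposure_rows[name] = latents["covariates"][name].ravel()
    exposure = pd.DataFrame(exposure_rows)

    t_centred = years - years.mean()
    demog_frames = []
    stream = 0
    for sex in SEXES:
        for i, age in enumerate(AGE_GROUPS):
            rng = np.random.default_rng(latents["death_streams"][stream])
            stream += 1
            pop = np.maximum(
                np.rint(pop_total * 0.5 * _AGE_PYRAMID[i]), 1.0
            )
            gamma = config.true_gamma_by_age_sex[(sex, age)]
            base = config.baseline_log_rates[(sex, age)]
            eps = config.overdispersion_sd * rng.standard_normal((n, T))
            eta = (base
                   + config.trend_slope * t_centred[None, :]
                   + alpha_c[:, None]
                   + gamma * (pm - config.pm_ref)
                   + theta_term
                   + eps)
            mu_cardio = pop[:, None] * np.exp(eta)
            cardio = rng.poisson(mu_cardio)
            f_nc = config.noncardio_fraction_by_age[age]
            # independent non-cardiorespiratory stream with matching share
            mu_nc = pop[:, None] * np.exp(base) * f_nc / max(1.0 - f_nc, 1e-12)
            noncardio = rng.poisson(np.broadcast_to(mu_nc, (n, T)))
            allcause = cardio + noncardio
            # cap at population (only binds in tiny counties)
            allcause = np.minimum(allcause, pop[:, None].astype(int))
            cardio = np.minimum(cardio, allcause)
            demog_frames.append(pd.DataFrame({
                "county": np.repeat(np.arange(n), T),
                "year": np.tile(years, n),
                "sex": sex,
                "age_group": age,
                "population": np.repeat(pop.astype(int), T),
                "cardio_deaths": cardio.ravel(),
                "allcause_deaths": allcause.ravel(),
            }))
    demography = pd.concat(demog_frames, ignore_index=True)

    panel = CountyPanel(
        counties=counties[["state", "urbanicity"]],
        exposure=exposure,
        demography=demography,
        adjacency=edges,
    )
    return panel.validate()


def generate_truth_record(config: GeneratorConfig, panel: CountyPanel) -> dict:
    """Ground-truth quantities for parameter-recovery tests.

    Returns a dict with the generating ``gamma`` map, ``theta`` vector,
    spatial ``county_effects``, and ``expected_cardio_deaths`` — the
    Poisson means ``population * exp(linear predictor)`` per
    (county, year, sex, age) cell, excluding the realised overdispersion
    noise (i.e. the marginal mean up to the lognormal correction, which
    is applied as exp(sd^2/2)).

    Raises
    ------
    ValueError
        If the panel's shape does not match the configuration.
    """
    if len(panel.county_ids) != config.n_counties or len(panel.years) != len(
        config.year_list
    ):
        raise ValueError("panel does not match configuration")
    n, T = config.n_counties, len(config.year_list)
    years = config.year_list
    t_centred = years - years.mean()
    latents = _generate_latents(config)
    pm = latents["pm"]
    if not np.allclose(pm, panel.pm_wide().to_numpy(), atol=1e-9):
        raise ValueError("panel was not generated from this configuration")
    alpha_c = latents["alpha_c"]
    theta_term = latents["theta_term"]

    lognorm_corr = np.exp(0.5 * config.overdispersion_sd ** 2)
    frames = []
    for sex in SEXES:
        for i, age in enumerate(AGE_GROUPS):
            gamma = config.true_gamma_by_age_sex[(sex, age)]
            base = config.baseline_log_rates[(sex, age)]
            pop = (
                panel.demography.query("sex == @sex and age_group == @age")
                .pivot(index="county", columns="year", values="population")
                .to_numpy()
                .astype(float)
            )
            eta = (base + config.trend_slope * t_centred[None, :]
                   + alpha_c[:, None]
                   + gamma * (pm - config.pm_ref) + theta_term)
            frames.append(pd.DataFrame({
                "county": np.repeat(np.arange(n), T),
                "year": np.tile(years, n),
                "sex": sex,
                "age_group": age,
                "expected_cardio_deaths": (pop * np.exp(eta) * lognorm_corr).ravel(),
            }))
    return {
        "gamma": dict(config.true_gamma_by_age_sex),
        "theta": np.asarray(config.true_theta).copy(),
        "county_effects": alpha_c,
        "expected_cardio_deaths": pd.concat(frames, ignore_index=True),
    }


def expected_averted_deaths(truth: dict, panel: CountyPanel,
                            pm_counterfactual, year: int | None = None) -> float:
    """Exact expected averted deaths under a counterfactual PM field.

    Computed from the generating rates: ``sum E[D] * (1 - exp(gamma * (pm_cf
    - pm_obs)))`` over all (county, year, sex, age) cells in scope.

    Parameters
    ----------
    truth : dict
        Output of :func:`generate_truth_record`.
    pm_counterfactual : float or mapping county -> float
        Counterfactual concentration(s), ug/m3.
    year : int, optional
        Restrict to one evaluation year (default: all years).
    """
    exp_d = truth["expected_cardio_deaths"].merge(
        panel.exposure[["county", "year", "pm"]], on=["county", "year"]
    )
    if year is not None:
        exp_d = exp_d[exp_d["year"] == year]
    if np.isscalar(pm_counterfactual):
        pm_cf = np.full(len(exp_d), float(pm_counterfactual))
    else:
        pm_cf = exp_d["county"].map(pm_counterfactual).to_numpy(dtype=float)
    gamma = np.array([
        truth["gamma"][(s, a)] for s, a in zip(exp_d["sex"], exp_d["age_group"])
    ])
    delta = pm_cf - exp_d["pm"].to_numpy()
    return float(np.sum(exp_d["expected_cardio_deaths"].to_numpy()
                        * (1.0 - np.exp(gamma * delta))))
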