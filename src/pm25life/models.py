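"""Bayesian spatiotemporal Poisson models of county death rates on PM2.5.

Four nested specifications relate the log cardiorespiratory death rate of
a county-year to its annual PM2.5 concentration:

=====================  ============================================================
Unadjusted             alpha0 + beta0*year + nu_year + gamma*PM + eps
Covariate              ... + sum_i theta_i X_i
Covariate-and-county   ... + alpha_county (intrinsic CAR)
Restrictive            ... + alpha_county + beta_county*year (both intrinsic CAR)
=====================  ============================================================

with ``deaths ~ Poisson(rate * population)``, a first-order random walk
``nu_year`` for nonlinear time trends, iid Gaussian overdispersion
``eps`` per county-year, and logGamma(1, 0.001) hyperpriors on the log
precisions of all random terms. ``gamma`` is the log rate ratio per
1 ug/m3 PM2.5. Each model is fitted separately by sex and 5-year age
group (18 groups, birth to 85+), i.e. 36 independent tasks.

The estimator follows the scikit-learn protocol: construct with the
model choice and inference options, ``fit(X, y, exposure=...)`` on a
design frame, read ``gamma_`` / ``gamma_sd_`` / ``summary_`` afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from ._laplace import LatentBlock, fit_latent_gaussian_poisson
from .panel import COVARIATE_COLUMNS, CountyPanel

__all__ = [
    "ModelSpec",
    "MODEL_NAMES",
    "DegenerateDesignError",
    "build_design",
    "SpatiotemporalPoissonRegression",
    "fit",
    "rate_ratio",
    "fit_all_strata",
]


class DegenerateDesignError(ValueError):
    """The design carries no identifying variation (e.g. constant PM2.5)."""


MODEL_NAMES = ("unadjusted", "covariate", "covariate_county", "restrictive")

_ALIASES = {
    "unadjusted": "unadjusted",
    "covariate": "covariate",
    "covariate-and-county": "covariate_county",
    "covariate_county": "covariate_county",
    "restrictive": "restrictive",
}


@dataclass(frozen=True)
class ModelSpec:
    """Flags of one of the four model specifications."""

    name: str
    include_covariates: bool
    include_county_intercepts: bool
    include_county_slopes: bool

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        key = _ALIASES.get(name.lower().replace(" ", "_"))
        if key is None:
            raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
        flags = {
            "unadjusted": (False, False, False),
            "covariate": (True, False, False),
            "covariate_county": (True, True, False),
            "restrictive": (True, True, True),
        }[key]
        return cls(key, *flags)


# --------------------------------------------------------------------- #
# structure matrices
# --------------------------------------------------------------------- #

def rw1_structure(T: int) -> tuple[sp.csc_matrix, int]:
    """First-order random-walk structure matrix (rank T-1)."""
    D = sp.diags([np.ones(T - 1), -np.ones(T - 1)], [0, 1], shape=(T - 1, T))
    return (D.T @ D).tocsc(), T - 1


def icar_structure(graph: nx.Graph, order: list[int]) -> tuple[sp.csc_matrix, int]:
    """Intrinsic CAR structure (graph Laplacian) over counties in ``order``.

    Isolated counties (no neighbours, e.g. flagged unmergeable islands)
    receive an exchangeable unit-precision diagonal entry instead of the
    undefined intrinsic prior.
    """
    index = {c: i for i, c in enumerate(order)}
    n = len(order)
    rows, cols, vals = [], [], []
    deg = np.zeros(n)
    for a, b in graph.edges():
        i, j = index[a], index[b]
        deg[i] += 1
        deg[j] += 1
        rows += [i, j]
        cols += [j, i]
        vals += [-1.0, -1.0]
    diag = np.where(deg > 0, deg, 1.0)  # islands: iid N(0, 1/tau)
    L = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc() + sp.diags(diag).tocsc()
    rank = sum(
        (len(comp) - 1) if len(comp) > 1 else 1
        for comp in nx.connected_components(graph)
    )
    return L.tocsc(), rank


# --------------------------------------------------------------------- #
# design construction
# --------------------------------------------------------------------- #

def build_design(panel: CountyPanel, spec: ModelSpec | str, sex: str,
                 age_group: str) -> dict:
    """Assemble model inputs for one (model, sex, age group) task.

    Returns a dict with the response counts ``y``, population offsets
    ``exposure``, the design frame ``X`` (county, year, centred year
    index, PM, covariates), the county order and adjacency graph, and the
    model spec. Covariates and PM are passed through uncentred; the
    estimator centres internally.
    """
    if isinstance(spec, str):
        spec = ModelSpec.from_name(spec)
    d = panel.demography
    sub = d[(d["sex"] == sex) & (d["age_group"] == age_group)]
    if sub.empty:
        raise ValueError(f"no rows for sex={sex!r}, age_group={age_group!r}")
    merged = sub.merge(panel.exposure, on=["county", "year"], how="left")
    if merged[["pm", *COVARIATE_COLUMNS]].isna().any().any():
        raise ValueError("missing exposure or covariate rows for this stratum")
    merged = merged.sort_values(["county", "year"]).reset_index(drop=True)
    if (merged["population"] <= 0).any():
        raise ValueError(
            "zero-population cell; run the small-county merge step first"
        )
    if float(merged["pm"].std()) < 1e-10:
        raise DegenerateDesignError("PM2.5 is constant across the panel")
    cols = ["county", "year", "pm"] + (
        list(COVARIATE_COLUMNS) if spec.include_covariates else []
    )
    X = merged[cols].copy()
    X["year_index"] = X["year"] - float(np.mean(np.unique(X["year"])))
    return {
        "spec": spec,
        "sex": sex,
        "age_group": age_group,
        "X": X,
        "y": merged["cardio_deaths"].to_numpy(dtype=float),
        "exposure": merged["population"].to_numpy(dtype=float),
        "county_order": list(np.sort(merged["county"].unique())),
        "graph": panel.graph(),
    }


# --------------------------------------------------------------------- #
# estimator
# --------------------------------------------------------------------- #

class SpatiotemporalPoissonRegression(BaseEstimator):
    """Spatiotemporal Poisson regression of death counts on PM2.5.

    Parameters
    ----------
    model : str
        One of ``"unadjusted"``, ``"covariate"``, ``"covariate_county"``
        (the main specification), ``"restrictive"``.
    adjacency : list of (int, int), optional
        County adjacency edges; required by the CAR models unless the
        design dict from :func:`build_design` carries a graph.
    include_time_rw, include_overdispersion : bool
        Switch off the RW1 year effects / iid overdispersion to obtain a
        fixed-effects-only model (used for oracle comparisons against
        maximum-likelihood Poisson regression).
    fixed_effect_precision : float
        Gaussian prior precision on intercept, slope, gamma and thetas.
    hyper_a, hyper_b : float
        logGamma hyperprior on log random-effect precisions.
    optimizer_maxiter, optimizer_xatol : int, float
        Budget of the hyperparameter (log-precision) optimisation.
    init_log_precisions : array, optional
        Warm start for the log precisions.
    seed : int
        Seed for posterior draws of gamma.

    Attributes
    ----------
    gamma_ : float
        Posterior mean log rate ratio per 1 ug/m3.
    gamma_sd_ : float
        Posterior sd of gamma.
    coef_ : ndarray
        Posterior means of the fixed effects (intercept, year slope,
        gamma, covariate thetas).
    nu_ : ndarray
        Nonlinear year effects (sum-to-zero, orthogonal to the linear
        year term).
    county_intercepts_, county_slopes_ : pandas.Series or None
        CAR fields, indexed by county id.
    epsilon_ : ndarray
        Overdispersion field per design row.
    precisions_ : dict
        Posterior-mode precisions of the random terms.
    summary_ : pandas.DataFrame
        term, mean, sd, q2.5, q50, q97.5 for fixed effects and nu.
    converged_ : bool
    """

    def __init__(
        self,
        model: str = "covariate_county",
        adjacency: list[tuple[int, int]] | None = None,
        include_time_rw: bool = True,
        include_overdispersion: bool = True,
        fixed_effect_precision: float = 0.001,
        hyper_a: float = 1.0,
        hyper_b: float = 0.001,
        optimizer_maxiter: int = 80,
        optimizer_xatol: float = 0.05,
        newton_maxiter: int = 60,
        init_log_precisions=None,
        n_draws: int = 1000,
        seed: int = 0,
    ):
        self.model = model
        self.adjacency = adjacency
        self.include_time_rw = include_time_rw
        self.include_overdispersion = include_overdispersion
        self.fixed_effect_precision = fixed_effect_precision
        self.hyper_a = hyper_a
        self.hyper_b = hyper_b
        self.optimizer_maxiter = optimizer_maxiter
        self.optimizer_xatol = optimizer_xatol
        self.newton_maxiter = newton_maxiter
        self.init_log_precisions = init_log_precisions
        self.n_draws = n_draws
        self.seed = seed

    # -------------------------------------------------------------- #
    def fit(self, X, y=None, exposure=None, graph=None, sex=None, age_group=None):
        """Fit the model.

        ``X`` may be the dict returned by :func:`build_design`, in which
        case the remaining arguments are ignored; or a design DataFrame
        with columns ``county``, ``year``, ``pm`` (and the nine
        covariates for adjusted models), with ``y`` the death counts and
        ``exposure`` the populations.
        """
        if isinstance(X, dict):
            design = X
        else:
            spec = ModelSpec.from_name(self.model)
            X = pd.DataFrame(X).copy()
            if "year_index" not in X:
                X["year_index"] = X["year"] - float(np.mean(np.unique(X["year"])))
            g = graph
            if g is None:
                g = nx.Graph()
                g.add_nodes_from(np.unique(X["county"]))
                if self.adjacency:
                    g.add_edges_from(self.adjacency)
            design = {
                "spec": spec,
                "sex": sex,
                "age_group": age_group,
                "X": X,
                "y": np.asarray(y, dtype=float),
                "exposure": np.asarray(exposure, dtype=float),
                "county_order": list(np.sort(pd.unique(X["county"]))),
                "graph": g,
            }
        spec = design["spec"]
        if isinstance(spec, str):
            spec = ModelSpec.from_name(spec)
        if spec.name != ModelSpec.from_name(self.model).name:
            spec = ModelSpec.from_name(self.model)
        Xf = design["X"]
        yv = np.asarray(design["y"], dtype=float)
        ev = np.asarray(design["exposure"], dtype=float)
        if np.any(yv < 0):
            raise ValueError("negative death counts")
        if float(np.std(Xf["pm"])) < 1e-10:
            raise DegenerateDesignError("PM2.5 is constant across the panel")

        n = len(Xf)
        t = Xf["year_index"].to_numpy(dtype=float)
        years = np.sort(Xf["year"].unique())
        t_levels = years - float(np.mean(years))
        T = len(years)
        year_pos = pd.Categorical(Xf["year"], categories=years).codes
        county_order = design["county_order"]
        county_pos = pd.Categorical(Xf["county"], categories=county_order).codes
        C = len(county_order)

        # fixed effects, centred for conditioning; gamma unaffected
        pm = Xf["pm"].to_numpy(dtype=float)
        self.pm_center_ = float(pm.mean())
        cols = [np.ones(n), t, pm - self.pm_center_]
        names = ["alpha0", "beta0", "gamma"]
        self.covariate_centers_ = {}
        if spec.include_covariates:
            for c in COVARIATE_COLUMNS:
                v = Xf[c].to_numpy(dtype=float)
                self.covariate_centers_[c] = float(v.mean())
                cols.append(v - v.mean())
                names.append(f"theta_{c}")
        F = np.column_stack(cols)

        blocks: list[LatentBlock] = []
        ones = np.ones(n)
        if self.include_time_rw and T >= 3:
            R, rank = rw1_structure(T)
            Z = sp.coo_matrix((ones, (np.arange(n), year_pos)), shape=(n, T)).tocsr()
            cons = np.vstack([np.ones(T), t_levels])  # sum zero, orthogonal to year
            blocks.append(LatentBlock("nu", Z, R, rank, cons))
        graph_c = design["graph"].subgraph(county_order).copy()
        if spec.include_county_intercepts:
            R, rank = icar_structure(graph_c, county_order)
            Z = sp.coo_matrix((ones, (np.arange(n), county_pos)), shape=(n, C)).tocsr()
            blocks.append(LatentBlock("alpha", Z, R, rank, np.ones((1, C))))
        if spec.include_county_slopes:
            R, rank = icar_structure(graph_c, county_order)
            Z = sp.coo_matrix((t, (np.arange(n), county_pos)), shape=(n, C)).tocsr()
            blocks.append(LatentBlock("beta", Z, R, rank, np.ones((1, C))))
        if self.include_overdispersion:
            # iid overdispersion, eliminated analytically by the backend
            blocks.append(
                LatentBlock("eps", None, sp.identity(n, format="csc"), n, None)
            )

        init = self.init_log_precisions
        if init is not None:
            init = np.asarray(init, dtype=float)
            if init.shape != (len(blocks),):
                raise ValueError(
                    f"init_log_precisions must have {len(blocks)} entries"
                )
        res = fit_latent_gaussian_poisson(
            yv, ev, F, names, blocks,
            fe_prec=self.fixed_effect_precision,
            hyper_a=self.hyper_a, hyper_b=self.hyper_b,
            init_log_precisions=init,
            optimizer_maxiter=self.optimizer_maxiter,
            optimizer_xatol=self.optimizer_xatol,
            newton_maxiter=self.newton_maxiter,
        )

        self.spec_ = spec
        self.sex_ = design.get("sex")
        self.age_group_ = design.get("age_group")
        self.result_ = res
        self.coef_names_ = names
        fixed = res.mean[res.slices["fixed"]]
        self.coef_ = fixed
        self.coef_sd_ = res.marginal_sd[res.slices["fixed"]]
        self.alpha0_ = float(fixed[0])
        self.beta0_ = float(fixed[1])
        self.gamma_ = float(fixed[2])
        self.gamma_sd_ = float(self.coef_sd_[2])
        self.theta_ = fixed[3:].copy() if spec.include_covariates else None
        self.nu_ = (res.mean[res.slices["nu"]].copy() if "nu" in res.slices
                    else np.zeros(T))
        self.years_ = years
        self.county_order_ = county_order
        self.county_intercepts_ = (
            pd.Series(res.mean[res.slices["alpha"]], index=county_order)
            if "alpha" in res.slices else None
        )
        self.county_slopes_ = (
            pd.Series(res.mean[res.slices["beta"]], index=county_order)
            if "beta" in res.slices else None
        )
        self.epsilon_ = (res.mean[res.slices["eps"]].copy()
                         if "eps" in res.slices else np.zeros(n))
        self.precisions_ = {k: float(np.exp(v)) for k, v in res.log_precisions.items()}
        self.log_marginal_likelihood_ = res.log_marginal_likelihood
        self.converged_ = res.converged
        self.convergence_message_ = res.message

        rows = []
        z = 1.959963984540054
        for i, nm in enumerate(names):
            m, s = fixed[i], self.coef_sd_[i]
            rows.append((nm, m, s, m - z * s, m, m + z * s))
        if "nu" in res.slices:
            sl = res.slices["nu"]
            for j, yr in enumerate(years):
                m = res.mean[sl][j]
                s = res.marginal_sd[sl][j]
                rows.append((f"nu_{yr}", m, s, m - z * s, m, m + z * s))
        self.summary_ = pd.DataFrame(
            rows, columns=["term", "mean", "sd", "q2.5", "q50", "q97.5"]
        )
        return self

    # -------------------------------------------------------------- #
    def _check_fitted(self):
        if not hasattr(self, "gamma_"):
            raise RuntimeError("model is not fitted")

    def predict(self, X, exposure=None):
        """Expected death counts at the posterior mean of the latent field.

        ``X`` must carry ``county``, ``year``, ``pm`` (and covariates for
        adjusted models); counties/years unseen at fit time contribute no
        random effects.
        """
        self._check_fitted()
        X = pd.DataFrame(X)
        t = X["year"].to_numpy(dtype=float) - float(np.mean(self.years_))
        eta = self.alpha0_ + self.beta0_ * t + self.gamma_ * (
            X["pm"].to_numpy(dtype=float) - self.pm_center_
        )
        if self.spec_.include_covariates:
            for j, c in enumerate(COVARIATE_COLUMNS):
                eta += self.theta_[j] * (
                    X[c].to_numpy(dtype=float) - self.covariate_centers_[c]
                )
        nu_map = dict(zip(self.years_, self.nu_))
        eta += np.array([nu_map.get(yr, 0.0) for yr in X["year"]])
        if self.county_intercepts_ is not None:
            eta += self.county_intercepts_.reindex(X["county"]).fillna(0.0).to_numpy()
        if self.county_slopes_ is not None:
            eta += self.county_slopes_.reindex(X["county"]).fillna(0.0).to_numpy() * t
        rate = np.exp(eta)
        if exposure is None:
            return rate
        return np.asarray(exposure, dtype=float) * rate

    def sample_gamma(self, n_draws: int | None = None,
                     rng: np.random.Generator | None = None) -> np.ndarray:
        """Draws of gamma from its Gaussian posterior marginal."""
        self._check_fitted()
        if rng is None:
            rng = np.random.default_rng(self.seed)
        n = n_draws if n_draws is not None else self.n_draws
        return rng.normal(self.gamma_, self.gamma_sd_, size=n)

    def rate_ratio(self, delta_pm: float = 1.0) -> dict:
        """Posterior summary of the rate ratio exp(gamma * delta_pm)."""
        self._check_fitted()
        z = 1.959963984540054
        m, s = self.gamma_ * delta_pm, self.gamma_sd_ * abs(delta_pm)
        return {
            "delta_pm": delta_pm,
            "mean": float(np.exp(m + 0.5 * s**2)),
            "median": float(np.exp(m)),
            "q2.5": float(np.exp(m - z * s)),
            "q97.5": float(np.exp(m + z * s)),
        }


# --------------------------------------------------------------------- #
# functional wrappers
# --------------------------------------------------------------------- #

def fit(design: dict, **options) -> SpatiotemporalPoissonRegression:
    """Fit one (model, sex, age) task from :func:`build_design` output."""
    spec = design["spec"]
    name = spec.name if isinstance(spec, ModelSpec) else spec
    est = SpatiotemporalPoissonRegression(model=name, **options)
    return est.fit(design)


def rate_ratio(fitted: SpatiotemporalPoissonRegression, delta_pm: float = 1.0) -> dict:
    """Posterior rate-ratio summary of a fitted model."""
    return fitted.rate_ratio(delta_pm)


def fit_all_strata(panel: CountyPanel, model: str = "covariate_county",
                   sexes=None, age_groups=None, progress: bool = False,
                   **options) -> dict[tuple[str, str], SpatiotemporalPoissonRegression]:
    """Fit every (sex, age group) stratum independently.

    Hyperparameter optima are warm-started from the previous stratum of
    the same sex, which roughly halves the optimisation cost.
    """
    from .panel import AGE_GROUPS, SEXES

    sexes = sexes or SEXES
    age_groups = age_groups or AGE_GROUPS
    fits: dict[tuple[str, str], SpatiotemporalPoissonRegression] = {}
    for sex in sexes:
        warm = options.pop("init_log_precisions", None)
        for age in age_groups:
            design = build_design(panel, model, sex, age)
            est = SpatiotemporalPoissonRegression(
                model=model, init_log_precisions=warm, **options
            )
            est.fit(design)
            fits[(sex, age)] = est
            warm = np.array([
                np.log(est.precisions_[k]) for k in est.result_.log_precisions
            ])
            if progress:
                print(f"fitted {model} {sex} {age}: gamma={est.gamma_:.5f} "
                      f"(sd {est.gamma_sd_:.5f})")
        options["init_log_precisions"] = None
    return fits
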