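"""Abridged lifetables with Kannisto-Thatcher old-age extension.

Converts age-specific death rates (18 groups, 0-4 ... 80-84, 85+) into
survivorship and life expectancy at birth. The open 85+ interval is
expanded into 5-year intervals 85-89 ... 105-109 plus an open 110+
interval by fitting the logistic (Kannisto) hazard

    mu(x) = a * exp(b x) / (1 + a * exp(b x))

to the old-age rates (60-84 by default) and adjusting its level so that
the stationary-population-weighted extended rates reproduce the observed
85+ rate. Life-expectancy loss attributable to PM2.5 is the difference
between the counterfactual lifetable (all-cause deaths minus averted
cardiorespiratory deaths) and the observed one, computed per posterior
draw because expectation of life is nonlinear in the rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.base import BaseEstimator

from .attribution import AttributionResult
from .panel import AGE_GROUPS, SEXES, CountyPanel

__all__ = [
    "KannistoThatcherExtender",
    "kannisto_thatcher_extend",
    "Lifetable",
    "build_lifetable",
    "LELossResult",
    "le_loss",
]

#: midpoints of the five fitting intervals 60-64 ... 80-84
KT_FIT_MIDPOINTS = np.array([62.5, 67.5, 72.5, 77.5, 82.5])
#: midpoints of the extension intervals 85-89 ... 105-109 and open 110+
KT_EXT_MIDPOINTS = np.array([87.5, 92.5, 97.5, 102.5, 107.5, 112.5])
#: average years lived within the interval by those dying in it
A_FIRST = 2.0   # 0-4: deaths concentrate early in childhood
A_MID = 2.5     # all other 5-year intervals


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _weighted_open_rate(rates: np.ndarray, width: float = 5.0) -> float:
    """Stationary-population-weighted mean of extension rates.

    Weights are the person-years implied by the extension hazards
    themselves (piecewise-constant within intervals, final open
    interval exponential); equals l(85) / total person-years.
    """
    m = np.asarray(rates, dtype=float)
    k = len(m) - 1
    surv = np.exp(-width * m[:k])
    l = np.concatenate([[1.0], np.cumprod(surv)])
    L = (l[:-1] - l[1:]) / m[:k]
    L_open = l[-1] / m[-1]
    return 1.0 / (L.sum() + L_open)


class KannistoThatcherExtender(BaseEstimator):
    """Logistic-hazard extension of the open old-age interval.

    Fit on the old-age rates; ``predict`` evaluates the calibrated
    logistic hazard at arbitrary ages. The level parameter ``a`` is
    rescaled (keeping the asymptote at 1/year) so the extension
    reproduces the open-interval rate under its own stationary
    population.

    Attributes
    ----------
    a_, b_ : float
        Fitted logistic parameters after level calibration.
    scale_ : float
        Level multiplier applied to the raw fit (1.0 when the input is
        exactly logistic and self-consistent).
    fallback_ : bool
        True when the rates were non-increasing in age and a flat
        extension at the open-interval rate was used instead.
    extended_rates_ : ndarray
        Rates for 85-89 ... 105-109 and 110+.
    """

    def __init__(self, fit_midpoints=KT_FIT_MIDPOINTS,
                 ext_midpoints=KT_EXT_MIDPOINTS, interval_width: float = 5.0):
        self.fit_midpoints = fit_midpoints
        self.ext_midpoints = ext_midpoints
        self.interval_width = interval_width

    def fit(self, X, y=None):
        """Fit to old-age rates.

        Parameters
        ----------
        X : array of shape (n_fit + 1,)
            Rates at the fitting midpoints followed by the open-interval
            (85+) rate.
        """
        X = np.asarray(X, dtype=float)
        mids = np.asarray(self.fit_midpoints, dtype=float)
        if X.shape != (len(mids) + 1,):
            raise ValueError(
                f"expected {len(mids)} fitting rates plus the open rate"
            )
        rates, m_open = X[:-1], float(X[-1])
        if np.any(rates <= 0) or m_open <= 0:
            raise ValueError("old-age death rates must be positive")
        if np.any(rates >= 1.0):
            raise ValueError("old-age death rates must be below 1/year")
        self.open_rate_ = m_open
        ext_mids = np.asarray(self.ext_midpoints, dtype=float)

        # logit-linear fit: logit(mu) = log a + b x
        z = _logit(rates)
        b, log_a = np.polyfit(mids, z, 1)
        if b <= 0:
            # non-increasing hazard: flat extension at the open rate
            self.fallback_ = True
            self.a_, self.b_ = m_open / (1.0 - m_open), 0.0
            self.scale_ = 1.0
            self.extended_rates_ = np.full(len(ext_mids), m_open)
            return self
        self.fallback_ = False
        a0 = float(np.exp(log_a))

        def mismatch(log_s: float) -> float:
            s = np.exp(log_s)
            m_ext = s * a0 * np.exp(b * ext_mids)
            m_ext = m_ext / (1.0 + m_ext)
            return _weighted_open_rate(m_ext, self.interval_width) - m_open

        lo, hi = -12.0, 12.0
        if mismatch(lo) * mismatch(hi) > 0:  # open rate unreachable
            self.fallback_ = True
            self.a_, self.b_ = m_open / (1.0 - m_open), 0.0
            self.scale_ = 1.0
            self.extended_rates_ = np.full(len(ext_mids), m_open)
            return self
        log_s = brentq(mismatch, lo, hi, xtol=1e-14)
        self.scale_ = float(np.exp(log_s))
        self.a_ = self.scale_ * a0
        self.b_ = float(b)
        self.extended_rates_ = self.predict(ext_mids)
        return self

    def predict(self, ages) -> np.ndarray:
        """Calibrated logistic hazard at the given ages (per year, < 1)."""
        if not hasattr(self, "a_"):
            raise RuntimeError("extender is not fitted")
        ages = np.asarray(ages, dtype=float)
        if self.b_ == 0.0:
            return np.full(ages.shape, self.open_rate_)
        u = self.a_ * np.exp(self.b_ * ages)
        return u / (1.0 + u)


def kannisto_thatcher_extend(old_age_rates, open_interval_rate: float,
                             fit_midpoints=KT_FIT_MIDPOINTS) -> np.ndarray:
    """Extend the open 85+ rate into 85-89 ... 105-109 and 110+ rates."""
    ext = KannistoThatcherExtender(fit_midpoints=fit_midpoints)
    ext.fit(np.concatenate([np.asarray(old_age_rates, dtype=float),
                            [open_interval_rate]]))
    return ext.extended_rates_


# --------------------------------------------------------------------- #
# abridged lifetable
# --------------------------------------------------------------------- #

@dataclass
class Lifetable:
    """Abridged lifetable columns with expanded old-age intervals.

    ``table`` columns: age (interval lower bound), n (width), m (central
    rate), a (years lived in interval by the dying), q, l, d, L, T, e.
    """

    table: pd.DataFrame
    kt_fallback: bool

    @property
    def e0(self) -> float:
        """Life expectancy at birth (years)."""
        return float(self.table["e"].iloc[0])


def _extend_rates(m: np.ndarray) -> tuple[np.ndarray, bool]:
    """18 abridged rates -> (23 rates with KT-expanded old ages, fallback flag)."""
    ext = KannistoThatcherExtender()
    # fitting ages 60-84 are indices 12..16 of the abridged schedule
    fit_rates = m[12:17]
    if np.any(fit_rates <= 0):
        # degenerate schedules (zero old-age mortality below 85): flat
        return np.concatenate([m[:-1], np.full(6, max(m[-1], 1e-10))]), True
    ext.fit(np.concatenate([fit_rates, [m[-1]]]))
    return np.concatenate([m[:-1], ext.extended_rates_]), ext.fallback_


def build_lifetable(death_rates, population=None) -> Lifetable:
    """Abridged lifetable from 18 age-specific death rates.

    Parameters
    ----------
    death_rates : array of shape (18,)
        Central death rates m_x per person-year for 0-4 ... 80-84, 85+.
    population : array, optional
        Unused in the person-period columns; accepted so callers can
        pass (deaths, population) pairs through a common interface.

    Notes
    -----
    q_x = n m_x / (1 + (n - a_x) m_x) with n = 5, a_x = 2.0 for the
    first interval and 2.5 otherwise; the 85+ group is replaced by its
    Kannisto-Thatcher expansion, closed at an open 110+ interval with
    L = l / m.
    """
    m = np.asarray(death_rates, dtype=float)
    if m.shape != (len(AGE_GROUPS),):
        raise ValueError(f"expected {len(AGE_GROUPS)} age-specific rates")
    if np.any(m < 0):
        raise ValueError("negative death rate")
    if m[-1] <= 0:
        raise ValueError("open-interval (85+) rate must be positive")
    m_full, fallback = _extend_rates(m)

    n_int = len(m_full)  # 17 closed below 85 + 5 extension + open = 23
    widths = np.full(n_int, 5.0)
    a = np.full(n_int, A_MID)
    a[0] = A_FIRST
    ages = np.arange(0, 5 * n_int, 5)

    q = widths * m_full / (1.0 + (widths - a) * m_full)
    q = np.clip(q, 0.0, 1.0)
    q[-1] = 1.0

    radix = 100_000.0
    l = np.empty(n_int)
    l[0] = radix
    for i in range(n_int - 1):
        l[i + 1] = l[i] * (1.0 - q[i])
    d = np.empty(n_int)
    d[:-1] = l[:-1] - l[1:]
    d[-1] = l[-1]
    L = np.empty(n_int)
    L[:-1] = widths[:-1] * l[1:] + a[:-1] * d[:-1]
    L[-1] = l[-1] / m_full[-1] if l[-1] > 0 else 0.0
    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / l, 0.0)

    table = pd.DataFrame({
        "age": ages, "n": widths, "m": m_full, "a": a, "q": q,
        "l": l, "d": d, "L": L, "T": T, "e": e,
    })
    return Lifetable(table=table, kt_fallback=fallback)


# --------------------------------------------------------------------- #
# life-expectancy loss
# --------------------------------------------------------------------- #

@dataclass
class LELossResult:
    """Life-expectancy loss attributable to PM2.5 for one sex.

    ``per_unit`` has one row per unit (county id, or -1 for national)
    with observed e0, counterfactual e0 (posterior mean) and the loss
    (counterfactual minus observed, years) with 95% interval.
    ``clipped_cells`` counts cells where a pathological gamma draw
    implied more averted deaths than observed cardiorespiratory deaths.
    """

    sex: str
    unit: str
    per_unit: pd.DataFrame
    loss_draws: dict[int, np.ndarray]
    clipped_cells: int


def _pool_by_age(frame: pd.DataFrame, col: str) -> np.ndarray:
    by_age = frame.groupby("age_group")[col].sum()
    return by_age.reindex(list(AGE_GROUPS)).to_numpy(dtype=float)


def le_loss(panel: CountyPanel, attribution: AttributionResult,
            unit: str = "national", sex: str = "F",
            max_draws: int | None = None) -> LELossResult:
    """Life-expectancy loss from the averted-deaths draws of a scenario.

    The observed lifetable uses all-cause rates in the scenario's
    evaluation year; the counterfactual lifetable subtracts the averted
    cardiorespiratory deaths (clipped at the observed cardiorespiratory
    count) from all-cause deaths, draw by draw, and the loss draws
    ``e0_cf - e0_obs`` are summarised by mean and 95% interval.

    Parameters
    ----------
    unit : {"national", "county"}
    max_draws : int, optional
        Cap on posterior draws per unit (county-level lifetables are
        ~100x more numerous; capping keeps the cost proportionate).
    """
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}")
    if unit not in ("national", "county"):
        raise ValueError("unit must be 'national' or 'county'")
    years = sorted({int(y) for key in attribution.cell_index
                    for y in attribution.cell_index[key]["year"].unique()})
    if len(years) != 1:
        raise ValueError("life-expectancy loss needs a single evaluation year")
    year = years[0]

    d = panel.demography
    d = d[(d["year"] == year) & (d["sex"] == sex)]

    # assemble averted draws per (county, age): draws x county x age
    counties = np.sort(d["county"].unique())
    c_index = {c: i for i, c in enumerate(counties)}
    a_index = {a: i for i, a in enumerate(AGE_GROUPS)}
    some_key = (sex, AGE_GROUPS[0])
    n_draws = attribution.cell_draws[some_key].shape[0]
    averted = np.zeros((n_draws, len(counties), len(AGE_GROUPS)))
    for age in AGE_GROUPS:
        key = (sex, age)
        idx = attribution.cell_index[key]
        cols = idx["county"].map(c_index).to_numpy()
        averted[:, cols, a_index[age]] += attribution.cell_draws[key]

    # clip: averted cannot exceed observed cardiorespiratory deaths
    cardio = (
        d.pivot(index="county", columns="age_group", values="cardio_deaths")
        .reindex(index=counties, columns=list(AGE_GROUPS))
        .to_numpy(dtype=float)
    )
    allcause = (
        d.pivot(index="county", columns="age_group", values="allcause_deaths")
        .reindex(index=counties, columns=list(AGE_GROUPS))
        .to_numpy(dtype=float)
    )
    pop = (
        d.pivot(index="county", columns="age_group", values="population")
        .reindex(index=counties, columns=list(AGE_GROUPS))
        .to_numpy(dtype=float)
    )
    clipped = int(np.sum(averted > cardio[None, :, :]))
    averted = np.minimum(averted, cardio[None, :, :])

    if max_draws is not None and n_draws > max_draws:
        averted = averted[:max_draws]
        n_draws = max_draws

    def e0_from_deaths(deaths_by_age: np.ndarray, pop_by_age: np.ndarray) -> float:
        m = deaths_by_age / pop_by_age
        # a zero 85+ rate cannot close the table; use a tiny positive rate
        if m[-1] <= 0:
            m = m.copy()
            m[-1] = 1e-8
        return build_lifetable(m).e0

    rows = []
    loss_draws: dict[int, np.ndarray] = {}
    if unit == "national":
        targets = [(-1, slice(None))]
    else:
        targets = [(int(c), c_index[c]) for c in counties]
    for uid, sel in targets:
        if uid == -1:
            dth = allcause.sum(axis=0)
            p = pop.sum(axis=0)
            av = averted.sum(axis=1)
        else:
            dth = allcause[sel]
            p = pop[sel]
            av = averted[:, sel, :]
        e0_obs = e0_from_deaths(dth, p)
        losses = np.empty(n_draws)
        for k in range(n_draws):
            cf = np.maximum(dth - av[k], 0.0)
            losses[k] = e0_from_deaths(cf, p) - e0_obs
        loss_draws[uid] = losses
        rows.append({
            "unit": uid,
            "observed_e0": e0_obs,
            "counterfactual_e0": e0_obs + float(losses.mean()),
            "loss_mean": float(losses.mean()),
            "loss_q2.5": float(np.percentile(losses, 2.5)),
            "loss_q97.5": float(np.percentile(losses, 97.5)),
        })
    return LELossResult(
        sex=sex,
        unit=unit,
        per_unit=pd.DataFrame(rows),
        loss_draws=loss_draws,
        clipped_cells=clipped,
    )
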