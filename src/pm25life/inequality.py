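"""Sociodemographic inequality in PM2.5-attributable life-expectancy loss.

After accounting for how much a county's PM2.5 exceeds the observed
floor, does the life-expectancy loss still differ across counties
grouped by income, poverty, racial composition or education? The
question is answered by ordinary least squares of county-level LE loss
on the excess concentration plus quintile indicators of the chosen
characteristic; the headline quantity is the fifth-minus-first quintile
coefficient with its 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

__all__ = [
    "InequalityEstimate",
    "quintile_assign",
    "QuintileInequalityRegression",
    "le_loss_inequality",
]


@dataclass
class InequalityEstimate:
    """Q5 - Q1 difference in LE loss after accounting for PM2.5 excess."""

    covariate: str
    sex: str
    q5_minus_q1: float
    ci_low: float
    ci_high: float
    quintile_boundaries: np.ndarray
    degenerate: bool = False  # all covariate values tied
    rank_deficient: bool = False


def quintile_assign(values: pd.Series | np.ndarray,
                    ids: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """County-count quintiles (1-5) by sorted value, ties broken by id.

    Returns the quintile index per input position and the four interior
    boundaries (value at each quintile cut).

    Raises
    ------
    ValueError
        With fewer than 5 counties.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 5:
        raise ValueError("need at least 5 counties to form quintiles")
    if ids is None:
        ids = np.arange(n)
    order = np.lexsort((np.asarray(ids), values))
    # near-equal group sizes: first (n mod 5) groups get the extra county
    sizes = np.full(5, n // 5)
    sizes[: n % 5] += 1
    q_sorted = np.repeat(np.arange(1, 6), sizes)
    q = np.empty(n, dtype=int)
    q[order] = q_sorted
    cuts = np.cumsum(sizes)[:-1] - 1
    boundaries = values[order][cuts]
    return q, boundaries


class QuintileInequalityRegression(BaseEstimator):
    """OLS of LE loss on PM2.5 excess and covariate quintiles.

    The design is ``loss ~ 1 + pm_excess + I(Q2) + ... + I(Q5)`` with the
    first quintile as reference; ``q5_minus_q1_`` is the Q5 indicator
    coefficient. Conventional (non-robust) standard errors by default.

    Parameters
    ----------
    alpha : float
        1 - confidence level of the reported interval.
    robust : bool
        Use heteroskedasticity-robust (HC1) standard errors.
    weights : array, optional
        Per-county weights (e.g. population) for weighted least squares;
        default is unweighted county-count regression.
    """

    def __init__(self, alpha: float = 0.05, robust: bool = False, weights=None):
        self.alpha = alpha
        self.robust = robust
        self.weights = weights

    def fit(self, X, y=None):
        """Fit on a frame with columns ``loss``, ``pm_excess``, ``covariate``
        and optionally ``county`` (tie-break ids)."""
        X = pd.DataFrame(X)
        ids = X["county"].to_numpy() if "county" in X else np.arange(len(X))
        vals = X["covariate"].to_numpy(dtype=float)
        self.quintile_, self.boundaries_ = quintile_assign(vals, ids)
        self.degenerate_ = bool(np.ptp(vals) == 0)

        dummies = np.column_stack(
            [(self.quintile_ == k).astype(float) for k in range(2, 6)]
        )
        design = sm.add_constant(
            np.column_stack([X["pm_excess"].to_numpy(dtype=float), dummies])
        )
        names = ["const", "pm_excess", "Q2", "Q3", "Q4", "Q5"]
        if self.weights is not None:
            model = sm.WLS(X["loss"].to_numpy(dtype=float), design,
                           weights=np.asarray(self.weights, dtype=float))
        else:
            model = sm.OLS(X["loss"].to_numpy(dtype=float), design)
        res = model.fit(cov_type="HC1" if self.robust else "nonrobust")
        self.rank_deficient_ = bool(np.linalg.matrix_rank(design) < design.shape[1])
        self.result_ = res
        self.params_ = pd.Series(res.params, index=names)
        ci = res.conf_int(alpha=self.alpha)
        self.q5_minus_q1_ = float(self.params_["Q5"])
        self.ci_ = (float(ci[names.index("Q5"), 0]), float(ci[names.index("Q5"), 1]))
        return self


def le_loss_inequality(le_loss_by_county, pm_excess_by_county,
                       covariate_by_county, sex: str,
                       covariate_name: str = "covariate",
                       weights=None, robust: bool = False) -> InequalityEstimate:
    """Q5 - Q1 inequality in LE loss for one sociodemographic covariate.

    All three inputs are aligned pandas Series indexed by county (or
    equal-length arrays). ``pm_excess`` is the county concentration
    above the observed floor (2.8 ug/m3 in the reference analysis).
    """
    loss = pd.Series(le_loss_by_county)
    pm_ex = pd.Series(pm_excess_by_county)
    cov = pd.Series(covariate_by_county)
    if not (len(loss) == len(pm_ex) == len(cov)):
        raise ValueError("inputs must cover the same county set")
    if isinstance(loss.index, pd.Index) and not loss.index.equals(cov.index):
        cov = cov.reindex(loss.index)
        pm_ex = pm_ex.reindex(loss.index)
        if cov.isna().any() or pm_ex.isna().any():
            raise ValueError("inputs must cover the same county set")
    frame = pd.DataFrame({
        "county": loss.index,
        "loss": loss.to_numpy(dtype=float),
        "pm_excess": pm_ex.to_numpy(dtype=float),
        "covariate": cov.to_numpy(dtype=float),
    })
    reg = QuintileInequalityRegression(robust=robust, weights=weights).fit(frame)
    return InequalityEstimate(
        covariate=covariate_name,
        sex=sex,
        q5_minus_q1=reg.q5_minus_q1_,
        ci_low=reg.ci_[0],
        ci_high=reg.ci_[1],
        quintile_boundaries=reg.boundaries_,
        degenerate=reg.degenerate_,
        rank_deficient=reg.rank_deficient_,
    )
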