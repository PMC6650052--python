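"""Unit-of-analysis construction: recursive small-county merging.

Counties whose sex-specific population falls below a threshold (25,000
persons by default) in any year are recursively merged with an adjacent
county of the same state and urban/rural class until every sex-year
population of the merged unit clears the threshold. Deaths and
populations are summed over members; PM2.5 and covariates become
population-weighted means (log-scale covariates are aggregated on the
natural scale and re-logged). Counties with no eligible neighbour are
left unmerged and flagged.

The merge order is deterministic: always take the currently smallest
deficient unit (by its minimum sex-year population) and merge it with
its smallest-population eligible neighbour, breaking ties by lowest id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .panel import (
    COVARIATE_COLUMNS,
    LOG_SCALE_COVARIATES,
    CountyPanel,
    PanelValidationError,
)

__all__ = [
    "MergePlan",
    "SmallCountyMerger",
    "merge_small_counties",
    "age_standardised_rate",
]

DEFAULT_THRESHOLD = 25_000  # persons, per sex and year


@dataclass
class MergePlan:
    """Mapping from original counties to merged analysis units.

    Attributes
    ----------
    assignment : dict
        original county id -> merged unit id (total and surjective).
    members : dict
        merged unit id -> sorted list of original member ids.
    state : dict
        merged unit id -> state id (members never cross states).
    urbanicity : dict
        merged unit id -> urban/rural class (never mixed).
    unmergeable : set
        Units still below threshold with no eligible neighbour.
    """

    assignment: dict[int, int]
    members: dict[int, list[int]]
    state: dict[int, int]
    urbanicity: dict[int, str]
    unmergeable: set[int] = field(default_factory=set)

    @property
    def is_identity(self) -> bool:
        return all(k == v for k, v in self.assignment.items()) and all(
            len(m) == 1 for m in self.members.values()
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (orig, unit, self.state[unit], self.urbanicity[unit],
             unit in self.unmergeable)
            for orig, unit in sorted(self.assignment.items())
        ]
        return pd.DataFrame(
            rows, columns=["county", "merged_unit", "state", "urbanicity", "flagged"]
        )


class SmallCountyMerger(BaseEstimator, TransformerMixin):
    """Transformer producing merged analysis units from a raw county panel.

    Parameters
    ----------
    threshold : int
        Minimum sex-specific population required in every year.

    Attributes
    ----------
    plan_ : MergePlan
        Fitted merge plan.
    n_units_ : int
        Number of merged analysis units.
    """

    def __init__(self, threshold: int = DEFAULT_THRESHOLD):
        self.threshold = threshold

    # -------------------------------------------------------------- #
    def fit(self, X: CountyPanel, y=None):
        self.plan_ = self._build_plan(X)
        self.n_units_ = len(self.plan_.members)
        return self

    def transform(self, X: CountyPanel) -> CountyPanel:
        if not hasattr(self, "plan_"):
            raise RuntimeError("merger is not fitted")
        return _apply_plan(X, self.plan_)

    def fit_transform(self, X: CountyPanel, y=None, **kwargs) -> CountyPanel:
        return self.fit(X).transform(X)

    # -------------------------------------------------------------- #
    def _build_plan(self, panel: CountyPanel) -> MergePlan:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if len(panel.demography) == 0:
            raise PanelValidationError("empty panel")
        seen = set()
        for a, b in panel.adjacency:
            seen.add((a, b))
        for a, b in seen:
            if (b, a) in seen and a == b:
                raise PanelValidationError(f"self-loop at {a}")

        # min sex-year population per county (the deficiency criterion)
        sexyear = (
            panel.demography.groupby(["county", "year", "sex"])["population"]
            .sum()
            .groupby("county")
        )
        min_pop = sexyear.min().to_dict()
        total_pop = (
            panel.demography.groupby("county")["population"].sum().to_dict()
        )
        state = panel.counties["state"].to_dict()
        urb = panel.counties["urbanicity"].to_dict()
        nbrs = panel.neighbours()

        # unit state: each unit is a set of member counties
        unit_of = {c: c for c in panel.county_ids}
        members: dict[int, set[int]] = {c: {c} for c in panel.county_ids}
        unit_min = dict(min_pop)
        unit_total = dict(total_pop)
        unit_nbrs = {c: set(nbrs[c]) for c in panel.county_ids}
        unmergeable: set[int] = set()

        def eligible(u: int) -> list[int]:
            return [
                v for v in unit_nbrs[u]
                if state[v] == state[u] and urb[v] == urb[u]
            ]

        while True:
            deficient = [
                u for u in members
                if unit_min[u] < self.threshold and u not in unmergeable
            ]
            if not deficient:
                break
            # smallest deficient unit; ties by lowest id
            u = min(deficient, key=lambda c: (unit_min[c], c))
            cands = eligible(u)
            if not cands:
                unmergeable.add(u)
                continue
            v = min(cands, key=lambda c: (unit_total[c], c))
            # absorb v and u into the unit keyed by the smaller id
            keep, drop = (u, v) if u < v else (v, u)
            members[keep] = members[keep] | members[drop]
            unit_nbrs[keep] = (unit_nbrs[keep] | unit_nbrs[drop]) - {keep, drop}
            for w in unit_nbrs:
                s = unit_nbrs[w]
                if drop in s:
                    s.discard(drop)
                    if w != keep:
                        s.add(keep)
            unit_total[keep] = unit_total[keep] + unit_total[drop]
            del members[drop], unit_nbrs[drop], unit_total[drop], unit_min[drop]
            unmergeable.discard(keep)
            # recompute the sex-year minimum of the merged unit
            mem = list(members[keep])
            unit_min[keep] = (
                panel.demography[panel.demography["county"].isin(mem)]
                .groupby(["year", "sex"])["population"]
                .sum()
                .min()
            )
            for c in mem:
                unit_of[c] = keep

        assignment = {int(c): int(unit_of[c]) for c in panel.county_ids}
        return MergePlan(
            assignment=assignment,
            members={int(u): sorted(int(c) for c in m) for u, m in members.items()},
            state={int(u): state[u] for u in members},
            urbanicity={int(u): urb[u] for u in members},
            unmergeable={int(u) for u in unmergeable},
        )


def _apply_plan(panel: CountyPanel, plan: MergePlan) -> CountyPanel:
    """Aggregate a panel onto the merged units of a plan."""
    amap = plan.assignment
    # demography: plain sums
    d = panel.demography.copy()
    d["county"] = d["county"].map(amap)
    demography = (
        d.groupby(["county", "year", "sex", "age_group"], as_index=False)[
            ["population", "cardio_deaths", "allcause_deaths"]
        ].sum()
    )

    # exposure: population-weighted means (log covariates on natural scale)
    pop_cy = (
        panel.demography.groupby(["county", "year"])["population"].sum().rename("w")
    )
    e = panel.exposure.merge(pop_cy, on=["county", "year"])
    e["unit"] = e["county"].map(amap)
    for c in LOG_SCALE_COVARIATES:
        e[c] = np.exp(e[c])
    value_cols = ["pm", *COVARIATE_COLUMNS]
    weighted = e[value_cols].multiply(e["w"], axis=0)
    weighted["unit"] = e["unit"]
    weighted["year"] = e["year"]
    weighted["w"] = e["w"]
    agg = weighted.groupby(["unit", "year"]).sum()
    exposure = agg[value_cols].div(agg["w"], axis=0).reset_index()
    for c in LOG_SCALE_COVARIATES:
        exposure[c] = np.log(exposure[c])
    exposure = exposure.rename(columns={"unit": "county"})

    counties = pd.DataFrame(
        {
            "state": pd.Series(plan.state),
            "urbanicity": pd.Series(plan.urbanicity),
        }
    ).rename_axis("county")

    # adjacency between merged units (no self-edges)
    edges = set()
    for a, b in panel.adjacency:
        ua, ub = amap[a], amap[b]
        if ua != ub:
            edges.add((min(ua, ub), max(ua, ub)))

    merged = CountyPanel(
        counties=counties.sort_index(),
        exposure=exposure.sort_values(["county", "year"]).reset_index(drop=True),
        demography=demography.sort_values(
            ["county", "year", "sex", "age_group"]
        ).reset_index(drop=True),
        adjacency=sorted(edges),
        merged_from={u: m for u, m in plan.members.items()},
        unmergeable=set(plan.unmergeable),
    )
    return merged.validate()


def merge_small_counties(
    panel: CountyPanel, threshold: int = DEFAULT_THRESHOLD
) -> tuple[CountyPanel, MergePlan]:
    """Merge small counties; returns the merged panel and the plan."""
    merger = SmallCountyMerger(threshold=threshold).fit(panel)
    return merger.transform(panel), merger.plan_


def age_standardised_rate(
    deaths: np.ndarray, population: np.ndarray, weights: np.ndarray
) -> float:
    """Age-standardised death rate per 100,000.

    ``sum_a w_a * (deaths_a / population_a) * 100000`` with the standard
    weights summing to one.

    Raises
    ------
    ValueError
        If weights do not sum to 1, or an age group with nonzero weight
        has zero population.
    """
    deaths = np.asarray(deaths, dtype=float)
    population = np.asarray(population, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if deaths.shape != population.shape or deaths.shape != weights.shape:
        raise ValueError("deaths, population and weights must align")
    if not np.isclose(weights.sum(), 1.0, atol=1e-8):
        raise ValueError("standard weights must sum to 1")
    bad = (population <= 0) & (weights != 0)
    if bad.any():
        raise ValueError("zero population in an age group with nonzero weight")
    rates = np.divide(deaths, population, out=np.zeros_like(deaths),
                      where=population > 0)
    return float(np.sum(weights * rates) * 100_000.0)
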