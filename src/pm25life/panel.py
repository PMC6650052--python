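"""County-by-year-by-sex-by-age mortality panel container and text-file I/O.

The panel is the unit of exchange between every stage of the pipeline:
a set of county units (with state membership, urban/rural class and a
symmetric adjacency relation), an exposure table of annual PM2.5 and nine
time-varying covariates, and a demography table of population and death
counts (cardiorespiratory and all-cause) per county, year, sex and
5-year age group (0-4 ... 80-84, 85+).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

#: canonical 18 age-group labels, birth to 85+
AGE_GROUPS: tuple[str, ...] = tuple(
    f"{lo}-{lo + 4}" for lo in range(0, 85, 5)
) + ("85+",)

#: lower bound (years) of each age interval, aligned with AGE_GROUPS
AGE_LOWER: tuple[int, ...] = tuple(range(0, 90, 5))

SEXES: tuple[str, str] = ("F", "M")

#: the nine time-varying county covariates, in model order; income and the
#: lung-cancer smoking proxy are stored log-transformed
COVARIATE_COLUMNS: tuple[str, ...] = (
    "log_income",
    "poverty_pct",
    "black_pct",
    "hs_grad_pct",
    "urban_pct",
    "unemployment_pct",
    "log_lung_cancer_rate",
    "temperature",
    "humidity",
)

#: covariates whose natural measurement scale is the exponentiated one;
#: population-weighted aggregation happens on that scale, then re-logs
LOG_SCALE_COVARIATES: tuple[str, ...] = ("log_income", "log_lung_cancer_rate")


class PanelValidationError(ValueError):
    """Raised when a panel violates one of its structural invariants."""


@dataclass
class CountyPanel:
    """Observational county panel.

    Parameters
    ----------
    counties : pandas.DataFrame
        Indexed by integer county id, columns ``state`` (int) and
        ``urbanicity`` ("urban" or "rural").
    exposure : pandas.DataFrame
        One row per (county, year); columns ``county``, ``year``, ``pm``
        plus the nine covariates of :data:`COVARIATE_COLUMNS`.
    demography : pandas.DataFrame
        One row per (county, year, sex, age_group); columns ``county``,
        ``year``, ``sex``, ``age_group``, ``population``, ``cardio_deaths``,
        ``allcause_deaths``.
    adjacency : list of (int, int)
        Undirected edge list over county ids, no self-loops.
    merged_from : dict, optional
        Mapping merged-unit id -> list of original member ids, populated by
        the small-county merge step.
    unmergeable : set, optional
        Units left below the population threshold because no eligible
        neighbour existed.
    """

    counties: pd.DataFrame
    exposure: pd.DataFrame
    demography: pd.DataFrame
    adjacency: list[tuple[int, int]]
    merged_from: dict[int, list[int]] = field(default_factory=dict)
    unmergeable: set[int] = field(default_factory=set)

    # ------------------------------------------------------------------ #
    # derived views
    # ------------------------------------------------------------------ #
    @property
    def county_ids(self) -> np.ndarray:
        return self.counties.index.to_numpy()

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.exposure["year"].unique())

    @property
    def age_groups(self) -> tuple[str, ...]:
        return AGE_GROUPS

    def graph(self) -> nx.Graph:
        """Adjacency as a networkx graph (isolated counties included)."""
        g = nx.Graph()
        g.add_nodes_from(self.county_ids)
        g.add_edges_from(self.adjacency)
        return g

    def neighbours(self) -> dict[int, set[int]]:
        nbrs: dict[int, set[int]] = {c: set() for c in self.county_ids}
        for a, b in self.adjacency:
            nbrs[a].add(b)
            nbrs[b].add(a)
        return nbrs

    def pm_wide(self) -> pd.DataFrame:
        """PM2.5 as a (county x year) matrix."""
        return self.exposure.pivot(index="county", columns="year", values="pm")

    def population_weighted_pm(self, year: int) -> float:
        """National population-weighted mean PM2.5 for one year."""
        pop = (
            self.demography[self.demography["year"] == year]
            .groupby("county")["population"]
            .sum()
        )
        pm = (
            self.exposure[self.exposure["year"] == year]
            .set_index("county")["pm"]
            .reindex(pop.index)
        )
        return float(np.average(pm.to_numpy(), weights=pop.to_numpy()))

    # ------------------------------------------------------------------ #
    # validation
    # ------------------------------------------------------------------ #
    def validate(self) -> "CountyPanel":
        """Check structural invariants; return self or raise.

        Invariants: symmetric adjacency without self-loops over known ids;
        PM2.5 >= 0; positive populations; cardiorespiratory deaths bounded
        by all-cause deaths and population; a complete (county, year, sex,
        age group) grid with all 18 age groups.
        """
        ids = set(self.county_ids)
        for a, b in self.adjacency:
            if a == b:
                raise PanelValidationError(f"self-loop at county {a}")
            if a not in ids or b not in ids:
                raise PanelValidationError(f"edge ({a},{b}) references unknown county")
        if (self.exposure["pm"] < 0).any():
            raise PanelValidationError("negative PM2.5 concentration")
        d = self.demography
        if (d["population"] <= 0).any():
            raise PanelValidationError("non-positive population cell")
        if (d["cardio_deaths"] > d["allcause_deaths"]).any():
            raise PanelValidationError("cardiorespiratory deaths exceed all-cause deaths")
        if (d["allcause_deaths"] > d["population"]).any():
            raise PanelValidationError("deaths exceed population")
        got_ages = set(d["age_group"].unique())
        if got_ages != set(AGE_GROUPS):
            raise PanelValidationError(
                f"expected 18 age groups, got {sorted(got_ages)}"
            )
        n_expected = len(ids) * len(self.years) * 2 * len(AGE_GROUPS)
        if len(d) != n_expected:
            raise PanelValidationError(
                f"demography has {len(d)} rows, expected complete grid of {n_expected}"
            )
        if len(self.exposure) != len(ids) * len(self.years):
            raise PanelValidationError("exposure table is not a complete county-year grid")
        return self

    # ------------------------------------------------------------------ #
    # text-file round trip
    # ------------------------------------------------------------------ #
    def write(self, directory: str | Path) -> None:
        """Write the panel as plain-text tables.

        ``counties.csv`` (id, state, urbanicity), ``exposure.csv``
        (county-year PM and covariates), ``demography.csv``
        (county-year-sex-age counts) and ``adjacency.txt`` (edge list).
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.counties.rename_axis("county").to_csv(directory / "counties.csv")
        self.exposure.to_csv(directory / "exposure.csv", index=False)
        self.demography.to_csv(directory / "demography.csv", index=False)
        with open(directory / "adjacency.txt", "w") as fh:
            for a, b in sorted(tuple(sorted(e)) for e in self.adjacency):
                fh.write(f"{a}\t{b}\n")

    @classmethod
    def read(cls, directory: str | Path) -> "CountyPanel":
        directory = Path(directory)
        counties = pd.read_csv(directory / "counties.csv", index_col="county")
        exposure = pd.read_csv(directory / "exposure.csv")
        demography = pd.read_csv(directory / "demography.csv")
        edges: list[tuple[int, int]] = []
        adj_path = directory / "adjacency.txt"
        if adj_path.exists():
            with open(adj_path) as fh:
                for line in fh:
                    if line.strip():
                        a, b = line.split()
                        edges.append((int(a), int(b)))
        return cls(
            counties=counties,
            exposure=exposure,
            demography=demography,
            adjacency=edges,
        ).validate()
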