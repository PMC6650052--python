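"""Shared fixtures: tiny hand-built panels and simple posterior stand-ins."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pm25life import AGE_GROUPS, COVARIATE_COLUMNS, SEXES, CountyPanel, GeneratorConfig, generate_panel


class FixedGammaFit:
    """Posterior stand-in with a known gamma (optionally with spread).

    Mimics the ``sample_gamma`` interface of a fitted model so that
    attribution and lifetable stages can be tested against closed forms
    without running inference.
    """

    def __init__(self, gamma: float, sd: float = 0.0):
        self.gamma_ = gamma
        self.gamma_sd_ = sd

    def sample_gamma(self, n_draws, rng=None):
        if self.gamma_sd_ == 0.0:
            return np.full(n_draws, self.gamma_)
        if rng is None:
            rng = np.random.default_rng(0)
        return rng.normal(self.gamma_, self.gamma_sd_, size=n_draws)


def fixed_fits(gamma: float, sd: float = 0.0) -> dict:
    return {(s, a): FixedGammaFit(gamma, sd) for s in SEXES for a in AGE_GROUPS}


def build_toy_panel(
    populations,
    pms,
    states=None,
    urbanicity=None,
    edges=(),
    years=(2014, 2015),
    cardio_rate=0.004,
    allcause_rate=0.01,
    covariate_values=None,
) -> CountyPanel:
    """Small deterministic panel: equal population in every sex-age cell.

    ``populations`` are per-sex county populations; deaths are set from
    the constant rates (rounded), identical across years.
    """
    n = len(populations)
    ids = np.arange(n)
    states = states if states is not None else np.zeros(n, dtype=int)
    urbanicity = urbanicity if urbanicity is not None else ["urban"] * n
    years = list(range(years[0], years[1] + 1))
    counties = pd.DataFrame(
        {"state": states, "urbanicity": urbanicity},
        index=pd.Index(ids, name="county"),
    )
    pms = np.asarray(pms, dtype=float)
    exposure_rows = []
    for c in ids:
        for j, y in enumerate(years):
            pm_val = pms[c, j] if pms.ndim == 2 else pms[c]
            row = {"county": c, "year": y, "pm": pm_val}
            for k, name in enumerate(COVARIATE_COLUMNS):
                row[name] = (covariate_values or {}).get(name, 1.0 + 0.1 * k)
            exposure_rows.append(row)
    demog_rows = []
    for c in ids:
        cell_pop = max(int(populations[c] / len(AGE_GROUPS)), 1)
        for y in years:
            for s in SEXES:
                for a in AGE_GROUPS:
                    demog_rows.append({
                        "county": c, "year": y, "sex": s, "age_group": a,
                        "population": cell_pop,
                        "cardio_deaths": int(round(cell_pop * cardio_rate)),
                        "allcause_deaths": int(round(cell_pop * allcause_rate)),
                    })
    return CountyPanel(
        counties=counties,
        exposure=pd.DataFrame(exposure_rows),
        demography=pd.DataFrame(demog_rows),
        adjacency=list(edges),
    ).validate()


@pytest.fixture(scope="session")
def default_panel_small():
    """36-county default-parameter panel used by read-only tests."""
    cfg = GeneratorConfig(n_counties=36, n_states=3, seed=42, pop_median=3e5)
    return cfg, generate_panel(cfg)


@pytest.fixture(scope="session")
def default_panel_400():
    """400-county default panel for distribution-level checks."""
    cfg = GeneratorConfig(n_counties=400, seed=7)
    return cfg, generate_panel(cfg)


def single_year_e0(rates_5yr: np.ndarray, open_rate: float | None = None) -> float:
    """Brute-force single-year lifetable under piecewise-constant hazards.

    ``rates_5yr`` are hazards of consecutive 5-year intervals starting at
    age 0; the final entry is an open interval closed with exponential
    person-years ``l/m``. Independent oracle for the abridged lifetable.
    """
    m = np.repeat(np.asarray(rates_5yr[:-1], dtype=float), 5)
    m_open = float(rates_5yr[-1]) if open_rate is None else open_rate
    l = 1.0
    total = 0.0
    for mx in m:
        if mx <= 0:
            total += l  # no deaths: a full person-year lived
            continue
        l_next = l * np.exp(-mx)
        total += (l - l_next) / mx
        l = l_next
    total += l / m_open
    return total
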