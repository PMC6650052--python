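"""Small-county merging and age standardisation."""

import numpy as np
import pandas as pd
import pytest

from pm25life import (
    GeneratorConfig,
    SmallCountyMerger,
    age_standardised_rate,
    generate_panel,
    merge_small_counties,
)
from pm25life.panel import PanelValidationError

from conftest import build_toy_panel


def test_large_counties_return_identity_plan():
    panel = build_toy_panel(
        populations=[900_000, 900_000, 900_000],
        pms=[5.0, 7.0, 9.0],
        edges=[(0, 1), (1, 2)],
    )
    merged, plan = merge_small_counties(panel, threshold=25_000)
    assert plan.is_identity
    pd.testing.assert_frame_equal(
        merged.exposure.reset_index(drop=True),
        panel.exposure.sort_values(["county", "year"]).reset_index(drop=True),
        check_dtype=False,
    )


def test_three_county_chain_merges_smallest_into_neighbour():
    """Chain 0-1-2 with per-sex populations 10k/30k/40k: county 0 merges
    with county 1; merged PM is the population-weighted member mean."""
    panel = build_toy_panel(
        populations=[10_000, 30_000, 40_000],
        pms=[12.0, 8.0, 6.0],
        edges=[(0, 1), (1, 2)],
    )
    merged, plan = merge_small_counties(panel, threshold=25_000)
    assert plan.assignment == {0: 0, 1: 0, 2: 2}
    assert plan.members[0] == [0, 1]
    # cells round to equal populations so weights are 10:30
    expected_pm = (10_000 * 12.0 + 30_000 * 8.0) / 40_000
    got = merged.exposure.query("county == 0")["pm"].iloc[0]
    assert got == pytest.approx(expected_pm, rel=1e-3)
    assert not plan.unmergeable


def test_merge_respects_state_and_urbanicity_boundaries():
    panel = build_toy_panel(
        populations=[10_000, 500_000, 500_000],
        pms=[10.0, 10.0, 10.0],
        states=[0, 1, 0],
        urbanicity=["rural", "rural", "urban"],
        edges=[(0, 1), (0, 2)],
    )
    # neighbour 1 is another state, neighbour 2 another class: unmergeable
    _, plan = merge_small_counties(panel, threshold=25_000)
    assert plan.assignment == {0: 0, 1: 1, 2: 2}
    assert plan.unmergeable == {0}


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_randomised_merge_conserves_counts_and_meets_threshold(seed):
    cfg = GeneratorConfig(n_counties=80, n_states=4, seed=seed, pop_median=4e4)
    panel = generate_panel(cfg)
    merged, plan = merge_small_counties(panel, threshold=25_000)

    # conservation per sex-year-age
    for col in ("population", "cardio_deaths", "allcause_deaths"):
        before = panel.demography.groupby(["year", "sex", "age_group"])[col].sum()
        after = merged.demography.groupby(["year", "sex", "age_group"])[col].sum()
        pd.testing.assert_series_equal(before, after, check_dtype=False)

    # threshold audit
    sexyear = merged.demography.groupby(["county", "year", "sex"])["population"].sum()
    min_by_unit = sexyear.groupby("county").min()
    for unit, mn in min_by_unit.items():
        assert mn >= 25_000 or unit in merged.unmergeable

    # no state or urban/rural crossing
    for unit, members in plan.members.items():
        states = {panel.counties.loc[m, "state"] for m in members}
        classes = {panel.counties.loc[m, "urbanicity"] for m in members}
        assert len(states) == 1 and len(classes) == 1

    # merged units are connected in the original adjacency
    g = panel.graph()
    for members in plan.members.values():
        sub = g.subgraph(members)
        import networkx as nx

        assert nx.is_connected(sub)


def test_merged_pm_lies_within_member_bounds():
    cfg = GeneratorConfig(n_counties=60, seed=3, pop_median=4e4)
    panel = generate_panel(cfg)
    merged, plan = merge_small_counties(panel)
    pm = panel.exposure.set_index(["county", "year"])["pm"]
    for unit, members in plan.members.items():
        if len(members) == 1:
            continue
        for year in panel.years:
            vals = [pm.loc[(m, year)] for m in members]
            got = merged.exposure.query(
                "county == @unit and year == @year"
            )["pm"].iloc[0]
            assert min(vals) - 1e-9 <= got <= max(vals) + 1e-9


def test_merging_twice_is_idempotent():
    cfg = GeneratorConfig(n_counties=49, n_states=2, seed=9, pop_median=4e4)
    panel = generate_panel(cfg)
    merged, _ = merge_small_counties(panel)
    again, plan2 = merge_small_counties(merged)
    assert plan2.is_identity
    assert len(again.county_ids) == len(merged.county_ids)


def test_empty_panel_is_rejected():
    panel = build_toy_panel([50_000], [5.0])
    panel.demography = panel.demography.iloc[0:0]
    with pytest.raises(PanelValidationError):
        SmallCountyMerger().fit(panel)


# ------------------------------------------------------------------ #
# age standardisation
# ------------------------------------------------------------------ #

def test_equal_rates_give_rate_times_1e5_for_any_weights():
    pop = np.array([1000.0, 2000.0, 500.0])
    r = 0.007
    deaths = r * pop
    for w in ([0.2, 0.3, 0.5], [1 / 3] * 3):
        out = age_standardised_rate(deaths, pop, np.array(w))
        assert out == pytest.approx(r * 1e5)


def test_two_age_half_weights_example():
    out = age_standardised_rate(
        deaths=np.array([1.0, 3.0]),
        population=np.array([1000.0, 1000.0]),
        weights=np.array([0.5, 0.5]),
    )
    assert out == pytest.approx(200.0)


def test_zero_deaths_standardise_to_zero():
    out = age_standardised_rate(
        np.zeros(4), np.full(4, 100.0), np.full(4, 0.25)
    )
    assert out == 0.0


def test_zero_population_with_weight_is_an_error():
    with pytest.raises(ValueError):
        age_standardised_rate(
            np.array([1.0, 1.0]), np.array([100.0, 0.0]), np.array([0.5, 0.5])
        )


def test_weights_must_sum_to_one():
    with pytest.raises(ValueError):
        age_standardised_rate(
            np.array([1.0, 1.0]), np.array([100.0, 100.0]), np.array([0.5, 0.6])
        )
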