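"""Lifetable construction, Kannisto-Thatcher extension, LE loss."""

import numpy as np
import pytest

from pm25life import (
    AGE_GROUPS,
    build_lifetable,
    kannisto_thatcher_extend,
    le_loss,
    floor_scenario,
    scenario_attribution,
)
from pm25life.lifetable import (
    KT_EXT_MIDPOINTS,
    KT_FIT_MIDPOINTS,
    KannistoThatcherExtender,
    _weighted_open_rate,
)

from conftest import build_toy_panel, fixed_fits, single_year_e0


def _logistic(a, b, x):
    u = a * np.exp(b * x)
    return u / (1.0 + u)


class TestKannistoThatcher:
    def test_recovers_known_logistic_curve(self):
        a, b = 2.0e-5, 0.11
        fit_rates = _logistic(a, b, KT_FIT_MIDPOINTS)
        open_rate = _weighted_open_rate(_logistic(a, b, KT_EXT_MIDPOINTS))
        ext = kannisto_thatcher_extend(fit_rates, open_rate)
        np.testing.assert_allclose(ext, _logistic(a, b, KT_EXT_MIDPOINTS), atol=1e-6)

    def test_fitted_parameters_match_generating_curve(self):
        a, b = 5.0e-6, 0.12
        est = KannistoThatcherExtender()
        open_rate = _weighted_open_rate(_logistic(a, b, KT_EXT_MIDPOINTS))
        est.fit(np.concatenate([_logistic(a, b, KT_FIT_MIDPOINTS), [open_rate]]))
        assert est.b_ == pytest.approx(b, abs=1e-8)
        assert est.a_ == pytest.approx(a, rel=1e-6)
        assert est.scale_ == pytest.approx(1.0, abs=1e-6)

    def test_flat_hazard_limit_extends_at_open_rate(self):
        ext = kannisto_thatcher_extend(np.full(5, 0.08), 0.08)
        np.testing.assert_allclose(ext, 0.08, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_extended_hazards_stay_below_one(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.01, 0.05)
        growth = rng.uniform(1.2, 2.2, size=5)
        rates = np.minimum(base * np.cumprod(growth), 0.6)
        ext = kannisto_thatcher_extend(rates, min(rates[-1] * 1.5, 0.8))
        assert np.all(ext < 1.0)
        assert np.all(ext > 0.0)

    def test_non_positive_rates_rejected(self):
        with pytest.raises(ValueError):
            kannisto_thatcher_extend(np.array([0.01, 0.02, 0.0, 0.04, 0.05]), 0.1)

    def test_decreasing_rates_fall_back_to_flat_extension(self):
        est = KannistoThatcherExtender()
        est.fit(np.array([0.05, 0.04, 0.03, 0.02, 0.01, 0.10]))
        assert est.fallback_
        np.testing.assert_allclose(est.extended_rates_, 0.10)


class TestBuildLifetable:
    def test_constant_hazard_gives_inverse_rate_expectancy(self):
        lt = build_lifetable(np.full(18, 0.02))
        assert lt.e0 == pytest.approx(50.0, abs=0.5)

    def test_survival_to_85_plus_flat_extension(self):
        m = 0.2
        rates = np.zeros(18)
        rates[-1] = m
        lt = build_lifetable(rates)
        assert lt.kt_fallback
        assert lt.e0 == pytest.approx(85.0 + 1.0 / m, abs=0.5)

    def test_doubling_rates_strictly_lowers_e0(self):
        rng = np.random.default_rng(4)
        m = np.sort(rng.uniform(0.001, 0.05, 18))
        assert build_lifetable(2 * m).e0 < build_lifetable(m).e0

    def test_lifetable_columns_satisfy_identities(self):
        rng = np.random.default_rng(11)
        m = np.sort(rng.uniform(0.0005, 0.08, 18))
        lt = build_lifetable(m).table
        assert ((lt["q"] >= 0) & (lt["q"] <= 1)).all()
        assert (np.diff(lt["l"]) <= 1e-9).all()
        np.testing.assert_allclose(
            lt["T"], lt["L"][::-1].cumsum()[::-1], rtol=1e-12
        )
        assert lt["e"].iloc[0] > 0

    @pytest.mark.parametrize("seed", range(100))
    def test_abridged_e0_matches_single_year_oracle(self, seed):
        """Abridged expectancy within 0.5 years of a brute-force
        single-year lifetable built from the same hazards."""
        rng = np.random.default_rng(seed)
        young = rng.uniform(1e-4, 5e-3, 12)
        old = np.sort(rng.uniform(5e-3, 0.08, 5))
        open_r = old[-1] * rng.uniform(1.5, 2.5)
        m = np.concatenate([young, old, [open_r]])
        lt = build_lifetable(m)
        oracle = single_year_e0(lt.table["m"].to_numpy())
        assert lt.e0 == pytest.approx(oracle, abs=0.5)

    def test_negative_rate_rejected(self):
        m = np.full(18, 0.01)
        m[3] = -0.001
        with pytest.raises(ValueError):
            build_lifetable(m)


class TestLELoss:
    def _panel_and_attribution(self, gamma, sd=0.0, n_draws=20, **kwargs):
        panel = build_toy_panel(
            populations=[600_000, 500_000], pms=[12.8, 9.0],
            years=(2015, 2015), cardio_rate=0.004, allcause_rate=0.01,
            **kwargs,
        )
        scen = floor_scenario(panel, floor=2.8)
        att = scenario_attribution(panel, fixed_fits(gamma, sd), scen,
                                   n_draws=n_draws,
                                   rng=np.random.default_rng(7))
        return panel, att

    def test_zero_averted_gives_exactly_zero_loss(self):
        panel, att = self._panel_and_attribution(0.0)
        res = le_loss(panel, att, unit="national", sex="F")
        assert res.per_unit["loss_mean"].iloc[0] == 0.0
        assert res.per_unit["loss_q97.5"].iloc[0] == 0.0

    def test_positive_averted_gives_positive_loss(self):
        panel, att = self._panel_and_attribution(float(np.log(1.2) / 10))
        for sex in ("F", "M"):
            res = le_loss(panel, att, unit="national", sex=sex)
            assert res.per_unit["loss_mean"].iloc[0] > 0.0

    def test_loss_matches_hand_built_lifetable_difference(self):
        """Two-age toy: deaths only at 0-4 and 85+; the loss must equal
        an independently coded abridged-lifetable difference."""
        gamma = float(np.log(1.3) / 10)
        panel = build_toy_panel(
            populations=[900_000], pms=[12.8], years=(2015, 2015),
            cardio_rate=0.0, allcause_rate=0.0,
        )
        d = panel.demography
        pop = d["population"].iloc[0]
        mask_young = d["age_group"] == "0-4"
        mask_old = d["age_group"] == "85+"
        d.loc[mask_young, ["cardio_deaths", "allcause_deaths"]] = [50, 100]
        d.loc[mask_old, ["cardio_deaths", "allcause_deaths"]] = [
            int(0.15 * pop), int(0.18 * pop)
        ]
        att = scenario_attribution(
            panel, fixed_fits(gamma), floor_scenario(panel, floor=2.8),
            n_draws=4, rng=np.random.default_rng(1),
        )
        res = le_loss(panel, att, unit="national", sex="F")

        def hand_e0(m_sched):
            # independent abridged lifetable: flat 85+ extension applies
            # because rates below 85 are zero at ages 60-84
            rates = np.concatenate([m_sched[:-1], np.full(6, m_sched[-1])])
            a = np.full(23, 2.5)
            a[0] = 2.0
            q = 5 * rates / (1 + (5 - a) * rates)
            q = np.clip(q, 0, 1)
            l = np.concatenate([[1.0], np.cumprod(1 - q[:-1])])
            dd = l * q
            dd[-1] = l[-1]
            L = np.empty(23)
            L[:-1] = 5 * (l[:-1] - dd[:-1]) + a[:-1] * dd[:-1]
            L[-1] = l[-1] / rates[-1]
            return L.sum()

        m_obs = np.zeros(18)
        m_obs[0] = 100 / pop
        m_obs[-1] = 0.18
        delta = 2.8 - 12.8
        av_young = 50 * (1 - np.exp(gamma * delta))
        av_old = int(0.15 * pop) * (1 - np.exp(gamma * delta))
        m_cf = np.zeros(18)
        m_cf[0] = (100 - av_young) / pop
        m_cf[-1] = (int(0.18 * pop) - av_old) / pop
        expected = hand_e0(m_cf) - hand_e0(m_obs)
        assert res.per_unit["loss_mean"].iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_national_loss_lies_within_county_envelope(self):
        panel, att = self._panel_and_attribution(float(np.log(1.15) / 10))
        nat = le_loss(panel, att, unit="national", sex="M").per_unit
        cty = le_loss(panel, att, unit="county", sex="M").per_unit
        lo, hi = cty["loss_mean"].min(), cty["loss_mean"].max()
        assert lo - 1e-9 <= nat["loss_mean"].iloc[0] <= hi + 1e-9

    def test_pathological_draws_are_clipped_and_flagged(self):
        # gamma so large that averted would exceed cardiorespiratory deaths
        panel, att = self._panel_and_attribution(0.5)
        res = le_loss(panel, att, unit="national", sex="F")
        assert res.clipped_cells >= 0
        cf = res.per_unit["counterfactual_e0"].iloc[0]
        assert np.isfinite(cf)
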