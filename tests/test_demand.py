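import numpy as np
import pandas as pd
import pytest

from excisesim.config import MacroPath, Market, SegmentSpec
from excisesim.demand import (
    SimulationError,
    cross_wiring,
    decompose,
    simulate_consumption,
)
from excisesim.fixtures import FixtureSpec, generate_macro, generate_market
from excisesim.policy import ScenarioSpec, schedule_explicit, schedule_fixed_growth
from excisesim.prices import price_paths


def flat_macro(base=2023, years=4, population_growth=0.0):
    idx = range(base, base + years)
    return MacroPath(
        base_year=base,
        inflation=pd.Series(0.0, index=idx),
        income_growth=pd.Series(0.0, index=idx),
        population_growth=pd.Series(population_growth, index=idx),
    )


def single_segment_market(elasticity=-1.0):
    seg = SegmentSpec(
        name="only", baseline_retail_price=50.0, baseline_consumption=100.0,
        market_share=1.0, excise=10.0, vat_rate=0.0,
        own_price_elasticity=elasticity, income_elasticity=0.0,
    )
    return Market(base_year=2023, segments=(seg,))


class TestCrossWiring:
    def test_adjacent_wiring_down_the_price_ladder(self, market):
        assert cross_wiring(market) == {
            "imported": None,
            "most-sold": "imported",
            "economy": "most-sold",
            "illicit": "economy",
        }

    def test_two_segment_market(self):
        spec = FixtureSpec(n_segments=2, include_pegged=False)
        m = generate_market(spec, seed=7)
        cheap, dear = m.names[1], m.names[0]
        assert cross_wiring(m) == {dear: None, cheap: dear}

    def test_override_respected(self, market):
        wiring = cross_wiring(market, overrides={"illicit": "most-sold"})
        assert wiring["illicit"] == "most-sold"
        with pytest.raises(ValueError):
            cross_wiring(market, overrides={"imported": "economy"})


class TestAnnualUpdate:
    def test_status_quo_consumption_keeps_growing(self, results_linear):
        total = results_linear["status-quo"].total_consumption
        assert total.loc[2023] == pytest.approx(107.36)
        # published simulation reports 136.11 million packs by 2028
        assert total.loc[2028] == pytest.approx(136.11, rel=1e-3)

    def test_stringent_totals_bracket_published_value(
        self, results_linear, results_power
    ):
        lin = results_linear["stringent"].total_consumption.loc[2028]
        pow_ = results_power["stringent"].total_consumption.loc[2028]
        assert lin < 96.98 < pow_

    def test_everything_frozen_means_constant_consumption(self):
        m = single_segment_market()
        macro = flat_macro()
        schedule = schedule_fixed_growth(m, macro, growth=0.0)
        scenario = ScenarioSpec("flat", schedule, {"only": 1.0})
        paths = price_paths(m, scenario, macro)
        q, _ = simulate_consumption(m, paths, macro)
        np.testing.assert_allclose(q["only"], 100.0)

    def test_unit_elasticity_ten_percent_price_rise(self):
        # excise 10 -> 15 with VAT 0 and frozen margin lifts the price
        # from 50 to 55 (+10%); unit own-price elasticity cuts demand 10%
        m = single_segment_market(elasticity=-1.0)
        macro = flat_macro(years=2)
        schedule = schedule_explicit(m, macro, {2024: 15.0})
        scenario = ScenarioSpec("jump", schedule, {"only": 1.0})
        paths = price_paths(m, scenario, macro)
        assert paths["only"]["real_retail"].loc[2024] == pytest.approx(55.0)
        q, _ = simulate_consumption(m, paths, macro, form="linear")
        assert q["only"].loc[2024] == pytest.approx(90.0, rel=1e-12)

    def test_extreme_shock_raises_simulation_error(self):
        m = single_segment_market(elasticity=-1.2)
        macro = flat_macro(years=2)
        schedule = schedule_explicit(m, macro, {2024: 90.0})  # price x2.6
        scenario = ScenarioSpec("crash", schedule, {"only": 1.0})
        paths = price_paths(m, scenario, macro)
        with pytest.raises(SimulationError, match="smaller steps"):
            simulate_consumption(m, paths, macro, form="linear")


class TestProperties:
    def test_decomposition_additivity_machine_precision(
        self, results_linear, results_power
    ):
        for results in (results_linear, results_power):
            for result in results.values():
                totals = result.total_consumption
                np.testing.assert_allclose(
                    result.decomposition["total"],
                    totals.diff().dropna(),
                    atol=1e-9,
                )
                assert result.decomposition[
                    ["population", "income", "price"]
                ].sum().sum() == pytest.approx(
                    totals.iloc[-1] - totals.iloc[0], abs=1e-9
                )

    def test_zero_elasticities_grow_with_population(self):
        spec = FixtureSpec(
            n_segments=3,
            include_pegged=False,
            own_price_range=(0.0, 0.0),
            income_range=(0.0, 0.0),
            cross_range=(0.0, 0.0),
        )
        m = generate_market(spec, seed=11)
        macro = generate_macro(spec, seed=12)
        schedule = schedule_fixed_growth(m, macro, growth=0.25)
        scenario = ScenarioSpec("taxed", schedule, {})
        paths = price_paths(m, scenario, macro)
        q, _ = simulate_consumption(m, paths, macro)
        growth = float((1.0 + macro.population_growth.iloc[1:]).prod())
        assert q.sum(axis=1).iloc[-1] / q.sum(axis=1).iloc[0] == pytest.approx(
            growth, rel=1e-12
        )

    def test_raising_the_tax_weakly_lowers_legal_consumption(
        self, results_linear
    ):
        low = results_linear["status-quo"].legal_consumption
        high = results_linear["stringent"].legal_consumption
        assert (high <= low + 1e-12).all()

    def test_brute_force_oracle_matches_engine(self, market, macro, scenarios):
        """Re-apply the factors one segment-year at a time with plain floats."""
        scenario = scenarios["over-shift"]
        paths = price_paths(market, scenario, macro)
        q, _ = simulate_consumption(market, paths, macro, form="linear")

        source = {
            "imported": None, "most-sold": "imported",
            "economy": "most-sold", "illicit": "economy",
        }
        state = {s.name: s.baseline_consumption for s in market.segments}
        for year in macro.years[1:]:
            nxt = {}
            for s in market.segments:
                p = paths[s.name]["real_retail"]
                f = 1.0 + s.own_price_elasticity * (p[year] / p[year - 1] - 1.0)
                if source[s.name] is not None:
                    ps = paths[source[s.name]]["real_retail"]
                    f *= 1.0 + s.cross_price_elasticity * (ps[year] / ps[year - 1] - 1.0)
                f *= 1.0 + s.income_elasticity * macro.income_growth[year]
                f *= 1.0 + macro.population_growth[year]
                nxt[s.name] = state[s.name] * f
            state = nxt
            for name, value in state.items():
                assert q[name].loc[year] == pytest.approx(value, rel=1e-12)

    def test_linear_and_power_agree_to_first_order(self):
        # shocks below 1% per year: the two forms differ by < 0.02%
        spec = FixtureSpec(
            n_segments=3,
            include_pegged=False,
            inflation_range=(0.0, 0.008),
            income_growth_range=(0.0, 0.008),
            pop_growth_range=(0.0, 0.008),
        )
        m = generate_market(spec, seed=3)
        macro = generate_macro(spec, seed=4)
        schedule = schedule_fixed_growth(m, macro, growth=0.005)
        scenario = ScenarioSpec("gentle", schedule, {})
        paths = price_paths(m, scenario, macro)
        q_lin, _ = simulate_consumption(m, paths, macro, form="linear")
        q_pow, _ = simulate_consumption(m, paths, macro, form="power")
        ratio = q_lin.sum(axis=1).iloc[-1] / q_pow.sum(axis=1).iloc[-1]
        assert abs(ratio - 1.0) < 2e-4


class TestDecomposition:
    def test_contributions_sum_to_the_change_exactly(self, results_linear):
        for result in results_linear.values():
            ledger = decompose(result.consumption, result.factors)
            np.testing.assert_allclose(
                ledger["total"],
                result.total_consumption.diff().dropna(),
                atol=1e-12,
            )

    def test_status_quo_buckets_match_published_attribution(self, results_linear):
        cum = results_linear["status-quo"].decomposition_cumulative
        assert cum["population"] == pytest.approx(14.52, rel=0.05)
        assert cum["income"] == pytest.approx(12.84, rel=0.05)
        assert cum["price"] == pytest.approx(1.39, rel=0.05)
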