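import numpy as np
import pandas as pd
import pytest

from dairygap.herd import (
    BreedParams,
    HerdState,
    ScenarioConfig,
    ScenarioValidationError,
    annual_economics,
    conception_probability,
    herd_management_step,
    monthly_mortality,
    reproduction_and_mortality_step,
    run_scenario,
)
from dairygap.nutrition import FeedResource, RationPolicy

ZEBU = BreedParams("zebu", 350.0, 22.0, 3.0, 6, 0.05, 36, 0.25)


def make_config(**over):
    feeds = {
        "straw": FeedResource("straw", 0.9, 6.5, 0.06, price=2.0, monthly_supply=0.0, purchasable=True),
        "hay": FeedResource("hay", 0.88, 8.5, 0.16, price=4.0, monthly_supply=0.0, purchasable=True),
    }
    ration = RationPolicy(
        {
            "breeder": [("straw", 6.0), ("hay", 1.5)],
            "heifer": [("straw", 3.0), ("hay", 0.5)],
            "female_calf": [("hay", 1.0)],
            "male_calf": [("hay", 0.5)],
            "growing_male": [("straw", 2.0)],
        }
    )
    cfg = dict(
        name="test", region="test", breed=ZEBU, min_breeders=3, max_breeders=5,
        feeds=feeds, ration=ration, male_sale_age=1, male_sale_weight=0.0,
        cull_age=132, base_mortality=0.05, milk_price=10.0,
        animal_prices={"cull_breeder": 7000.0, "heifer": 5000.0, "female_calf": 1000.0,
                       "male_calf": 800.0, "growing_male": 4000.0},
        health_mating_cost=200.0, currency="ETB", horizon=240,
    )
    cfg.update(over)
    return ScenarioConfig(**cfg)


class TestReproductionAndMortality:
    def test_conception_probability_logistic_midpoint(self):
        assert conception_probability(0.8) == pytest.approx(0.35 / 2)
        assert conception_probability(1.2) < 0.35
        assert conception_probability(0.4) < conception_probability(0.9)

    def test_poor_condition_raises_mortality(self):
        # condition 0.6: annualised extra mortality = 0.02 x 0.15 x 12 = 3.6 points
        base = 0.10
        annual = monthly_mortality(base, 0.6) * 12
        assert annual == pytest.approx(base + 0.036)
        assert monthly_mortality(base, 1.0) * 12 == pytest.approx(base)

    def test_step_bookkeeping(self):
        cfg = make_config()
        state = HerdState.initial(cfg)
        state.preg[-1] = 1.0  # one cow due to calve
        opening = state.total_head()
        rate = monthly_mortality(cfg.base_mortality, 0.9)
        flows = reproduction_and_mortality_step(state, cfg)
        assert flows["calvings"] == pytest.approx(1.0 - rate)  # mortality applies first
        assert flows["births"] == pytest.approx(1.0 - rate)
        assert state.lact[0] == pytest.approx(1.0 - rate)
        assert state.total_head() == pytest.approx(opening + flows["births"] - flows["deaths"])

    def test_expected_calving_interval_at_high_condition(self):
        # anoestrus + gestation + geometric wait: 2 + 9 + 1/p(1.0) ~ 14 months
        p = conception_probability(1.0)
        assert 9 + 2 + 1 / p == pytest.approx(14.1, abs=0.3)


class TestHerdManagement:
    def test_max_bound_enforced(self):
        cfg = make_config(min_breeders=3, max_breeders=5)
        state = HerdState.initial(cfg)
        state.breeders = 6.0
        sales = herd_management_step(state, cfg)
        assert state.breeders == pytest.approx(cfg.max_breeders)
        # age culling and the cap together remove exactly the one excess head
        assert sales["cull_breeder"] == pytest.approx(1.0)

    def test_male_sale_rule_age_and_weight(self):
        cfg = make_config(male_sale_age=12, male_sale_weight=180.0)
        state = HerdState.initial(cfg)
        state.male_count[:] = 0
        state.male_count[12] = 2.0
        state.male_weight[12] = 185.0
        state.male_count[13] = 1.0
        state.male_weight[13] = 150.0  # too light: held back
        sales = herd_management_step(state, cfg)
        assert sales["growing_male"] == pytest.approx(2.0)
        assert state.male_count[14] == pytest.approx(1.0)  # aged one month, unsold

    def test_no_triggers_leaves_herd_unchanged(self):
        cfg = make_config(male_sale_age=12, cull_age=10**9)
        state = HerdState.initial(cfg)
        state.female_count[:] = 0.0
        state.male_count[:] = 0.0
        state.breeders = 4.0
        before = state.total_head()
        sales = herd_management_step(state, cfg)
        assert sum(sales.values()) == pytest.approx(0.0, abs=1e-6)
        assert state.total_head() == pytest.approx(before)

    def test_surplus_female_weaners_sold(self):
        cfg = make_config(max_breeders=4)
        state = HerdState.initial(cfg)
        state.female_count[:] = 0.0
        state.female_count[5] = 10.0  # large weaner cohort
        sales = herd_management_step(state, cfg)
        assert sales["female_calf"] > 0


class TestAnnualEconomics:
    def _year(self, milk=0.0, feed_cost=0.0, herd=5.0, **sold):
        rows = pd.DataFrame(
            {
                "milk_kg": [milk / 12] * 12,
                "feed_cost": [feed_cost / 12] * 12,
                "herd_total": [herd] * 12,
            }
        )
        for cls in ("cull_breeder", "heifer", "female_calf", "male_calf", "growing_male"):
            rows[f"sold_{cls}"] = sold.get(cls, 0.0) / 12
        return rows

    def test_feed_only_is_negative(self):
        cfg = make_config()
        assert annual_economics(self._year(feed_cost=5000.0), cfg) < 0

    def test_arithmetic(self):
        cfg = make_config(milk_price=10.0, health_mating_cost=0.0)
        profit = annual_economics(self._year(milk=1000.0, feed_cost=4000.0, herd=0.0), cfg)
        assert profit == pytest.approx(6000.0)

    def test_milk_income_linear_in_price(self):
        year = self._year(milk=2000.0, feed_cost=1000.0)
        p1 = annual_economics(year, make_config(milk_price=10.0))
        p2 = annual_economics(year, make_config(milk_price=20.0))
        assert p2 - p1 == pytest.approx(2000.0 * 10.0)

    def test_needs_twelve_months(self):
        with pytest.raises(ValueError):
            annual_economics(self._year().iloc[:6], make_config())


class TestRunScenario:
    def test_starvation_collapses_production(self):
        feeds = {"straw": FeedResource("straw", 0.9, 6.5, 0.04, price=2.0,
                                       monthly_supply=0.0, purchasable=False)}
        ration = RationPolicy({"breeder": [("straw", 0.1)]})
        cfg = make_config(feeds=feeds, ration=ration, health_mating_cost=500.0)
        res = run_scenario(cfg)
        assert res.milk_per_farm_year < 50.0
        assert res.annual_profit < 0
        assert res.herd_size < 6.0

    def test_head_count_conservation_every_month(self):
        res = run_scenario(make_config())
        tr = res.monthly_trace
        resid = tr["opening_head"] + tr["births"] - tr["deaths"] - tr["sold_total"] - tr["closing_head"]
        assert np.abs(resid).max() < 1e-9

    def test_milk_per_cow_year_consistent_with_lactation(self):
        res = run_scenario(make_config())
        L = ZEBU.lactation_length
        assert res.milk_per_cow_year <= res.milk_per_cow_lactation * 12 / L + 1e-6

    def test_deterministic_rerun_identical(self):
        a = run_scenario(make_config())
        b = run_scenario(make_config())
        assert a.milk_per_farm_year == b.milk_per_farm_year
        assert a.annual_profit == b.annual_profit

    def test_stochastic_mode_seeded(self):
        a = run_scenario(make_config(), seed=42, stochastic=True)
        b = run_scenario(make_config(), seed=42, stochastic=True)
        c = run_scenario(make_config(), seed=43, stochastic=True)
        assert a.milk_per_farm_year == b.milk_per_farm_year
        assert a.milk_per_farm_year != c.milk_per_farm_year

    def test_invalid_ration_rejected_before_loop(self):
        cfg = make_config()
        cfg.ration.offers["breeder"].append(("unknown_feed", 1.0))
        with pytest.raises(ScenarioValidationError):
            run_scenario(cfg)
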