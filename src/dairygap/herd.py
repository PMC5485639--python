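"""Monthly bio-economic simulation of a smallholder dairy household.

A cohort-structured herd (breeders, heifers, calves, growing males) is
advanced month by month over a multi-year horizon: feed allocation,
energy/protein-limited milk production and liveweight change, condition-
dependent reproduction and mortality, management rules (breeder bounds,
male sale rules, culling, replacement retention), and annual livestock
profit. Dynamics are deterministic expected-value flows over continuous
(fractional) cohort counts by default; a seeded integer-stochastic mode is
available.

The breeder pool carries two stage pipelines — months of gestation and
months of lactation — rather than per-cow records; a cow may appear in both
(mid-lactation conception), which is exactly the information the energy and
calving accounting needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .nutrition import (
    DAYS_PER_MONTH,
    E_GAIN,
    E_MOBILIZED,
    GESTATION_MONTHS,
    K_G,
    MAX_GAIN,
    FeedResource,
    Intake,
    RationPolicy,
    allocate_feed,
    growth_step,
    maintenance_energy,
    milk_yield_step,
    pregnancy_energy,
)

__all__ = [
    "BreedParams",
    "ScenarioConfig",
    "HerdState",
    "SimulationResult",
    "reproduction_and_mortality_step",
    "herd_management_step",
    "annual_economics",
    "run_scenario",
]

WEANING_AGE = 6          # months; calves become heifers / growing males
MAX_YOUNG_AGE = 72       # bookkeeping ceiling for young-stock age arrays
ANOESTRUS_MONTHS = 2     # post-partum months with no conception
CONCEPTION_PMAX = 0.35   # maximum monthly conception probability
CONCEPTION_SLOPE = 12.0  # logistic steepness on body condition
CONCEPTION_MID = 0.8     # condition at half-maximal conception
COND_MORT_SLOPE = 0.02   # extra monthly mortality per unit condition below threshold
COND_MORT_THRESHOLD = 0.75
REPLACEMENT_MARGIN = 1.5  # retain heifer pipeline up to this multiple of max breeders
MALE_SALE_FAILSAFE = 24   # months past the sale age after which males sell regardless of weight
BURN_IN_YEARS = 5


class ScenarioValidationError(ValueError):
    """The scenario configuration is internally inconsistent."""


@dataclass(frozen=True)
class BreedParams:
    """Breed-level production parameters."""

    name: str
    mature_weight: float          # kg standard reference weight (SRW)
    birth_weight: float           # kg
    potential_peak_milk: float    # kg/day at mature weight and full condition
    lactation_length: int         # months
    milk_fat: float               # fraction of fresh milk
    age_first_mating: int         # months
    growth_rate_potential: float  # kg/day for growing stock

    def __post_init__(self) -> None:
        if self.mature_weight <= 0:
            raise ValueError("mature_weight must be positive")
        if not (0.0 < self.milk_fat <= 0.12):
            raise ValueError("milk_fat out of (0, 0.12]")
        if not (4 <= self.lactation_length <= 12):
            raise ValueError("lactation_length out of [4, 12] months")


@dataclass
class ScenarioConfig:
    """One household scenario: breed, feed basket, ration, bounds, prices."""

    name: str
    region: str
    breed: BreedParams
    min_breeders: float
    max_breeders: float
    feeds: dict[str, FeedResource]
    ration: RationPolicy
    male_sale_age: int          # months
    male_sale_weight: float     # kg; 0 disables the weight condition
    cull_age: int               # months
    base_mortality: float       # fraction per year
    milk_price: float           # currency per kg
    animal_prices: dict[str, float]  # by class: cull_breeder, heifer, female_calf, male_calf, growing_male
    health_mating_cost: float   # currency per head per year
    currency: str = "ETB"
    horizon: int = 240          # months

    def validate(self) -> None:
        if self.min_breeders > self.max_breeders:
            raise ScenarioValidationError(f"{self.name}: min_breeders > max_breeders")
        if self.horizon % 12 != 0:
            raise ScenarioValidationError(f"{self.name}: horizon must be a multiple of 12")
        missing = self.ration.feeds_used() - set(self.feeds)
        if missing:
            raise ScenarioValidationError(f"{self.name}: ration references unknown feeds {sorted(missing)}")
        for cls in self.ration.offers:
            if cls not in ("breeder", "heifer", "female_calf", "male_calf", "growing_male"):
                raise ScenarioValidationError(f"{self.name}: unknown animal class {cls!r}")


@dataclass
class HerdState:
    """Cohort-structured herd state at the start of a month."""

    breeders: float
    breeder_weight: float
    preg: np.ndarray   # len 9; preg[g] = breeders in gestation month g+1
    lact: np.ndarray   # len L; lact[l] = breeders in lactation month l+1
    female_count: np.ndarray  # young females by age month (0..MAX_YOUNG_AGE)
    female_weight: np.ndarray
    male_count: np.ndarray
    male_weight: np.ndarray
    stocks: dict[str, float] = field(default_factory=dict)
    month_index: int = 0

    @classmethod
    def initial(cls, config: ScenarioConfig) -> "HerdState":
        breed = config.breed
        b0 = 0.5 * (config.min_breeders + config.max_breeders)
        L = breed.lactation_length
        preg = np.zeros(GESTATION_MONTHS)
        preg[:] = 0.3 * b0 / GESTATION_MONTHS  # seed the pipeline so calvings start early
        fc = np.zeros(MAX_YOUNG_AGE + 1)
        fw = np.full(MAX_YOUNG_AGE + 1, breed.birth_weight)
        # seed a replacement pipeline of heifers at age-appropriate weights
        for age in range(WEANING_AGE, breed.age_first_mating, 6):
            fc[age] = 0.3 * b0 / max(1, (breed.age_first_mating - WEANING_AGE) // 6)
        for age in range(MAX_YOUNG_AGE + 1):
            fw[age] = min(
                breed.mature_weight,
                breed.birth_weight + 0.8 * breed.growth_rate_potential * DAYS_PER_MONTH * age,
            )
        mc = np.zeros(MAX_YOUNG_AGE + 1)
        mw = fw.copy()
        return cls(
            breeders=b0,
            breeder_weight=0.9 * breed.mature_weight,
            preg=preg,
            lact=np.zeros(L),
            female_count=fc,
            female_weight=fw,
            male_count=mc,
            male_weight=mw,
            stocks={name: 0.0 for name in config.feeds},
        )

    def class_counts(self) -> dict[str, float]:
        return {
            "breeder": self.breeders,
            "female_calf": float(self.female_count[:WEANING_AGE].sum()),
            "heifer": float(self.female_count[WEANING_AGE:].sum()),
            "male_calf": float(self.male_count[:WEANING_AGE].sum()),
            "growing_male": float(self.male_count[WEANING_AGE:].sum()),
        }

    def total_head(self) -> float:
        return self.breeders + float(self.female_count.sum()) + float(self.male_count.sum())


@dataclass
class SimulationResult:
    """Horizon-averaged summary plus the full monthly trace."""

    scenario: str
    region: str
    herd_size: float
    calving_interval: float       # months
    milk_per_cow_lactation: float
    milk_per_cow_year: float
    milk_per_farm_year: float
    turnoff: float                # head sold per year
    mortality_pct: float          # % of mean herd per year
    annual_profit: float
    currency: str
    monthly_trace: pd.DataFrame = field(repr=False, default=None)
    annual_profits: list[float] = field(repr=False, default_factory=list)


def _young_condition(weight: np.ndarray, ages: np.ndarray, breed: BreedParams) -> np.ndarray:
    """Weight relative to the age-appropriate target, used for mortality."""
    target = np.minimum(
        breed.mature_weight,
        breed.birth_weight + breed.growth_rate_potential * DAYS_PER_MONTH * ages,
    )
    return weight / np.maximum(target, 1e-9)


def conception_probability(condition: float) -> float:
    """Monthly conception probability of an open, cycling breeder."""
    return CONCEPTION_PMAX / (1.0 + math.exp(-CONCEPTION_SLOPE * (condition - CONCEPTION_MID)))


def monthly_mortality(base_mortality: float, condition: float) -> float:
    """Monthly mortality: baseline plus a penalty for poor condition."""
    return base_mortality / 12.0 + COND_MORT_SLOPE * max(0.0, COND_MORT_THRESHOLD - condition)


def reproduction_and_mortality_step(
    state: HerdState,
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Apply mortality, conception, gestation advance and calving in place.

    Returns flow bookkeeping: births, deaths, calvings, conceptions.
    """
    breed = config.breed
    condition = min(state.breeder_weight / breed.mature_weight, 1.2)

    # --- mortality (every cohort) ---
    deaths = 0.0
    rate_b = min(monthly_mortality(config.base_mortality, condition), 1.0)
    d_b = state.breeders * rate_b
    if rng is not None:
        d_b = min(float(rng.poisson(d_b)), state.breeders)
    frac_surv = 1.0 - (d_b / state.breeders if state.breeders > 0 else 0.0)
    state.breeders -= d_b
    state.preg *= frac_surv
    state.lact *= frac_surv
    deaths += d_b

    for count, weight in ((state.female_count, state.female_weight), (state.male_count, state.male_weight)):
        ages = np.arange(count.size)
        cond_y = _young_condition(weight, ages, breed)
        rates = np.minimum(
            config.base_mortality / 12.0 + COND_MORT_SLOPE * np.maximum(0.0, COND_MORT_THRESHOLD - cond_y),
            1.0,
        )
        d = count * rates
        if rng is not None:
            d = np.minimum(rng.poisson(d).astype(float), count)
        count -= d
        deaths += float(d.sum())

    # --- conception ---
    recently_calved = float(state.lact[:ANOESTRUS_MONTHS].sum())
    eligible = max(0.0, state.breeders - float(state.preg.sum()) - recently_calved)
    p = conception_probability(condition)
    conceptions = eligible * p
    if rng is not None:
        conceptions = min(float(rng.poisson(conceptions)), eligible)

    # --- advance pipelines: calve, then shift ---
    calvings = float(state.preg[-1])
    state.preg[1:] = state.preg[:-1]
    state.preg[0] = conceptions
    state.lact[1:] = state.lact[:-1]
    state.lact[0] = calvings

    # --- births (50:50 sex ratio) ---
    female_births = calvings / 2.0
    male_births = calvings / 2.0
    if rng is not None and calvings > 0:
        n = int(round(calvings))
        female_births = float(rng.binomial(n, 0.5))
        male_births = n - female_births
    state.female_count[0] += female_births
    state.male_count[0] += male_births
    state.female_weight[0] = breed.birth_weight
    state.male_weight[0] = breed.birth_weight

    return {
        "births": female_births + male_births,
        "deaths": deaths,
        "calvings": calvings,
        "conceptions": conceptions,
    }


def _scale_breeder_pipelines(state: HerdState, frac: float) -> None:
    state.preg *= frac
    state.lact *= frac


def herd_management_step(state: HerdState, config: ScenarioConfig) -> dict[str, float]:
    """Sales and promotions: male sale rule, replacement retention, promotion,
    culling, and breeder-bound enforcement. Returns heads sold by class."""
    breed = config.breed
    sales = {"male_calf": 0.0, "growing_male": 0.0, "female_calf": 0.0, "heifer": 0.0, "cull_breeder": 0.0}

    # males: sold at the configured age/weight rule (failsafe on age alone)
    ages = np.arange(state.male_count.size)
    sellable = (ages >= config.male_sale_age) & (state.male_weight >= config.male_sale_weight)
    sellable |= ages >= config.male_sale_age + MALE_SALE_FAILSAFE
    sell_m = state.male_count * sellable
    sales["male_calf"] += float(sell_m[:WEANING_AGE].sum())
    sales["growing_male"] += float(sell_m[WEANING_AGE:].sum())
    state.male_count[sellable] = 0.0

    # female calves beyond replacement needs sold at weaning
    heifers = float(state.female_count[WEANING_AGE:].sum())
    weaners = float(state.female_count[WEANING_AGE - 1])
    if weaners > 0:
        room = max(0.0, REPLACEMENT_MARGIN * config.max_breeders - state.breeders - heifers)
        keep = min(weaners, room)
        sales["female_calf"] += weaners - keep
        state.female_count[WEANING_AGE - 1] = keep

    # promotion to the breeding pool at age of first mating
    promote_mask = np.arange(state.female_count.size) >= breed.age_first_mating
    n_promote = float(state.female_count[promote_mask].sum())
    if n_promote > 0:
        w_promote = float(
            (state.female_count[promote_mask] * state.female_weight[promote_mask]).sum() / n_promote
        )
        total = state.breeders + n_promote
        state.breeder_weight = (
            state.breeders * state.breeder_weight + n_promote * w_promote
        ) / total
        state.breeders = total
        state.female_count[promote_mask] = 0.0

    # culling at cull age: steady-state turnover of the pool, suspended at the
    # minimum breeder bound (old cows are kept rather than dropping below it)
    cull_months = max(1, config.cull_age - breed.age_first_mating)
    culls = min(state.breeders / cull_months, max(0.0, state.breeders - config.min_breeders))
    if culls > 0 and state.breeders > 0:
        frac = 1.0 - culls / state.breeders
        state.breeders -= culls
        _scale_breeder_pipelines(state, frac)
        sales["cull_breeder"] += culls

    # enforce the maximum breeder bound
    if state.breeders > config.max_breeders:
        excess = state.breeders - config.max_breeders
        frac = config.max_breeders / state.breeders
        state.breeders = config.max_breeders
        _scale_breeder_pipelines(state, frac)
        sales["cull_breeder"] += excess

    # age the young stock one month (weights move with their cohort; the top
    # age bin accumulates so no head is lost off the end of the array)
    for count, weight in ((state.female_count, state.female_weight), (state.male_count, state.male_weight)):
        top_n, top_w = float(count[-1]), float(weight[-1])
        count[1:] = count[:-1]
        count[0] = 0.0
        weight[1:] = weight[:-1]
        weight[0] = breed.birth_weight
        if top_n > 0:
            merged = count[-1] + top_n
            weight[-1] = (count[-1] * weight[-1] + top_n * top_w) / merged
            count[-1] = merged

    return sales


def annual_economics(year_rows: pd.DataFrame, config: ScenarioConfig) -> float:
    """Livestock profit for one year of trace rows: milk and animal sales
    income minus purchased feed and health/mating costs. On-farm feed carries
    no cost; labour is not costed."""
    if len(year_rows) != 12:
        raise ValueError("annual_economics needs exactly 12 months of trace")
    income_milk = year_rows["milk_kg"].sum() * config.milk_price
    income_sales = 0.0
    for cls, price in config.animal_prices.items():
        col = f"sold_{cls}"
        if col in year_rows:
            income_sales += year_rows[col].sum() * price
    costs = year_rows["feed_cost"].sum()
    costs += config.health_mating_cost * year_rows["herd_total"].mean()
    return float(income_milk + income_sales - costs)


def _step_month(
    state: HerdState,
    config: ScenarioConfig,
    rng: np.random.Generator | None,
) -> dict[str, float]:
    """One full month: feed → milk/weights → reproduction/mortality → management."""
    breed = config.breed
    opening = state.total_head()

    counts = state.class_counts()
    intakes, state.stocks, feed_records = allocate_feed(
        counts, config.ration, config.feeds, state.stocks, state.month_index % 12
    )

    # --- breeder nutrition and milk ---
    milk_kg = 0.0
    mobilized_kg = 0.0
    breeder_me_total = 0.0
    if state.breeders > 0:
        bi: Intake = intakes["breeder"]
        me_eff = bi.usable_me
        breeder_me_total = me_eff * state.breeders * DAYS_PER_MONTH
        preg_load = sum(
            state.preg[g] * pregnancy_energy(g + 1) for g in range(GESTATION_MONTHS)
        ) / state.breeders
        weight_delta = 0.0
        lactating = 0.0
        for l in range(breed.lactation_length):
            n_l = float(state.lact[l])
            if n_l <= 0:
                continue
            res = milk_yield_step(
                me_eff,
                bi.cp,
                state.breeder_weight,
                l + 1,
                preg_load,
                breed.potential_peak_milk,
                breed.mature_weight,
                breed.milk_fat,
                breed.lactation_length,
            )
            milk_kg += n_l * res.milk_kg_day * DAYS_PER_MONTH
            mobilized_kg += n_l * res.mobilized_kg_day * DAYS_PER_MONTH
            weight_delta += n_l * res.weight_delta_day
            lactating += n_l
        dry = max(0.0, state.breeders - lactating)
        if dry > 0:
            surplus = me_eff - maintenance_energy(state.breeder_weight) - preg_load
            if surplus >= 0:
                d = min(surplus * K_G / E_GAIN, MAX_GAIN)
            else:
                d = surplus / E_MOBILIZED
            weight_delta += dry * d
        state.breeder_weight += weight_delta / state.breeders * DAYS_PER_MONTH
        state.breeder_weight = float(
            np.clip(state.breeder_weight, 0.4 * breed.mature_weight, 1.1 * breed.mature_weight)
        )

    # --- young growth ---
    for count, weight, calf_cls, grown_cls in (
        (state.female_count, state.female_weight, "female_calf", "heifer"),
        (state.male_count, state.male_weight, "male_calf", "growing_male"),
    ):
        for age in np.nonzero(count > 0)[0]:
            cls = calf_cls if age < WEANING_AGE else grown_cls
            intake = intakes[cls]
            d = growth_step(float(weight[age]), intake.usable_me, breed.growth_rate_potential, breed.mature_weight)
            weight[age] = max(float(weight[age]) + d * DAYS_PER_MONTH, 0.5 * breed.birth_weight)

    flows = reproduction_and_mortality_step(state, config, rng)
    sales = herd_management_step(state, config)

    state.month_index += 1
    closing = state.total_head()
    row = {
        "month": state.month_index,
        "opening_head": opening,
        "closing_head": closing,
        "herd_total": closing,
        "breeders": state.breeders,
        "breeder_weight": state.breeder_weight,
        "condition": state.breeder_weight / breed.mature_weight,
        "milk_kg": milk_kg,
        "mobilized_kg": mobilized_kg,
        "breeder_me_mj": breeder_me_total,
        "births": flows["births"],
        "deaths": flows["deaths"],
        "calvings": flows["calvings"],
        "conceptions": flows["conceptions"],
        "feed_cost": sum(r.cost for r in feed_records),
        "feed_shortfall_kg": sum(r.shortfall for r in feed_records),
        "sold_total": sum(sales.values()),
    }
    for cls, n in sales.items():
        row[f"sold_{cls}"] = n
    for r in feed_records:
        row[f"feed_{r.feed}_opening"] = r.opening
        row[f"feed_{r.feed}_supply"] = r.supply
        row[f"feed_{r.feed}_purchased"] = r.purchased
        row[f"feed_{r.feed}_consumed"] = r.consumed
        row[f"feed_{r.feed}_closing"] = r.closing
    return row


def run_scenario(
    config: ScenarioConfig,
    seed: int | None = None,
    stochastic: bool = False,
) -> SimulationResult:
    """Simulate one scenario over its horizon and summarise.

    Summary statistics average over the horizon after a 5-year burn-in so the
    herd equilibrates from its arbitrary initial state. Deterministic by
    default (continuous cohorts, expected-value dynamics); ``stochastic=True``
    draws integer events from the given seed.
    """
    config.validate()
    rng = np.random.default_rng(seed) if stochastic else None
    state = HerdState.initial(config)
    rows = [_step_month(state, config, rng) for _ in range(config.horizon)]
    trace = pd.DataFrame(rows)

    start = min(BURN_IN_YEARS * 12, max(0, config.horizon - 12))
    rep = trace.iloc[start:]
    years = len(rep) / 12.0

    mean_breeders = float(rep["breeders"].mean())
    total_calvings = float(rep["calvings"].sum())
    total_milk = float(rep["milk_kg"].sum())
    calvings_per_breeder_year = (
        total_calvings / years / mean_breeders if mean_breeders > 0 else 0.0
    )
    if calvings_per_breeder_year > 0:
        calving_interval = min(12.0 / calvings_per_breeder_year, float(config.horizon))
    else:
        calving_interval = float(config.horizon)

    profits = [
        annual_economics(trace.iloc[y * 12 : (y + 1) * 12], config)
        for y in range(start // 12, config.horizon // 12)
    ]

    return SimulationResult(
        scenario=config.name,
        region=config.region,
        herd_size=float(rep["herd_total"].mean()),
        calving_interval=calving_interval,
        milk_per_cow_lactation=total_milk / total_calvings if total_calvings > 0 else 0.0,
        milk_per_cow_year=total_milk / years / mean_breeders if mean_breeders > 0 else 0.0,
        milk_per_farm_year=total_milk / years,
        turnoff=float(rep["sold_total"].sum()) / years,
        mortality_pct=100.0 * float(rep["deaths"].sum()) / years / max(float(rep["herd_total"].mean()), 1e-9),
        annual_profit=float(np.mean(profits)),
        currency=config.currency,
        monthly_trace=trace,
        annual_profits=profits,
    )
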