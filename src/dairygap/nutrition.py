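"""Ruminant feed supply and energy/protein nutrition.

Simplified feeding-standards forms drive the simulator: metabolisable-energy
(ME) maintenance scaling with metabolic liveweight, a late-gestation ramp,
energy- and protein-allowable milk production, and tissue mobilisation when
the diet cannot support the lactation-curve potential. Feeds are offered per
head per day (never ad libitum), drawn from on-farm stocks first; stockpiled
feeds carry over between months and purchasable feeds are bought when stocks
run out.

All energy values are MJ ME; weights are kg; feed offers are kg fresh weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "FeedResource",
    "RationPolicy",
    "FeedMonthRecord",
    "Intake",
    "maintenance_energy",
    "pregnancy_energy",
    "growth_energy",
    "milk_energy_density",
    "lactation_curve_fraction",
    "allocate_feed",
    "energy_requirements",
    "milk_yield_step",
    "growth_step",
]

# feeding-standards constants (simplified forms; see the methods note)
K_M = 0.7          # efficiency of ME use for maintenance
K_L = 0.6          # efficiency of ME use for lactation
K_G = 0.43         # efficiency of ME use for growth
MAINT_COEF = 0.26  # MJ ME per kg^0.75 per day, before dividing by K_M
PREG_PEAK = 12.0   # MJ/day at the end of gestation
E_GAIN = 35.0      # MJ tissue energy per kg liveweight gain
E_MOBILIZED = 28.0  # MJ milk-energy equivalent per kg tissue mobilised
MILK_PROTEIN = 0.033   # kg crude protein per kg milk
PROTEIN_EFF = 0.6      # efficiency of dietary CP use for milk protein
MOBILIZATION_SHARE = 0.2  # at most this share of a milk-energy deficit is buffered from tissue
CONDITION_FLOOR = 0.75    # mobilisation stops at this fraction of mature weight
MAX_GAIN = 0.5            # kg/day ceiling on adult compensatory gain
DAYS_PER_MONTH = 365.25 / 12.0
GESTATION_MONTHS = 9
RUMEN_CP_REQ = 0.07       # dietary CP fraction of DM below which fermentation is N-limited
RUMEN_FACTOR_FLOOR = 0.6  # usable-ME discount never falls below this


@dataclass
class FeedResource:
    """One feed: composition, price and on-farm monthly availability.

    ``monthly_supply`` is kg fresh available on-farm per calendar month —
    a scalar (flat), a 12-vector (seasonal), or 0 for purchased-only feeds.
    ``storable`` feeds (residues, hays, concentrates) stockpile across months;
    standing pasture and cut green feed do not.
    """

    name: str
    dm_fraction: float
    me_density: float  # MJ ME / kg DM
    cp_fraction: float  # crude protein fraction of DM
    price: float = 0.0  # currency per kg fresh
    monthly_supply: float | Sequence[float] = 0.0
    purchasable: bool = False
    storable: bool = True
    cp_monthly: Sequence[float] | None = None  # optional seasonal CP override

    def __post_init__(self) -> None:
        if not (0.0 < self.dm_fraction <= 1.0):
            raise ValueError(f"{self.name}: dm_fraction out of (0,1]")
        if not (4.0 <= self.me_density <= 14.0):
            raise ValueError(f"{self.name}: me_density out of [4,14] MJ/kg DM")
        if not (0.0 <= self.cp_fraction <= 0.5):
            raise ValueError(f"{self.name}: cp_fraction out of [0,0.5]")
        if self.cp_monthly is not None and len(self.cp_monthly) != 12:
            raise ValueError(f"{self.name}: cp_monthly must have 12 entries")

    def supply_in(self, calendar_month: int) -> float:
        if np.isscalar(self.monthly_supply):
            return float(self.monthly_supply)  # type: ignore[arg-type]
        return float(self.monthly_supply[calendar_month % 12])  # type: ignore[index]

    def cp_in(self, calendar_month: int) -> float:
        if self.cp_monthly is None:
            return self.cp_fraction
        return float(self.cp_monthly[calendar_month % 12])


@dataclass
class RationPolicy:
    """Offered kg fresh per head per day, by animal class.

    offers: class -> list of (feed name, kg fresh/head/day).
    """

    offers: dict[str, list[tuple[str, float]]]

    def __post_init__(self) -> None:
        for cls, items in self.offers.items():
            for feed, kg in items:
                if kg < 0:
                    raise ValueError(f"negative offer {feed}={kg} for class {cls}")

    def feeds_used(self) -> set[str]:
        return {feed for items in self.offers.values() for feed, _ in items}


@dataclass
class FeedMonthRecord:
    """Mass balance for one feed in one month (kg fresh)."""

    feed: str
    opening: float
    supply: float
    purchased: float
    consumed: float
    closing: float
    shortfall: float
    cost: float


@dataclass
class Intake:
    """Per-head daily nutrient intake for one animal class."""

    me: float = 0.0  # MJ ME/head/day
    cp: float = 0.0  # kg CP/head/day
    dm: float = 0.0  # kg DM/head/day

    @property
    def usable_me(self) -> float:
        """ME discounted for nitrogen-limited rumen fermentation.

        Microbial digestion needs roughly 7% CP in diet dry matter; below
        that, energy extraction falls off roughly in proportion, floored at
        a 40% discount. At or above 7% CP the ME is fully usable.
        """
        if self.dm <= 0:
            return self.me
        factor = min(1.0, (self.cp / self.dm) / RUMEN_CP_REQ)
        return self.me * max(factor, RUMEN_FACTOR_FLOOR)


def maintenance_energy(liveweight: float) -> float:
    """Daily maintenance requirement, MJ ME: 0.26 W^0.75 / k_m."""
    if liveweight <= 0:
        raise ValueError("liveweight must be positive")
    return MAINT_COEF * liveweight**0.75 / K_M


def pregnancy_energy(gestation_month: int) -> float:
    """Daily pregnancy requirement, MJ ME: 0 until the last trimester, then a
    linear ramp reaching 12 MJ/day in the final gestation month."""
    if gestation_month < 1 or gestation_month > GESTATION_MONTHS:
        return 0.0
    ramp_start = GESTATION_MONTHS - 3  # months 7,8,9 carry the load
    if gestation_month <= ramp_start:
        return 0.0
    return PREG_PEAK * (gestation_month - ramp_start) / 3.0


def growth_energy(gain_kg_per_day: float) -> float:
    """Daily ME cost of liveweight gain: Δw × 35 MJ/kg / k_g."""
    return max(gain_kg_per_day, 0.0) * E_GAIN / K_G


def milk_energy_density(fat_fraction: float) -> float:
    """MJ per kg fresh milk as a linear function of fat content."""
    return 38.6 * fat_fraction + 1.69


def lactation_curve_fraction(stage_month: int, lactation_length: int) -> float:
    """Flat-topped lactation curve: linear rise over month 1, plateau, linear
    decline over the last third of lactation. Returns the fraction of peak."""
    L = lactation_length
    if stage_month < 1 or stage_month > L:
        return 0.0
    decline = max(1, round(L / 3))
    plateau_end = L - decline
    if stage_month == 1 and plateau_end >= 1:
        return 0.5
    if stage_month <= plateau_end:
        return 1.0
    j = stage_month - plateau_end
    return max(0.0, 1.0 - j / (decline + 1))


def energy_requirements(
    liveweight: float,
    gestation_month: int = 0,
    gain_kg_per_day: float = 0.0,
) -> dict[str, float]:
    """Component ME requirements (MJ/head/day) for one animal.

    Lactation energy is not a fixed requirement — it is resolved in
    milk_yield_step from the energy actually available.
    """
    return {
        "maintenance": maintenance_energy(liveweight),
        "pregnancy": pregnancy_energy(gestation_month),
        "growth": growth_energy(gain_kg_per_day),
    }


def allocate_feed(
    class_counts: Mapping[str, float],
    policy: RationPolicy,
    feeds: Mapping[str, FeedResource],
    stocks: dict[str, float],
    calendar_month: int,
) -> tuple[dict[str, Intake], dict[str, float], list[FeedMonthRecord]]:
    """Allocate one month of feed to the herd.

    On-farm stock (carry-over plus this month's supply) is drawn first;
    purchases cover the remainder only for purchasable feeds, otherwise intake
    is truncated proportionally across classes. Returns per-class intakes,
    updated stocks, and per-feed mass-balance records.
    """
    intakes = {cls: Intake() for cls in class_counts}
    records: list[FeedMonthRecord] = []
    new_stocks = dict(stocks)

    # demand per feed (kg fresh for the month)
    demand: dict[str, float] = {}
    demand_by_class: dict[str, dict[str, float]] = {}
    for cls, count in class_counts.items():
        for feed_name, kg_day in policy.offers.get(cls, []):
            if feed_name not in feeds:
                raise KeyError(f"ration references unknown feed {feed_name!r}")
            amt = kg_day * count * DAYS_PER_MONTH
            demand[feed_name] = demand.get(feed_name, 0.0) + amt
            demand_by_class.setdefault(feed_name, {})[cls] = amt

    for feed_name, feed in feeds.items():
        opening = new_stocks.get(feed_name, 0.0)
        supply = feed.supply_in(calendar_month)
        available = opening + supply
        dem = demand.get(feed_name, 0.0)
        purchased = 0.0
        shortfall = 0.0
        if dem <= available:
            consumed = dem
        elif feed.purchasable:
            consumed = dem
            purchased = dem - available
        else:
            consumed = available
            shortfall = dem - available
        closing = available + purchased - consumed
        if not feed.storable:
            closing = 0.0  # standing/cut feed does not carry over
        new_stocks[feed_name] = closing
        cost = purchased * feed.price
        records.append(
            FeedMonthRecord(feed_name, opening, supply, purchased, consumed, closing, shortfall, cost)
        )

        if dem > 0 and consumed > 0:
            frac = consumed / dem
            cp = feed.cp_in(calendar_month)
            for cls, amt in demand_by_class.get(feed_name, {}).items():
                count = class_counts[cls]
                if count <= 0:
                    continue
                kg_fresh_day = amt * frac / (count * DAYS_PER_MONTH)
                dm = kg_fresh_day * feed.dm_fraction
                intakes[cls].me += dm * feed.me_density
                intakes[cls].cp += dm * cp
                intakes[cls].dm += dm

    return intakes, new_stocks, records


@dataclass
class MilkStepResult:
    milk_kg_day: float       # per head
    weight_delta_day: float  # kg per head per day
    mobilized_kg_day: float


def milk_yield_step(
    me_intake: float,
    cp_intake: float,
    liveweight: float,
    stage_month: int,
    pregnancy_load: float,
    peak_milk: float,
    mature_weight: float,
    fat_fraction: float,
    lactation_length: int,
) -> MilkStepResult:
    """Resolve daily milk yield for one lactating cow.

    Realised yield is the minimum of the lactation-curve potential (scaled by
    relative liveweight), the energy-allowable yield from ME above maintenance
    and pregnancy, and the protein-allowable yield. When energy limits milk,
    body tissue buffers up to 20% of the deficit at 28 MJ/kg mobilised, never
    below 0.75 × mature weight.
    """
    m = maintenance_energy(liveweight)
    e_milk = milk_energy_density(fat_fraction)
    surplus = me_intake - m - pregnancy_load
    y_energy = max(0.0, surplus) * K_L / e_milk
    y_protein = cp_intake * PROTEIN_EFF / MILK_PROTEIN
    potential = peak_milk * (liveweight / mature_weight) * lactation_curve_fraction(
        stage_month, lactation_length
    )
    target = min(potential, y_protein)

    mobilized = 0.0
    milk = min(y_energy, target)
    if milk < target:
        deficit_mj = (target - milk) * e_milk
        buffer_kg_day = max(0.0, liveweight - CONDITION_FLOOR * mature_weight) / DAYS_PER_MONTH
        mobilized = min(MOBILIZATION_SHARE * deficit_mj / E_MOBILIZED, buffer_kg_day)
        milk = min(target, milk + mobilized * E_MOBILIZED / e_milk)

    # weight change: maintenance deficit is met from tissue too; surplus beyond
    # milk requirements rebuilds condition
    delta = -mobilized
    if surplus < 0:
        delta += surplus / E_MOBILIZED  # surplus < 0: tissue covers maintenance
    else:
        leftover = surplus - milk * e_milk / K_L
        if leftover > 0:
            delta += min(leftover * K_G / E_GAIN, MAX_GAIN)
    return MilkStepResult(milk_kg_day=milk, weight_delta_day=delta, mobilized_kg_day=mobilized)


def growth_step(
    liveweight: float,
    me_intake: float,
    growth_potential: float,
    mature_weight: float,
) -> float:
    """Daily liveweight change of a growing animal (kg/day), energy-limited."""
    m = maintenance_energy(liveweight)
    surplus = me_intake - m
    if surplus >= 0:
        if liveweight >= mature_weight:
            return 0.0
        return min(growth_potential, surplus * K_G / E_GAIN)
    return surplus / E_MOBILIZED
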