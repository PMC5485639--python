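"""Scenario library, intervention transforms, and yield-gap integration.

Encodes the five regional household scenarios (Ethiopia lowland grazing,
highland rainfall-deficient and rainfall-sufficient; India rainfed and
irrigated) with their nutrition and genetics interventions. Intervention
parameter values live in the shipped YAML scenario files — the transforms
here are generic — so every quantity can be audited in one place.

The gap report joins the best modelled lactation yield against the top-decile
attainable yield from benchmarking for the same region.
"""

from __future__ import annotations

import copy
import importlib.resources as resources
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .benchmarking import BenchmarkResult
from .herd import BreedParams, ScenarioConfig, SimulationResult, run_scenario
from .nutrition import FeedResource, RationPolicy

__all__ = [
    "Intervention",
    "GapReport",
    "apply_intervention",
    "load_library",
    "load_region",
    "list_regions",
    "run_region",
    "gap_report",
    "rank_interventions",
]

ATOMIC_KINDS = {
    "improved_pasture",
    "concentrate",
    "improved_forage",
    "improved_genetics",
    "residue_quality",
    "green_feed",
}
N_TO_CP = 6.25  # crude protein = nitrogen × 6.25


class InterventionError(ValueError):
    """The intervention does not apply to this scenario's structure."""


@dataclass(frozen=True)
class Intervention:
    """One intervention: a kind plus its parameters.

    ``combination`` interventions carry an ordered list of atomic parts.
    """

    name: str
    kind: str
    params: dict = field(default_factory=dict)
    parts: tuple["Intervention", ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "combination":
            if not all(p.kind in ATOMIC_KINDS for p in self.parts):
                raise ValueError("combination parts must be atomic interventions")
        elif self.kind not in ATOMIC_KINDS:
            raise ValueError(f"unknown intervention kind {self.kind!r}")


def _set_offer(ration: RationPolicy, cls: str, feed: str, kg: float) -> None:
    items = ration.offers.setdefault(cls, [])
    for i, (f, _) in enumerate(items):
        if f == feed:
            items[i] = (feed, kg)
            return
    items.append((feed, kg))


def _require_feed(config: ScenarioConfig, feed: str, kind: str) -> FeedResource:
    if feed not in config.feeds:
        raise InterventionError(
            f"{kind}: scenario {config.name!r} declares no feed {feed!r}"
        )
    return config.feeds[feed]


def apply_intervention(config: ScenarioConfig, iv: Intervention) -> ScenarioConfig:
    """Return a new ScenarioConfig with the intervention applied.

    The input config is never mutated; combinations apply their parts in order.
    """
    cfg = copy.deepcopy(config)
    cfg.name = f"{config.region}/{iv.name}" if iv.name else config.name

    if iv.kind == "combination":
        for part in iv.parts:
            cfg = apply_intervention(cfg, Intervention(name="", kind=part.kind, params=part.params))
        cfg.name = f"{config.region}/{iv.name}"
        return cfg

    p = iv.params
    if iv.kind == "improved_pasture":
        feed = _require_feed(cfg, p["feed"], iv.kind)
        delta_cp = p.get("delta_n", 0.005) * N_TO_CP
        feed.cp_fraction = min(feed.cp_fraction + delta_cp, 0.5)
        if feed.cp_monthly is not None:
            cp = np.asarray(feed.cp_monthly, dtype=float)
            # halve the seasonal swing around the mean, then shift the mean up
            feed.cp_monthly = (cp.mean() + (cp - cp.mean()) / 2.0 + delta_cp).tolist()
    elif iv.kind in ("concentrate", "green_feed"):
        classes = p.get("classes", ["breeder"])
        for feed, kg in p.get("offers", {}).items():
            _require_feed(cfg, feed, iv.kind)
            for cls in classes:
                _set_offer(cfg.ration, cls, feed, float(kg))
    elif iv.kind == "improved_forage":
        for feed, updates in p.get("feed_updates", {}).items():
            fr = _require_feed(cfg, feed, iv.kind)
            for attr, value in updates.items():
                if not hasattr(fr, attr):
                    raise InterventionError(f"improved_forage: feed has no field {attr!r}")
                setattr(fr, attr, value)
        for feed, factor in p.get("scale_supply", {}).items():
            fr = _require_feed(cfg, feed, iv.kind)
            if np.isscalar(fr.monthly_supply):
                fr.monthly_supply = float(fr.monthly_supply) * factor
            else:
                fr.monthly_supply = [s * factor for s in fr.monthly_supply]
        classes = p.get("classes", ["breeder"])
        for feed, kg in p.get("offers", {}).items():
            _require_feed(cfg, feed, iv.kind)
            for cls in classes:
                _set_offer(cfg.ration, cls, feed, float(kg))
    elif iv.kind == "residue_quality":
        fr = _require_feed(cfg, p["feed"], iv.kind)
        fr.me_density = min(fr.me_density + p.get("delta_me", 1.0), 14.0)
        if "price" in p:
            fr.price = float(p["price"])
    elif iv.kind == "improved_genetics":
        breed = p["breed"]
        if not isinstance(breed, BreedParams):
            raise InterventionError("improved_genetics: breed must be resolved to BreedParams")
        cfg.breed = breed
        classes = p.get("classes", ["breeder"])
        for feed, kg in p.get("offers", {}).items():
            _require_feed(cfg, feed, iv.kind)
            for cls in classes:
                _set_offer(cfg.ration, cls, feed, float(kg))
    # parameters common to every kind (herd bounds, prices and class-specific
    # feeding often move together with an intervention in the scenario
    # descriptions)
    for cls, offers in p.get("class_offers", {}).items():
        for feed, kg in offers.items():
            _require_feed(cfg, feed, iv.kind)
            _set_offer(cfg.ration, cls, feed, float(kg))
    if "min_breeders" in p:
        cfg.min_breeders = float(p["min_breeders"])
    if "max_breeders" in p:
        cfg.max_breeders = float(p["max_breeders"])
    if "milk_price" in p:
        cfg.milk_price = float(p["milk_price"])
    if "animal_prices" in p:
        cfg.animal_prices = dict(cfg.animal_prices, **p["animal_prices"])
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# shipped scenario library


def _data_path() -> Path:
    return Path(str(resources.files("dairygap").joinpath("data")))


def load_library() -> dict:
    """Breed parameters and feed compositions shared by all scenarios."""
    with open(_data_path() / "library.yaml") as fh:
        lib = yaml.safe_load(fh)
    breeds = {
        name: BreedParams(name=name, **params) for name, params in lib["breeds"].items()
    }
    return {"breeds": breeds, "feeds": lib["feeds"]}


def list_regions() -> list[str]:
    return sorted(p.stem for p in (_data_path() / "scenarios").glob("*.yaml"))


def _build_feed(name: str, composition: Mapping, supply) -> FeedResource:
    kwargs = dict(composition)
    return FeedResource(name=name, monthly_supply=supply, **kwargs)


def _build_config(region_doc: Mapping, scen_doc: Mapping, library: Mapping, name: str) -> ScenarioConfig:
    feeds = {}
    for feed_name, spec in scen_doc["feeds"].items():
        comp = library["feeds"].get(feed_name)
        if comp is None:
            raise KeyError(f"feed {feed_name!r} not in the feed library")
        feeds[feed_name] = _build_feed(feed_name, comp, spec.get("supply", 0.0))
    ration = RationPolicy(
        offers={
            cls: [(feed, float(kg)) for feed, kg in offers.items()]
            for cls, offers in scen_doc["ration"].items()
        }
    )
    cfg = ScenarioConfig(
        name=f"{region_doc['region']}/{name}",
        region=region_doc["region"],
        breed=library["breeds"][scen_doc["breed"]],
        min_breeders=float(scen_doc["min_breeders"]),
        max_breeders=float(scen_doc["max_breeders"]),
        feeds=feeds,
        ration=ration,
        male_sale_age=int(scen_doc["male_sale_age"]),
        male_sale_weight=float(scen_doc.get("male_sale_weight", 0.0)),
        cull_age=int(scen_doc["cull_age"]),
        base_mortality=float(scen_doc["base_mortality"]),
        milk_price=float(scen_doc.get("milk_price", region_doc["milk_price"])),
        animal_prices=dict(region_doc["animal_prices"], **scen_doc.get("animal_prices", {})),
        health_mating_cost=float(region_doc["health_mating_cost"]),
        currency=region_doc["currency"],
        horizon=int(region_doc.get("horizon", 240)),
    )
    cfg.validate()
    return cfg


def _parse_intervention(doc: Mapping, library: Mapping) -> Intervention:
    params = dict(doc.get("params", {}))
    if "breed" in params:
        params["breed"] = library["breeds"][params["breed"]]
    parts = tuple(_parse_intervention(d, library) for d in doc.get("parts", []))
    return Intervention(name=doc["name"], kind=doc["kind"], params=params, parts=parts)


def load_region(region: str, library: Mapping | None = None) -> tuple[ScenarioConfig, list[Intervention]]:
    """Load a region's baseline config and its intervention list from the
    shipped scenario file."""
    library = library or load_library()
    path = _data_path() / "scenarios" / f"{region}.yaml"
    if not path.exists():
        raise FileNotFoundError(f"unknown region {region!r}; known: {list_regions()}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    baseline = _build_config(doc, doc["baseline"], library, "baseline")
    interventions = [_parse_intervention(d, library) for d in doc.get("interventions", [])]
    return baseline, interventions


def run_region(
    baseline: ScenarioConfig,
    interventions: Sequence[Intervention],
    seed: int | None = None,
    stochastic: bool = False,
) -> list[SimulationResult]:
    """Simulate the baseline and every intervention; results carry scenario labels."""
    results = []
    for label, cfg in [("baseline", baseline)] + [
        (iv.name, apply_intervention(baseline, iv)) for iv in interventions
    ]:
        try:
            res = run_scenario(cfg, seed=seed, stochastic=stochastic)
        except Exception as exc:  # attach the scenario label to simulator errors
            raise RuntimeError(f"scenario {cfg.name!r} failed") from exc
        res.scenario = label
        results.append(res)
    return results


@dataclass
class GapReport:
    """Modelled-versus-attainable comparison for one region."""

    region: str
    attainable_yield: float       # kg/cow/lactation, benchmark top decile
    best_modelled_yield: float    # kg/cow/lactation, best scenario
    best_scenario: str
    modelled_over_attainable: float  # percent
    exceeds_attainable: bool
    table: pd.DataFrame = field(repr=False, default=None)
    note: str = (
        "Benchmark and modelled yields may aggregate different survey states "
        "within the zone; the ratio is indicative, not farm-matched."
    )

    @property
    def modelled_over_attainable_rounded(self) -> int:
        return int(math.floor(self.modelled_over_attainable + 0.5))


def gap_report(results: Sequence[SimulationResult], benchmark: BenchmarkResult) -> GapReport:
    """Integrate simulation and benchmarking into a relative yield-gap report."""
    if benchmark.top_decile_mean <= 0:
        raise ValueError("attainable yield must be positive")
    best = max(results, key=lambda r: r.milk_per_cow_lactation)
    ratio = 100.0 * best.milk_per_cow_lactation / benchmark.top_decile_mean
    return GapReport(
        region=benchmark.zone,
        attainable_yield=benchmark.top_decile_mean,
        best_modelled_yield=best.milk_per_cow_lactation,
        best_scenario=best.scenario,
        modelled_over_attainable=ratio,
        exceeds_attainable=ratio > 100.0,
        table=results_table(results),
    )


def results_table(results: Sequence[SimulationResult]) -> pd.DataFrame:
    """Summary table with the simulation-output column layout."""
    return pd.DataFrame(
        {
            "scenario": [r.scenario for r in results],
            "herd_size_heads": [r.herd_size for r in results],
            "calving_interval_months": [r.calving_interval for r in results],
            "milk_kg_cow_lactation": [r.milk_per_cow_lactation for r in results],
            "milk_kg_cow_yr": [r.milk_per_cow_year for r in results],
            "milk_kg_farm_yr": [r.milk_per_farm_year for r in results],
            "turnoff_heads_yr": [r.turnoff for r in results],
            "mortality_pct": [r.mortality_pct for r in results],
            "annual_profit": [r.annual_profit for r in results],
        }
    )


def rank_interventions(
    results: Sequence[SimulationResult],
    key: str = "milk_per_farm_year",
) -> list[str]:
    """Scenario labels in descending order of the key (stable for ties)."""
    if len(results) < 2:
        raise ValueError("need at least two results to rank")
    if key not in ("milk_per_farm_year", "annual_profit"):
        raise ValueError(f"unsupported ranking key {key!r}")
    return [r.scenario for r in sorted(results, key=lambda r: -getattr(r, key))]
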