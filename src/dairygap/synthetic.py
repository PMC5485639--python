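"""Synthetic survey populations and fixture tables.

Everything the pipeline needs can be generated here without external data:
right-skewed per-farm milk-yield populations for benchmarking, multi-input /
multi-output farm populations drawn from a known Cobb-Douglas frontier with
normal noise and half-normal inefficiency (so estimator recovery can be
scored against truth), and the feed/price/scenario fixture files.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .scenarios import _data_path, list_regions, load_library, load_region
from .survey import FarmRecord, SurveyTable

__all__ = [
    "FrontierTruth",
    "gen_benchmark_population",
    "gen_frontier_population",
    "gen_fixtures",
    "lognormal_top_decile_ratio",
]


@dataclass(frozen=True)
class FrontierTruth:
    """True data-generating parameters for a frontier population."""

    alpha0: float
    beta: tuple[float, ...]          # coefficients on ln-inputs
    gamma_out: tuple[float, ...]     # coefficients on ln of normalised outputs
    sigma_v_sq: float
    sigma_u_sq: float

    def __post_init__(self) -> None:
        if self.sigma_v_sq < 0 or self.sigma_u_sq < 0:
            raise ValueError("variances must be non-negative")
        if sum(self.gamma_out) >= 1.0:
            raise ValueError("sum of output coefficients must be < 1 for a solvable frontier")

    @property
    def sigma_sq(self) -> float:
        return self.sigma_v_sq + self.sigma_u_sq

    @property
    def gamma(self) -> float:
        return self.sigma_u_sq / self.sigma_sq if self.sigma_sq > 0 else 0.0


def gen_benchmark_population(
    n: int,
    zone: str,
    median_yield: float,
    shape: float,
    seed: int,
) -> SurveyTable:
    """Log-normal per-farm milk yields for one zone.

    ``median_yield`` is the log-normal median (kg/head/lactation) and
    ``shape`` the log-scale standard deviation; large shapes reproduce the
    severalfold top-decile-to-mean ratios seen in smallholder survey data.
    """
    if n < 10:
        raise ValueError("need n >= 10 for a meaningful decile")
    if median_yield <= 0 or shape < 0:
        raise ValueError("median_yield must be positive and shape non-negative")
    rng = np.random.default_rng(seed)
    yields = median_yield * np.exp(shape * rng.standard_normal(n))
    records = [
        FarmRecord(farm_id=f"{zone}-{i:05d}", zone=zone, milk_yield=float(y))
        for i, y in enumerate(yields)
    ]
    return SurveyTable(records)


def lognormal_top_decile_ratio(shape: float) -> float:
    """Closed-form E[X | X > q_0.9] / E[X] for a log-normal with log-sd shape."""
    from scipy.stats import norm

    z90 = norm.ppf(0.9)
    return float(norm.cdf(shape - z90) / 0.1)


def gen_frontier_population(
    n: int,
    truth: FrontierTruth,
    seed: int,
    input_mu: tuple[float, ...] | None = None,
    input_sigma: float = 0.5,
    zone: str = "synthetic",
) -> tuple[SurveyTable, np.ndarray]:
    """Farms drawn from a known Cobb-Douglas output distance frontier.

    Inputs are log-normal, and so is the farm's output *mix* (the ratios of
    secondary outputs to the normalising output): drawing the mix exogenously
    keeps the normalised-output regressors independent of the composed error
    v + u (v normal, u half-normal), so the frontier identity pins down the
    normalising output and the secondary outputs follow from the mix. Returns
    the survey table and the true per-farm efficiencies exp(-u). The
    generator shares no code with the estimator.
    """
    if n < 50:
        raise ValueError("need n >= 50")
    rng = np.random.default_rng(seed)
    K = len(truth.beta)
    M = len(truth.gamma_out) + 1
    mu = np.zeros(K) if input_mu is None else np.asarray(input_mu, dtype=float)

    ln_x = mu + input_sigma * rng.standard_normal((n, K))
    ln_mix = 0.5 * rng.standard_normal((n, M - 1))  # ln(y_m / y_M), exogenous
    v = np.sqrt(truth.sigma_v_sq) * rng.standard_normal(n)
    u = np.abs(np.sqrt(truth.sigma_u_sq) * rng.standard_normal(n))

    # -ln yM = a0 + β·ln x + Σγ ln(y_m/y_M) + v + u
    g = np.asarray(truth.gamma_out, dtype=float)
    b = np.asarray(truth.beta, dtype=float)
    ln_yM = -(truth.alpha0 + ln_x @ b + ln_mix @ g + v + u)
    ln_y_sec = ln_mix + ln_yM[:, None]

    input_names = [f"x{k+1}" for k in range(K)]
    output_names = ["milk"] + [f"y{m+2}" for m in range(M - 1)]
    records = []
    for i in range(n):
        outputs = {"milk": float(np.exp(ln_yM[i]))}
        for m in range(M - 1):
            outputs[output_names[1 + m]] = float(np.exp(ln_y_sec[i, m]))
        inputs = {name: float(np.exp(ln_x[i, k])) for k, name in enumerate(input_names)}
        records.append(
            FarmRecord(
                farm_id=f"{zone}-{i:05d}",
                zone=zone,
                milk_yield=outputs["milk"],
                outputs=outputs,
                inputs=inputs,
            )
        )
    table = SurveyTable(records, output_names=output_names, input_names=input_names)
    return table, np.exp(-u)


def gen_fixtures(region: str, out_dir: str | Path | None = None):
    """Feed/price fixture tables and the validated scenario set for a region.

    Returns (feed_table, price_table, configs) where configs is the baseline
    plus every intervention applied. With ``out_dir`` the scenario file and
    tables are also written out (deterministically — no randomness involved).
    """
    from .scenarios import apply_intervention

    if region not in list_regions():
        raise KeyError(f"unknown region {region!r}; known: {list_regions()}")
    library = load_library()
    baseline, interventions = load_region(region, library)
    configs = [baseline] + [apply_intervention(baseline, iv) for iv in interventions]
    for cfg in configs:
        cfg.validate()

    feed_rows, price_rows = [], []
    for name, feed in baseline.feeds.items():
        feed_rows.append(
            {
                "feed": name,
                "dm_fraction": feed.dm_fraction,
                "me_mj_per_kg_dm": feed.me_density,
                "cp_fraction_dm": feed.cp_fraction,
                "purchasable": feed.purchasable,
                "storable": feed.storable,
            }
        )
        price_rows.append({"feed": name, "price_per_kg_fresh": feed.price, "currency": baseline.currency})
    price_rows.append(
        {"feed": "milk", "price_per_kg_fresh": baseline.milk_price, "currency": baseline.currency}
    )
    feed_table = pd.DataFrame(feed_rows)
    price_table = pd.DataFrame(price_rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        feed_table.to_csv(out / f"{region}_feeds.csv", index=False)
        price_table.to_csv(out / f"{region}_prices.csv", index=False)
        src = _data_path() / "scenarios" / f"{region}.yaml"
        (out / f"{region}.yaml").write_text(src.read_text())
    return feed_table, price_table, configs
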