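"""Top-decile benchmarking of attainable milk yields.

The attainable yield for an agricultural zone is estimated as the mean milk
yield of the top 10% most productive farms; the relative yield gap is the
difference between that and the mean over all farms, expressed in kg per head
per lactation and as a percent increase over the overall mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .survey import EmptyTableError, SurveyTable, group_by_zone

__all__ = [
    "BenchmarkResult",
    "select_top_decile",
    "compute_yield_gap",
    "benchmark_all",
    "results_to_frame",
]


@dataclass(frozen=True)
class BenchmarkResult:
    """Per-zone benchmarking summary (Table-2-shaped)."""

    zone: str
    n: int
    top_decile_mean: float
    overall_mean: float
    gap_abs: float
    gap_pct: float | None  # unrounded percent increase; None when overall mean is 0
    gap_pct_rounded: int | None = None


def _round_half_away(x: float) -> int:
    """Round half away from zero (matches the printed integer percent column)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def select_top_decile(yields: Sequence[float]) -> list[float]:
    """Return the ceil(n/10) largest values.

    Ties at the cutoff are broken by taking the earliest-indexed records, so
    the result has exactly ceil(n/10) elements.
    """
    y = np.asarray(yields, dtype=float)
    if y.size == 0:
        raise EmptyTableError("select_top_decile: empty input")
    if not np.all(np.isfinite(y)) or np.any(y < 0):
        raise ValueError("yields must be finite and non-negative")
    k = math.ceil(y.size / 10)
    # sort by descending yield, ascending original index for ties
    order = np.lexsort((np.arange(y.size), -y))
    return y[order[:k]].tolist()


def compute_yield_gap(group: SurveyTable, zone: str | None = None) -> BenchmarkResult:
    """Benchmark one zone: overall mean vs top-decile mean and the gap between them."""
    yields = group.milk_yields
    if not yields:
        raise EmptyTableError("compute_yield_gap: no records")
    zone = zone if zone is not None else group.records[0].zone
    overall = float(np.mean(yields))
    top = float(np.mean(select_top_decile(yields)))
    gap_abs = top - overall
    if overall > 0:
        gap_pct = 100.0 * gap_abs / overall
        return BenchmarkResult(zone, len(yields), top, overall, gap_abs, gap_pct, _round_half_away(gap_pct))
    return BenchmarkResult(zone, len(yields), top, overall, gap_abs, None, None)


def benchmark_all(table: SurveyTable) -> list[BenchmarkResult]:
    """One BenchmarkResult per zone, in lexicographic zone order."""
    groups = group_by_zone(table)
    return [compute_yield_gap(groups[z], zone=z) for z in sorted(groups)]


def results_to_frame(results: Sequence[BenchmarkResult]) -> pd.DataFrame:
    """Tabulate results with the benchmark table's column layout."""
    return pd.DataFrame(
        {
            "zone": [r.zone for r in results],
            "n_farms": [r.n for r in results],
            "top10pct_mean_kg": [r.top_decile_mean for r in results],
            "overall_mean_kg": [r.overall_mean for r in results],
            "gap_kg": [r.gap_abs for r in results],
            "gap_pct_increase": [r.gap_pct_rounded for r in results],
        }
    )
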