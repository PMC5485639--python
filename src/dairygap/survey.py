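"""Farm-survey data model and I/O.

Holds the per-household records consumed by the benchmarking and frontier
stages: a zone label, per-head milk yield (kg per head per lactation), and
ordered baskets of farm outputs and inputs. Records emulate the content of
smallholder dairy survey databases (household livestock counts, milk
production, land, feed, labour, capital) without committing to any one
database's native layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FarmRecord",
    "SurveyTable",
    "SurveySchema",
    "SchemaError",
    "EmptyTableError",
    "read_survey_csv",
    "write_survey_csv",
    "group_by_zone",
]


class SchemaError(ValueError):
    """A mapped column is missing from the CSV."""


class EmptyTableError(ValueError):
    """No usable rows remain after validation."""


@dataclass(frozen=True)
class FarmRecord:
    """One surveyed household.

    milk_yield is kg milk per head per lactation; outputs and inputs are
    ordered name→quantity mappings, all quantities non-negative.
    """

    farm_id: str
    zone: str
    milk_yield: float
    outputs: dict[str, float] = field(default_factory=dict)
    inputs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.milk_yield < 0:
            raise ValueError(f"milk_yield < 0 for farm {self.farm_id}")
        for name, q in {**self.outputs, **self.inputs}.items():
            if q < 0:
                raise ValueError(f"negative quantity {name}={q} for farm {self.farm_id}")


@dataclass
class SurveyTable:
    """A homogeneous collection of FarmRecords.

    All records share the same output and input name sets, in the same order.
    """

    records: list[FarmRecord]
    output_names: list[str] = field(default_factory=list)
    input_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        out_set, in_set = set(self.output_names), set(self.input_names)
        for rec in self.records:
            if set(rec.outputs) != out_set or set(rec.inputs) != in_set:
                raise ValueError(f"farm {rec.farm_id} has inconsistent output/input names")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def milk_yields(self) -> list[float]:
        return [r.milk_yield for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row: dict[str, object] = {"farm_id": r.farm_id, "zone": r.zone, "milk_yield": r.milk_yield}
            row.update({f"out_{k}": v for k, v in r.outputs.items()})
            row.update({f"in_{k}": v for k, v in r.inputs.items()})
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SurveySchema:
    """Maps survey CSV columns onto the FarmRecord fields.

    ``milk_per_farm`` declares that the milk column is a whole-farm total and
    must be divided by the cow-count column (``herd_col``) to obtain the
    per-head figure used everywhere downstream.
    """

    farm_col: str = "farm_id"
    zone_col: str = "zone"
    milk_col: str = "milk_yield"
    output_cols: Mapping[str, str] = field(default_factory=dict)  # name -> column
    input_cols: Mapping[str, str] = field(default_factory=dict)
    milk_per_farm: bool = False
    herd_col: str | None = None


def read_survey_csv(path: str | Path, schema: SurveySchema | None = None) -> SurveyTable:
    """Read a survey CSV into a SurveyTable, dropping invalid rows.

    Rows with missing or negative values in any mapped column are dropped and
    counted; the drop count is logged and attached as ``table.dropped``.
    Raises SchemaError for a missing mapped column and EmptyTableError when no
    usable rows remain.
    """
    schema = schema or SurveySchema()
    df = pd.read_csv(path, float_precision="round_trip")

    needed = [schema.farm_col, schema.zone_col, schema.milk_col]
    needed += list(schema.output_cols.values()) + list(schema.input_cols.values())
    if schema.milk_per_farm:
        if schema.herd_col is None:
            raise SchemaError("milk_per_farm requires herd_col")
        needed.append(schema.herd_col)
    for col in needed:
        if col not in df.columns:
            raise SchemaError(f"mapped column {col!r} not present in {path}")

    numeric_cols = [c for c in needed if c not in (schema.farm_col, schema.zone_col)]
    for col in numeric_cols:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    n_read = len(df)
    valid = df[numeric_cols].notna().all(axis=1)
    for col in numeric_cols:
        valid &= df[col] >= 0
    if schema.milk_per_farm:
        valid &= df[schema.herd_col] > 0
    kept = df[valid]
    dropped = n_read - len(kept)
    if dropped:
        logger.info("read_survey_csv: read %d rows, dropped %d invalid", n_read, dropped)
    if kept.empty:
        raise EmptyTableError(f"no usable rows in {path} ({dropped} dropped)")

    records = []
    for _, row in kept.iterrows():
        milk = float(row[schema.milk_col])
        if schema.milk_per_farm:
            milk /= float(row[schema.herd_col])
        records.append(
            FarmRecord(
                farm_id=str(row[schema.farm_col]),
                zone=str(row[schema.zone_col]),
                milk_yield=milk,
                outputs={name: float(row[col]) for name, col in schema.output_cols.items()},
                inputs={name: float(row[col]) for name, col in schema.input_cols.items()},
            )
        )
    table = SurveyTable(
        records,
        output_names=list(schema.output_cols),
        input_names=list(schema.input_cols),
    )
    table.dropped = dropped  # type: ignore[attr-defined]
    return table


def write_survey_csv(table: SurveyTable, path: str | Path) -> None:
    """Write a SurveyTable to CSV (inverse of read_survey_csv's default schema)."""
    df = table.to_frame()
    df.to_csv(path, index=False)


def group_by_zone(table: SurveyTable) -> dict[str, SurveyTable]:
    """Partition a table by zone label.

    Every record lands in exactly one group; group sizes sum to len(table).
    """
    if not table.records:
        raise EmptyTableError("group_by_zone: empty table")
    groups: dict[str, list[FarmRecord]] = {}
    for rec in table.records:
        groups.setdefault(rec.zone, []).append(rec)
    return {
        zone: SurveyTable(recs, table.output_names, table.input_names)
        for zone, recs in groups.items()
    }
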