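"""Study data model and CSV input/output.

One row per animal. The experiment is cross-sectional: two baseline groups
sampled at day 0 (control, i.e. not electroejaculated, and electroejaculated)
plus a 2x2x2 factorial of recovery groups (temperature 12/16 degC x food
ad-libitum/deprived x period 15/30 d), all electroejaculated at day 0.

Units are fixed by the schema and never rescaled: vasa deferentia dry weight
in mg, hepatopancreas and whole-body dry weight in g, carapace length in mm.
Day-0 baseline rows carry no temperature/food treatment; these are encoded as
the literal strings ``NA`` / ``none`` in the CSV rather than empty cells, so
a blank always signals a data error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    MissingCellError,
    RowError,
    SchemaError,
    ValidationError,
)

#: Canonical CSV column names, in on-disk order.
COLUMNS = (
    "crab_id",
    "temperature_c",
    "food",
    "period_days",
    "electroejaculated",
    "carapace_length_mm",
    "vd_dry_weight_mg",
    "hep_dry_weight_g",
    "body_dry_weight_g",
    "season",
)

FOOD_LEVELS = ("ad_libitum", "deprived", "none")
TEMPERATURES = (12, 16)
PERIODS = (0, 15, 30)

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


@dataclass(frozen=True)
class Cell:
    """Design-cell key: the four factors that identify a treatment group."""

    temperature: Optional[int]  # 12 or 16 degC; None for day-0 baselines
    food: str                   # ad_libitum | deprived | none
    period_days: int            # 0 | 15 | 30
    electroejaculated: bool

    @staticmethod
    def control_t0() -> "Cell":
        """Day-0 control group (vasa deferentia intact)."""
        return Cell(None, "none", 0, False)

    @staticmethod
    def depleted_t0() -> "Cell":
        """Day-0 electroejaculated group (vasa deferentia emptied)."""
        return Cell(None, "none", 0, True)

    @staticmethod
    def recovery(temperature: int, food: str, period_days: int) -> "Cell":
        """An electroejaculated recovery group held for 15 or 30 days."""
        return Cell(temperature, food, period_days, True)

    def label(self) -> str:
        if self.period_days == 0:
            return "t0_ee" if self.electroejaculated else "t0_control"
        return f"{self.period_days}d_{self.temperature}C_{self.food}"


#: The ten cells of the study design, in reporting order.
DESIGN_CELLS = (
    Cell.control_t0(),
    Cell.depleted_t0(),
    *(
        Cell.recovery(t, f, p)
        for p in (15, 30)
        for t in (12, 16)
        for f in ("ad_libitum", "deprived")
    ),
)


@dataclass(frozen=True)
class CrabRecord:
    """Measurements for a single sacrificed animal."""

    crab_id: str
    temperature: Optional[int]
    food: str
    period_days: int
    electroejaculated: bool
    carapace_length: float  # mm
    vd_dry_weight: float    # mg, paired vasa deferentia
    hep_dry_weight: float   # g
    body_dry_weight: float  # g
    season: Optional[str] = None

    def __post_init__(self):
        if self.food not in FOOD_LEVELS:
            raise ValidationError(f"unknown food level {self.food!r}")
        if self.temperature is not None and self.temperature not in TEMPERATURES:
            raise ValidationError(f"unknown temperature {self.temperature!r}")
        if self.period_days not in PERIODS:
            raise ValidationError(f"unknown period {self.period_days!r}")
        if self.period_days == 0 and self.food != "none":
            raise ValidationError(
                f"{self.crab_id}: day-0 baseline rows must have food='none'"
            )
        for name in ("carapace_length", "vd_dry_weight", "body_dry_weight"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ValidationError(f"{self.crab_id}: {name} must be > 0, got {v}")
        if not (0 <= self.hep_dry_weight) or not math.isfinite(self.hep_dry_weight):
            raise ValidationError(
                f"{self.crab_id}: hep_dry_weight must be >= 0, got {self.hep_dry_weight}"
            )
        if self.hep_dry_weight > self.body_dry_weight:
            raise ValidationError(
                f"{self.crab_id}: hepatopancreas ({self.hep_dry_weight} g) heavier "
                f"than whole body ({self.body_dry_weight} g)"
            )

    @property
    def cell(self) -> Cell:
        return Cell(
            self.temperature, self.food, self.period_days, self.electroejaculated
        )


@dataclass
class StudyTable:
    """Ordered collection of :class:`CrabRecord` with provenance metadata."""

    records: list[CrabRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        ids = [r.crab_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate crab_id values: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def cell_records(self, cell: Cell) -> list[CrabRecord]:
        return [r for r in self.records if r.cell == cell]

    def cells(self) -> list[Cell]:
        """Distinct design cells present, in first-appearance order."""
        seen: dict[Cell, None] = {}
        for r in self.records:
            seen.setdefault(r.cell, None)
        return list(seen)

    def subset(self, predicate) -> "StudyTable":
        table = StudyTable.__new__(StudyTable)
        table.records = [r for r in self.records if predicate(r)]
        table.provenance = self.provenance
        return table

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "crab_id": r.crab_id,
                    "temperature_c": "NA" if r.temperature is None else r.temperature,
                    "food": r.food,
                    "period_days": r.period_days,
                    "electroejaculated": r.electroejaculated,
                    "carapace_length_mm": r.carapace_length,
                    "vd_dry_weight_mg": r.vd_dry_weight,
                    "hep_dry_weight_g": r.hep_dry_weight,
                    "body_dry_weight_g": r.body_dry_weight,
                    "season": r.season if r.season is not None else "NA",
                }
            )
        return pd.DataFrame(rows, columns=list(COLUMNS))


@dataclass(frozen=True)
class GroupSummary:
    """n, mean and standard error of one variable in one design cell."""

    cell: Cell
    variable: str
    n: int
    mean: float
    se: float


def _parse_bool(raw: str, row: int) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise RowError(row, f"cannot parse boolean {raw!r} for electroejaculated")


def _parse_float(raw, column: str, row: int) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise RowError(row, f"cannot parse numeric {raw!r} in column {column}")


def read_study_table(
    path, schema: Optional[Mapping[str, str]] = None
) -> StudyTable:
    """Read a record table from CSV.

    Parameters
    ----------
    path : path-like
        CSV file with one header row, comma-separated, UTF-8, "." decimals.
    schema : mapping, optional
        Maps canonical column names (:data:`COLUMNS`) to the names actually
        used in the file, for tables deposited under a different layout.
        Unmapped names are looked up verbatim.

    Row numbers in errors are 1-based counting the header, so the first data
    row is row 2 (what a spreadsheet shows).
    """
    schema = dict(schema or {})
    df = pd.read_csv(path, dtype=str, keep_default_na=False)

    def col(name: str, required: bool = True) -> Optional[pd.Series]:
        actual = schema.get(name, name)
        if actual not in df.columns:
            if required:
                raise SchemaError(f"missing required column {actual!r} (for {name})")
            return None
        return df[actual]

    series = {name: col(name, required=(name != "season")) for name in COLUMNS}

    records = []
    for i in range(len(df)):
        row_no = i + 2  # header is row 1
        raw_temp = str(series["temperature_c"].iloc[i]).strip()
        if raw_temp.upper() in ("NA", ""):
            temp: Optional[int] = None
        else:
            t = _parse_float(raw_temp, "temperature_c", row_no)
            if t not in TEMPERATURES:
                raise RowError(row_no, f"temperature {raw_temp!r} not one of {TEMPERATURES}")
            temp = int(t)
        food = str(series["food"].iloc[i]).strip()
        if food not in FOOD_LEVELS:
            raise RowError(row_no, f"food level {food!r} not one of {FOOD_LEVELS}")
        period = int(_parse_float(series["period_days"].iloc[i], "period_days", row_no))
        if period not in PERIODS:
            raise RowError(row_no, f"period {period!r} not one of {PERIODS}")
        season_series = series["season"]
        season = None
        if season_series is not None:
            s = str(season_series.iloc[i]).strip()
            season = None if s.upper() in ("NA", "") else s
        try:
            rec = CrabRecord(
                crab_id=str(series["crab_id"].iloc[i]).strip(),
                temperature=temp,
                food=food,
                period_days=period,
                electroejaculated=_parse_bool(
                    series["electroejaculated"].iloc[i], row_no
                ),
                carapace_length=_parse_float(
                    series["carapace_length_mm"].iloc[i], "carapace_length_mm", row_no
                ),
                vd_dry_weight=_parse_float(
                    series["vd_dry_weight_mg"].iloc[i], "vd_dry_weight_mg", row_no
                ),
                hep_dry_weight=_parse_float(
                    series["hep_dry_weight_g"].iloc[i], "hep_dry_weight_g", row_no
                ),
                body_dry_weight=_parse_float(
                    series["body_dry_weight_g"].iloc[i], "body_dry_weight_g", row_no
                ),
                season=season,
            )
        except ValidationError as exc:
            raise RowError(row_no, str(exc)) from exc
        records.append(rec)

    return StudyTable(records=records, provenance=str(path))


def write_study_table(table: StudyTable, path) -> None:
    """Write the table as CSV under the canonical column layout."""
    table.to_dataframe().to_csv(path, index=False)


def record_value(record: CrabRecord, variable: str) -> float:
    """Look up a summarizable variable on one record.

    ``hsi`` is the hepatosomatic index, hepatopancreas dry weight as a
    percentage of whole-body dry weight.
    """
    if variable == "vd_dry_weight":
        return record.vd_dry_weight
    if variable == "carapace_length":
        return record.carapace_length
    if variable == "hsi":
        from .recovery import hepatosomatic_index

        return hepatosomatic_index(record.hep_dry_weight, record.body_dry_weight)
    raise ValueError(f"unknown variable {variable!r}")


def summarize_cell(table: StudyTable, cell: Cell, variable: str) -> GroupSummary:
    """Mean +- SE summary of one variable in one design cell.

    The SE is the n-1 sample standard deviation divided by sqrt(n), the
    convention behind "means +- standard errors" reporting.
    """
    values = [record_value(r, variable) for r in table.cell_records(cell)]
    if not values:
        raise MissingCellError(f"no records in cell {cell.label()}")
    if len(values) < 2:
        raise MissingCellError(
            f"cell {cell.label()} has n=1; the standard error is undefined"
        )
    arr = np.asarray(values, dtype=float)
    n = arr.size
    return GroupSummary(
        cell=cell,
        variable=variable,
        n=int(n),
        mean=float(arr.mean()),
        se=float(arr.std(ddof=1) / math.sqrt(n)),
    )


def summarize_all(
    table: StudyTable, variables: Sequence[str] = ("vd_dry_weight", "hsi")
) -> pd.DataFrame:
    """Group-summary table (one row per present cell x variable)."""
    rows = []
    for cell in table.cells():
        if len(table.cell_records(cell)) < 2:
            continue
        for var in variables:
            s = summarize_cell(table, cell, var)
            rows.append(
                {
                    "cell": cell.label(),
                    "variable": var,
                    "n": s.n,
                    "mean": s.mean,
                    "se": s.se,
                }
            )
    return pd.DataFrame(rows, columns=["cell", "variable", "n", "mean", "se"])
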