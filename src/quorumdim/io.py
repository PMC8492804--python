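"""Reading and writing single-cell tables and concentration grids.

The canonical on-disk format is tab-separated text with a header.  Spreadsheet
(.xlsx) input is supported read-only and converted on ingest, so deposited
per-cell supplementary tables can be fed straight into the pipeline.

A cell table is a :class:`pandas.DataFrame` with the canonical columns

    condition_id  opaque condition label (string)
    c8            C8HSL concentration (unit carried on the grid, never guessed)
    oc6           3OC6HSL concentration
    green         green reporter fluorescence (a.u.)
    red           red fluorescence (a.u.); may be entirely missing/NaN
    area          cell area in pixels, > 0

Rows violating the invariants (non-finite green, non-positive area) are
rejected on ingest and the rejection count is reported alongside the table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import EmptyInputError, GridValidationError, SchemaError

CELL_COLUMNS = ["condition_id", "c8", "oc6", "green", "red", "area"]
REQUIRED_COLUMNS = ["condition_id", "c8", "oc6", "green", "area"]


@dataclass(frozen=True)
class ConditionGrid:
    """Rectangular grid of input (C8HSL x 3OC6HSL) concentrations.

    Levels must be strictly increasing; the first level may be 0.  Units are
    explicit metadata per axis (the C8HSL axis is in pM for the qrr reporter
    grid but nM for the lux grid) and no conversion is ever implicit.
    """

    c8_levels: tuple
    oc6_levels: tuple
    c8_unit: str = "nM"
    oc6_unit: str = "nM"

    def __post_init__(self):
        for name, levels in (("c8", self.c8_levels), ("oc6", self.oc6_levels)):
            arr = np.asarray(levels, dtype=float)
            if arr.size < 2:
                raise GridValidationError(f"{name} axis needs at least 2 levels")
            if np.any(arr < 0):
                raise GridValidationError(f"{name} levels must be non-negative")
            if np.any(np.diff(arr) <= 0):
                raise GridValidationError(
                    f"{name} levels must be strictly increasing, got {list(levels)}"
                )
        object.__setattr__(self, "c8_levels", tuple(float(x) for x in self.c8_levels))
        object.__setattr__(self, "oc6_levels", tuple(float(x) for x in self.oc6_levels))

    @property
    def shape(self) -> tuple:
        return (len(self.c8_levels), len(self.oc6_levels))

    @property
    def n_conditions(self) -> int:
        return len(self.c8_levels) * len(self.oc6_levels)

    @staticmethod
    def condition_id(c8: float, oc6: float) -> str:
        return f"c8={c8:g}|oc6={oc6:g}"

    def iter_conditions(self):
        """Yield (condition_id, c8, oc6) over the grid, c8-major."""
        for c8 in self.c8_levels:
            for oc6 in self.oc6_levels:
                yield self.condition_id(c8, oc6), c8, oc6


class ReadResult(NamedTuple):
    cells: pd.DataFrame
    n_rejected: int


def _load_table(path: Path) -> pd.DataFrame:
    if path.suffix.lower() in {".xlsx", ".xls"}:
        return pd.read_excel(path)
    # round_trip: the default float parser can be off by one ulp
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def read_cells(path, schema: Mapping[str, str] | None = None) -> ReadResult:
    """Read a per-cell table, validate invariants, and report rejections.

    Parameters
    ----------
    path:
        TSV (canonical) or xlsx file.
    schema:
        Optional mapping from canonical column names to the file's column
        names, e.g. ``{"green": "GFP", "area": "Area_px"}``.  Unmapped
        canonical names are looked up verbatim.

    Returns
    -------
    ReadResult
        ``cells`` with canonical columns, and ``n_rejected`` — the number of
        rows dropped for non-finite green or non-positive area.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = _load_table(path)
    if raw.empty:
        raise EmptyInputError(f"{path} contains no data rows")

    schema = dict(schema or {})
    rename = {}
    for canon in CELL_COLUMNS:
        src = schema.get(canon, canon)
        if src in raw.columns:
            rename[src] = canon
        elif canon in REQUIRED_COLUMNS:
            raise SchemaError(f"required column '{canon}' (file column '{src}') not found")
    df = raw.rename(columns=rename)
    if "red" not in df.columns:
        df["red"] = np.nan
    df = df[CELL_COLUMNS].copy()
    df["condition_id"] = df["condition_id"].astype(str)
    for col in ("c8", "oc6", "green", "red", "area"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)

    ok = np.isfinite(df["green"].to_numpy()) & (df["area"].to_numpy() > 0)
    ok &= np.isfinite(df["area"].to_numpy())
    n_rejected = int((~ok).sum())
    df = df.loc[ok].reset_index(drop=True)
    if df.empty:
        raise EmptyInputError(f"{path}: every row was rejected")
    return ReadResult(df, n_rejected)


def write_cells(cells: pd.DataFrame, path) -> None:
    """Write a cell table as TSV; floats round-trip at full precision."""
    cols = [c for c in cells.columns if c in CELL_COLUMNS or c.startswith("green")]
    # %.17g guarantees binary64 round-trip (the default writer keeps 16 digits)
    cells[cols].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_grid(path) -> ConditionGrid:
    """Read a condition grid from a YAML config.

    Expected layout::

        c8:  {unit: pM, levels: [0, 7, 20, 50, 100, 200, 1000]}
        oc6: {unit: nM, levels: [0, 7, 15, 20, 50, 100, 500]}
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "c8" not in cfg or "oc6" not in cfg:
        raise GridValidationError("grid config must define both 'c8' and 'oc6' axes")
    for axis in ("c8", "oc6"):
        if "levels" not in cfg[axis] or "unit" not in cfg[axis]:
            raise GridValidationError(f"axis '{axis}' must list 'unit' and 'levels'")
    return ConditionGrid(
        c8_levels=tuple(cfg["c8"]["levels"]),
        oc6_levels=tuple(cfg["oc6"]["levels"]),
        c8_unit=str(cfg["c8"]["unit"]),
        oc6_unit=str(cfg["oc6"]["unit"]),
    )


def write_grid(grid: ConditionGrid, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "c8": {"unit": grid.c8_unit, "levels": list(grid.c8_levels)},
                "oc6": {"unit": grid.oc6_unit, "levels": list(grid.oc6_levels)},
            },
            fh,
        )
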