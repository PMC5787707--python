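"""Data model and CSV readers/writers for screen tables.

All tables are comma-separated UTF-8 text with one header row. Numeric
values are serialized with 12 significant digits so write/read round trips
are stable. Well ids are normalized to letter + zero-padded two-digit
column (``B2`` -> ``B02``).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._util import normalize_well_id

FLOAT_FMT = "%.12g"

CELL_META_COLS = ["plate", "well", "cell", "transfected"]
PLATEMAP_COLS = ["plate", "well", "perturbation", "gene", "guide", "is_control"]

_BOOL_MAP = {
    "0": False, "1": True, "false": False, "true": True,
    "f": False, "t": True,
}


class SchemaError(ValueError):
    """A table is missing mandatory columns or violates a structural invariant."""


class TableParseError(ValueError):
    """A table cell could not be parsed (the offending row is named)."""


def _parse_bool(series: pd.Series, column: str) -> pd.Series:
    out = series.astype(str).str.strip().str.lower().map(_BOOL_MAP)
    if out.isna().any():
        row = int(out.index[out.isna()][0])
        raise TableParseError(
            f"non-boolean value {series.iloc[row]!r} in column {column!r} at row {row}"
        )
    return out.astype(bool)


@dataclasses.dataclass
class CellTable:
    """Single-cell feature table: one row per cell.

    ``data`` holds the columns plate, well, cell, transfected plus one
    numeric column per feature. T(+) cells (``transfected=True``) are the
    potentially perturbed population; T(-) cells are in-well wild-type
    controls.
    """

    data: pd.DataFrame
    feature_names: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in CELL_META_COLS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"cell table missing mandatory column(s): {missing}")
        if len(self.feature_names) == 0:
            raise SchemaError("cell table declares no feature columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise SchemaError("duplicate feature names")
        absent = [f for f in self.feature_names if f not in self.data.columns]
        if absent:
            raise SchemaError(f"declared features absent from table: {absent}")
        df = self.data.copy()
        df["well"] = df["well"].map(normalize_well_id)
        df["cell"] = df["cell"].astype(int)
        df["transfected"] = df["transfected"].astype(bool)
        for f in self.feature_names:
            if not np.issubdtype(df[f].dtype, np.number):
                raise TableParseError(f"feature column {f!r} is not numeric")
            if df[f].isna().any():
                row = int(df.index[df[f].isna()][0])
                raise TableParseError(f"missing/invalid value in feature {f!r} at row {row}")
            df[f] = df[f].astype(float)
        if df.duplicated(subset=["plate", "well", "cell"]).any():
            dup = df[df.duplicated(subset=["plate", "well", "cell"])].iloc[0]
            raise SchemaError(
                f"duplicate cell key ({dup['plate']}, {dup['well']}, {dup['cell']})"
            )
        self.data = df.reset_index(drop=True)

    @property
    def n_cells(self) -> int:
        return len(self.data)

    def wells(self) -> list[tuple[str, str]]:
        return sorted(set(zip(self.data["plate"], self.data["well"])))

    def features(self) -> pd.DataFrame:
        return self.data[self.feature_names]


@dataclasses.dataclass
class StandardizedCellTable(CellTable):
    """CellTable after in-well T(-) standardization.

    ``provenance`` maps (plate, well) -> {feature: (tneg_mean, tneg_sd)};
    ``dropped_features`` lists features removed screen-wide because their
    T(-) spread vanished in at least one well.
    """

    provenance: dict = dataclasses.field(default_factory=dict)
    dropped_features: list = dataclasses.field(default_factory=list)


@dataclasses.dataclass(frozen=True)
class FeatureSet:
    """A named, ordered group of feature columns to profile together."""

    name: str
    features: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.features) == 0:
            raise SchemaError(f"feature set {self.name!r} is empty")
        if len(set(self.features)) != len(self.features):
            raise SchemaError(f"feature set {self.name!r} has duplicate features")

    def validate_against(self, table: CellTable) -> None:
        absent = [f for f in self.features if f not in table.feature_names]
        if absent:
            raise SchemaError(f"feature set {self.name!r} references unknown features: {absent}")


@dataclasses.dataclass
class PlateMap:
    """Well -> perturbation assignments, including non-targeting-control flags."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PLATEMAP_COLS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"plate map missing mandatory column(s): {missing}")
        df = self.data.copy()
        df["well"] = df["well"].map(normalize_well_id)
        if not np.issubdtype(df["is_control"].dtype, np.bool_):
            df["is_control"] = _parse_bool(df["is_control"], "is_control")
        if df.duplicated(subset=["plate", "well"]).any():
            dup = df[df.duplicated(subset=["plate", "well"])].iloc[0]
            raise SchemaError(f"duplicate plate-map key ({dup['plate']}, {dup['well']})")
        self.data = df.reset_index(drop=True)

    def control_wells(self) -> list[tuple[str, str]]:
        ctl = self.data[self.data["is_control"]]
        return sorted(set(zip(ctl["plate"], ctl["well"])))

    def lookup(self, plate: str, well: str) -> pd.Series:
        well = normalize_well_id(well)
        hit = self.data[(self.data["plate"] == plate) & (self.data["well"] == well)]
        if hit.empty:
            raise KeyError(f"({plate}, {well}) not in plate map")
        return hit.iloc[0]


@dataclasses.dataclass
class ValidationReport:
    missing_in_map: list
    missing_in_cells: list
    n_control_wells: int
    passed: bool

    def __str__(self) -> str:  # human-readable CLI output
        lines = [f"validation: {'PASS' if self.passed else 'FAIL'}"]
        if self.missing_in_map:
            lines.append(f"  wells in cell table but not plate map: {self.missing_in_map}")
        if self.missing_in_cells:
            lines.append(f"  wells in plate map but not cell table: {self.missing_in_cells}")
        lines.append(f"  control wells: {self.n_control_wells}")
        if self.n_control_wells == 0:
            lines.append("  MISSING non-targeting control wells")
        return "\n".join(lines)


def read_cell_table(path: str | Path, feature_names: Sequence[str] | None = None) -> CellTable:
    """Read a single-cell feature CSV.

    Feature columns are auto-detected (every non-mandatory column) when
    ``feature_names`` is not given. ``NA``/empty feature cells raise a
    :class:`TableParseError` naming the offending row.
    """
    df = pd.read_csv(path, keep_default_na=False, na_values=[], dtype=str)
    missing = [c for c in CELL_META_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {missing}")
    if feature_names is None:
        feature_names = [c for c in df.columns if c not in CELL_META_COLS]
    out = df[CELL_META_COLS].copy()
    out["cell"] = pd.to_numeric(out["cell"], errors="raise").astype(int)
    out["transfected"] = _parse_bool(out["transfected"], "transfected")
    for f in feature_names:
        if f not in df.columns:
            raise SchemaError(f"{path}: declared feature {f!r} absent")
        vals = pd.to_numeric(df[f], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise TableParseError(
                f"{path}: non-numeric feature value {df[f].iloc[row]!r} "
                f"in column {f!r} at row {row}"
            )
        out[f] = vals.astype(float)
    return CellTable(out, list(feature_names))


def write_cell_table(table: CellTable, path: str | Path) -> None:
    df = table.data.copy()
    df["transfected"] = df["transfected"].astype(int)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_plate_map(path: str | Path) -> PlateMap:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    missing = [c for c in PLATEMAP_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {missing}")
    if len(df):
        df["is_control"] = _parse_bool(df["is_control"], "is_control")
    else:
        df["is_control"] = df["is_control"].astype(bool)
    return PlateMap(df[PLATEMAP_COLS])


def write_plate_map(pmap: PlateMap, path: str | Path) -> None:
    df = pmap.data.copy()
    df["is_control"] = df["is_control"].astype(int)
    df.to_csv(path, index=False)


def read_feature_set(path: str | Path) -> FeatureSet:
    """Read a YAML feature-set file: ``{name: ..., features: [...]}``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return FeatureSet(name=str(doc["name"]), features=tuple(doc["features"]))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a generic result table with the package float convention."""
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def validate_screen(cells: CellTable, pmap: PlateMap) -> ValidationReport:
    """Cross-check wells between a cell table and a plate map (pure; report only)."""
    cell_wells = set(cells.wells())
    map_wells = set(zip(pmap.data["plate"], pmap.data["well"]))
    missing_in_map = sorted(cell_wells - map_wells)
    missing_in_cells = sorted(map_wells - cell_wells)
    n_ctl = len(pmap.control_wells())
    passed = not missing_in_map and not missing_in_cells and n_ctl >= 1
    return ValidationReport(missing_in_map, missing_in_cells, n_ctl, passed)
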