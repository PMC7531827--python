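"""Gridded monthly climate I/O.

The canonical on-disk form is a CSV with header::

    cell_id, lat, lon, elev_m,
    tmin_01..tmin_12, tmax_01..tmax_12, prec_01..prec_12

one row per georeferenced cell (monthly columns Jan..Dec).  A "wide"
dialect adapter accepts the supplementary-table layout of the source
datasets (the same 40 quantities under arbitrary but ordered headers:
geography first, then 12 minima, 12 maxima, 12 precipitation columns).
Classified grids are written back as CSV or RFC 7946 GeoJSON with one
square cell polygon per feature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellRecord",
    "ClimateGrid",
    "read_climate_grid",
    "write_climate_grid",
    "write_classified_grid",
    "SchemaError",
    "GridValidationError",
    "AlignmentError",
    "CANONICAL_COLUMNS",
]

MONTH_TAGS = [f"{i:02d}" for i in range(1, 13)]
TMIN_COLS = [f"tmin_{t}" for t in MONTH_TAGS]
TMAX_COLS = [f"tmax_{t}" for t in MONTH_TAGS]
PREC_COLS = [f"prec_{t}" for t in MONTH_TAGS]
CANONICAL_COLUMNS = ["cell_id", "lat", "lon", "elev_m"] + TMIN_COLS + TMAX_COLS + PREC_COLS


class SchemaError(ValueError):
    """Missing, duplicated or non-numeric columns in an input table."""


class GridValidationError(ValueError):
    """Rows violating the cell invariants; offending cell ids are listed."""

    def __init__(self, message: str, cell_ids: Sequence):
        super().__init__(f"{message}: {list(cell_ids)}")
        self.cell_ids = list(cell_ids)


class AlignmentError(ValueError):
    """Label set and grid disagree on the cell ids."""


@dataclass(frozen=True)
class CellRecord:
    """One georeferenced cell of monthly climatology."""

    cell_id: str
    lat: float
    lon: float
    elevation: float
    tmin: np.ndarray
    tmax: np.ndarray
    prec: np.ndarray

    def __post_init__(self):
        for name in ("tmin", "tmax", "prec"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (12,):
                raise GridValidationError(f"{name} must have 12 entries", [self.cell_id])
            object.__setattr__(self, name, arr)
        problems = []
        if np.any(self.prec < 0):
            problems.append("negative precipitation")
        if np.any(self.tmax < self.tmin):
            problems.append("tmax < tmin")
        if not (-90 <= self.lat <= 90) or not (-180 <= self.lon <= 180):
            problems.append("coordinates out of range")
        if problems:
            raise GridValidationError("; ".join(problems), [self.cell_id])


@dataclass
class ClimateGrid:
    """An ordered collection of cells sharing the Jan→Dec convention.

    Backed by a DataFrame in the canonical column layout; array accessors
    expose (n, 12) views for the index computations.
    """

    frame: pd.DataFrame
    period_label: str = ""
    resolution_deg: float = 0.22
    cell_area_km2: float = 590.9

    def __post_init__(self):
        if len(self.frame) == 0:
            raise GridValidationError("empty grid", [])
        if self.frame["cell_id"].duplicated().any():
            dupes = self.frame.loc[self.frame["cell_id"].duplicated(), "cell_id"]
            raise GridValidationError("duplicate cell_id", dupes.tolist())
        self.frame = self.frame.reset_index(drop=True)

    # ------------------------------------------------------------- accessors
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def cell_ids(self) -> pd.Series:
        return self.frame["cell_id"]

    @property
    def lat(self) -> np.ndarray:
        return self.frame["lat"].to_numpy(float)

    @property
    def lon(self) -> np.ndarray:
        return self.frame["lon"].to_numpy(float)

    @property
    def elevation(self) -> np.ndarray:
        return self.frame["elev_m"].to_numpy(float)

    @property
    def tmin(self) -> np.ndarray:
        return self.frame[TMIN_COLS].to_numpy(float)

    @property
    def tmax(self) -> np.ndarray:
        return self.frame[TMAX_COLS].to_numpy(float)

    @property
    def prec(self) -> np.ndarray:
        return self.frame[PREC_COLS].to_numpy(float)

    def cells(self) -> Iterable[CellRecord]:
        for _, row in self.frame.iterrows():
            yield CellRecord(
                cell_id=str(row["cell_id"]),
                lat=float(row["lat"]),
                lon=float(row["lon"]),
                elevation=float(row["elev_m"]),
                tmin=row[TMIN_COLS].to_numpy(float),
                tmax=row[TMAX_COLS].to_numpy(float),
                prec=row[PREC_COLS].to_numpy(float),
            )

    @classmethod
    def from_cells(
        cls, cells: Sequence[CellRecord], period_label: str = "", **kw
    ) -> "ClimateGrid":
        rows = []
        for c in cells:
            row = {"cell_id": c.cell_id, "lat": c.lat, "lon": c.lon, "elev_m": c.elevation}
            row.update(dict(zip(TMIN_COLS, c.tmin)))
            row.update(dict(zip(TMAX_COLS, c.tmax)))
            row.update(dict(zip(PREC_COLS, c.prec)))
            rows.append(row)
        return cls(pd.DataFrame(rows, columns=CANONICAL_COLUMNS), period_label, **kw)


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    numeric = [c for c in CANONICAL_COLUMNS if c != "cell_id"]
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise SchemaError(f"non-numeric value in column {col!r}, row {row}")
        if parsed.isna().any():
            row = df.index[parsed.isna()][0]
            raise SchemaError(f"missing value in column {col!r}, row {row}")
        df[col] = parsed.astype(float)
    df["cell_id"] = df["cell_id"].astype(str)

    tmin = df[TMIN_COLS].to_numpy()
    tmax = df[TMAX_COLS].to_numpy()
    prec = df[PREC_COLS].to_numpy()
    bad = (
        (prec < 0).any(axis=1)
        | (tmax < tmin).any(axis=1)
        | ~df["lat"].between(-90, 90)
        | ~df["lon"].between(-180, 180)
    )
    if bad.any():
        raise GridValidationError(
            "rows violating cell invariants", df.loc[bad, "cell_id"].tolist()
        )
    return df


def _read_table(path: Path) -> pd.DataFrame:
    if path.suffix.lower() == ".ods":
        try:
            return pd.read_excel(path, engine="odf")
        except ImportError as exc:
            raise SchemaError(
                "reading .ods requires an ODF engine (odfpy); "
                "export the sheet to CSV and use the 'wide' dialect"
            ) from exc
    return pd.read_csv(path)


def read_climate_grid(
    path: str | Path,
    dialect: str = "canonical",
    period_label: str = "",
    resolution_deg: float = 0.22,
    cell_area_km2: float = 590.9,
) -> ClimateGrid:
    """Read and validate a gridded monthly climate table.

    ``dialect='canonical'`` expects the canonical header; ``'wide'``
    accepts the supplementary-table layout: four leading geography
    columns (id, lat, lon, elevation under any names) followed by 12
    minimum-temperature, 12 maximum-temperature and 12 precipitation
    columns in calendar order.
    """
    path = Path(path)
    df = _read_table(path)
    if dialect == "canonical":
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        if df.columns.duplicated().any():
            raise SchemaError("duplicated columns in header")
        df = df[CANONICAL_COLUMNS].copy()
    elif dialect == "wide":
        if df.shape[1] < 40:
            raise SchemaError(
                f"wide dialect needs >= 40 columns (4 geo + 36 monthly), got {df.shape[1]}"
            )
        df = df.iloc[:, :40].copy()
        df.columns = CANONICAL_COLUMNS
    else:
        raise SchemaError(f"unknown dialect {dialect!r}")
    df = _validate_frame(df)
    return ClimateGrid(df, period_label or path.stem, resolution_deg, cell_area_km2)


def write_climate_grid(grid: ClimateGrid, path: str | Path) -> Path:
    """Write a grid in the canonical CSV schema (full precision)."""
    path = Path(path)
    grid.frame[CANONICAL_COLUMNS].to_csv(path, index=False)
    return path


def _cell_polygon(lat: float, lon: float, half: float) -> list:
    # GeoJSON ring in lon-lat order, closed, counter-clockwise
    return [[
        [lon - half, lat - half],
        [lon + half, lat - half],
        [lon + half, lat + half],
        [lon - half, lat + half],
        [lon - half, lat - half],
    ]]


def write_classified_grid(
    grid: ClimateGrid,
    labels: pd.DataFrame,
    path: str | Path,
    format: str = "csv",
) -> Path:
    """Write per-cell classification labels as CSV or GeoJSON.

    ``labels`` must carry a ``cell_id`` column matching the grid exactly
    (same set of ids); the remaining columns are written as-is (CSV) or
    as feature properties attached to square cell polygons (GeoJSON).
    """
    path = Path(path)
    if set(labels["cell_id"].astype(str)) != set(grid.cell_ids.astype(str)):
        raise AlignmentError("label cell_id set does not match the grid")
    merged = grid.frame[["cell_id", "lat", "lon"]].merge(
        labels.assign(cell_id=labels["cell_id"].astype(str)), on="cell_id", how="left"
    )
    if format.lower() == "csv":
        merged.drop(columns=["lat", "lon"]).to_csv(path, index=False)
    elif format.lower() == "geojson":
        half = grid.resolution_deg / 2.0
        props_cols = [c for c in merged.columns if c not in ("lat", "lon")]
        features = []
        for _, row in merged.iterrows():
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": _cell_polygon(row["lat"], row["lon"], half),
                    },
                    "properties": {c: _jsonable(row[c]) for c in props_cols},
                }
            )
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        v = v.item()
    if isinstance(v, float) and np.isnan(v):
        return None
    return v
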