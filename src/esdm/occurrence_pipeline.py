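"""Occurrence cleaning and gridding.

Raw records come in as a DataFrame with DarwinCore-like columns
(``species, decimalLongitude, decimalLatitude, eventDate, source``;
alternative names can be mapped via ``column_map``). Cleaning removes
duplicates, on-land points, out-of-range coordinates, flagged-unreliable
records and records over cells deeper than the precautionary bathymetry
cutoff; every rejection carries a machine-readable reason. Kept records
are then aggregated to unique presence cells on the analysis grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import WorldGrid

__all__ = [
    "REQUIRED_COLUMNS",
    "OccurrenceSet",
    "normalize_columns",
    "clean_records",
    "grid_occurrences",
]

REQUIRED_COLUMNS = ("species", "decimalLongitude", "decimalLatitude")

#: rejection reason codes, in the order checks are applied
REASON_OUT_OF_RANGE = "out_of_range"
REASON_DUPLICATE = "duplicate"
REASON_OUTSIDE_GRID = "outside_grid"
REASON_ON_LAND = "on_land"
REASON_TOO_DEEP = "too_deep"
REASON_FLAGGED = "flagged_unreliable"


@dataclass
class OccurrenceSet:
    """Unique presence cells for one species, with provenance counts."""

    species: str
    cells: np.ndarray  # sorted unique flat cell ids
    record_counts: dict[int, int]  # records per presence cell
    source_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return int(self.cells.size)


def normalize_columns(records: pd.DataFrame, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Rename input columns to the canonical DarwinCore-like names."""
    df = records.rename(columns=column_map or {}).copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence table lacks required column(s): {missing}")
    if "eventDate" not in df.columns:
        df["eventDate"] = pd.NA
    if "source" not in df.columns:
        df["source"] = "unknown"
    return df


def clean_records(
    records: pd.DataFrame,
    grid: WorldGrid,
    land_mask: np.ndarray,
    bathymetry: np.ndarray,
    depth_cutoff_m: float = 1000.0,
    exclude_flags: set[str] | None = None,
    column_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clean raw occurrence records.

    Returns ``(kept, rejected)``; ``rejected`` carries a ``reason``
    column. Checks in order: coordinate validity, exclusion flags,
    duplicates (key: species, lon/lat rounded to 1e-4 degrees, date),
    grid membership, land mask, bathymetry cutoff (positive-down metres).
    Cleaning is idempotent: re-cleaning the kept set rejects nothing.

    Raises if bathymetry is missing (NaN) for an otherwise-valid ocean
    record's cell.
    """
    df = normalize_columns(records, column_map)
    if land_mask.shape != grid.shape or np.asarray(bathymetry).shape != grid.shape:
        raise ValueError("land_mask/bathymetry not aligned to grid")
    bathymetry = np.asarray(bathymetry, dtype=float)

    reason = pd.Series(pd.NA, index=df.index, dtype="object")
    lon = pd.to_numeric(df["decimalLongitude"], errors="coerce")
    lat = pd.to_numeric(df["decimalLatitude"], errors="coerce")

    bad_coord = lon.isna() | lat.isna() | (lon < -180) | (lon > 180) | (lat < -90) | (lat > 90)
    reason[bad_coord] = REASON_OUT_OF_RANGE

    if exclude_flags and "qc_flags" in df.columns:
        def _flagged(v) -> bool:
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return False
            flags = {t.strip() for t in str(v).split(";") if t.strip()}
            return bool(flags & exclude_flags)

        flagged = df["qc_flags"].map(_flagged) & reason.isna()
        reason[flagged] = REASON_FLAGGED

    # duplicates: exact (species, lon, lat, date) after 1e-4 deg rounding
    key = pd.DataFrame(
        {
            "species": df["species"],
            "lon": lon.round(4),
            "lat": lat.round(4),
            "date": df["eventDate"].astype("string"),
        }
    )
    dup = key.duplicated(keep="first") & reason.isna()
    reason[dup] = REASON_DUPLICATE

    candidate = reason.isna()
    inside = pd.Series(False, index=df.index)
    inside[candidate] = grid.contains(lon[candidate].to_numpy(), lat[candidate].to_numpy())
    reason[candidate & ~inside] = REASON_OUTSIDE_GRID

    ok = reason.isna()
    if ok.any():
        cell = grid.cell_id(lon[ok].to_numpy(), lat[ok].to_numpy())
        on_land = grid.values_at_cells(land_mask.astype(bool), cell)
        reason.loc[ok[ok].index[on_land]] = REASON_ON_LAND

        ocean_idx = ok[ok].index[~on_land]
        depth = grid.values_at_cells(bathymetry, cell[~on_land])
        if np.isnan(depth).any():
            n_bad = int(np.isnan(depth).sum())
            raise ValueError(f"bathymetry missing for {n_bad} ocean record cell(s)")
        reason.loc[ocean_idx[depth > depth_cutoff_m]] = REASON_TOO_DEEP

    kept = df[reason.isna()].copy()
    rejected = df[reason.notna()].copy()
    rejected["reason"] = reason[reason.notna()]
    return kept, rejected


def grid_occurrences(kept_records: pd.DataFrame, grid: WorldGrid) -> OccurrenceSet:
    """Aggregate cleaned records to one presence per occupied grid cell."""
    df = normalize_columns(kept_records)
    if df.empty:
        return OccurrenceSet(species="", cells=np.array([], dtype=int), record_counts={})
    species = str(df["species"].iloc[0])
    cell = grid.cell_id(
        df["decimalLongitude"].to_numpy(float), df["decimalLatitude"].to_numpy(float)
    )
    uniq, counts = np.unique(cell, return_counts=True)
    return OccurrenceSet(
        species=species,
        cells=uniq,
        record_counts=dict(zip(uniq.tolist(), counts.tolist())),
        source_counts=df["source"].value_counts().to_dict(),
    )
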