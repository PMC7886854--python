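"""Regular lon/lat analysis grid with cell-centre registration.

Cells are addressed by a single integer id in row-major order
(``id = iy * nx + ix``), with half-open membership intervals
``[west, east) x [south, north)`` so that every point maps to exactly
one cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WorldGrid"]


@dataclass(frozen=True)
class WorldGrid:
    """A regular lon/lat grid with cell-centre coordinates.

    Parameters
    ----------
    lon_min, lon_max, lat_min, lat_max
        Grid extent in decimal degrees (cell edges, not centres).
    resolution
        Cell size in degrees; must divide both extents within tolerance.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    resolution: float = 0.1

    nx: int = field(init=False)
    ny: int = field(init=False)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("grid extent is empty or inverted")
        nx = (self.lon_max - self.lon_min) / self.resolution
        ny = (self.lat_max - self.lat_min) / self.resolution
        if abs(nx - round(nx)) > 1e-6 or abs(ny - round(ny)) > 1e-6:
            raise ValueError("resolution does not divide the grid extent")
        object.__setattr__(self, "nx", int(round(nx)))
        object.__setattr__(self, "ny", int(round(ny)))

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def shape(self) -> tuple[int, int]:
        """(ny, nx) — the shape of every field on this grid."""
        return (self.ny, self.nx)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.nx) + 0.5) * self.resolution

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.ny) + 0.5) * self.resolution

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell (lon, lat) centre arrays of length n_cells (row-major)."""
        lon2, lat2 = np.meshgrid(self.lon_centers, self.lat_centers)
        return lon2.ravel(), lat2.ravel()

    def contains(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon_min)
            & (lon < self.lon_max)
            & (lat >= self.lat_min)
            & (lat < self.lat_max)
        )

    def cell_id(self, lon, lat) -> np.ndarray:
        """Map points to cell ids using half-open [west, east) x [south, north).

        Raises ValueError for points outside the grid extent.
        """
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        inside = self.contains(lon, lat)
        if not np.all(inside):
            bad = np.flatnonzero(~inside)[:5]
            raise ValueError(
                f"{(~inside).sum()} point(s) outside grid extent, e.g. "
                f"(lon={lon[bad[0]]:.4f}, lat={lat[bad[0]]:.4f})"
            )
        ix = np.floor((lon - self.lon_min) / self.resolution).astype(int)
        iy = np.floor((lat - self.lat_min) / self.resolution).astype(int)
        return iy * self.nx + ix

    def cell_center(self, cell_id) -> tuple[np.ndarray, np.ndarray]:
        cell_id = np.asarray(cell_id, dtype=int)
        iy, ix = np.divmod(cell_id, self.nx)
        lon = self.lon_min + (ix + 0.5) * self.resolution
        lat = self.lat_min + (iy + 0.5) * self.resolution
        return lon, lat

    def values_at_cells(self, field2d: np.ndarray, cell_id) -> np.ndarray:
        """Extract values of a (ny, nx) field at flat cell ids."""
        field2d = np.asarray(field2d)
        if field2d.shape != self.shape:
            raise ValueError(f"field shape {field2d.shape} != grid shape {self.shape}")
        return field2d.ravel()[np.asarray(cell_id, dtype=int)]
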