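"""Region masks and ESI-weighted distributional centroids.

Range shifts are summarized as displacements of the ESI-weighted
barycentre of all retained cells within a region, with the Atlantic
facade and the Mediterranean handled separately so their differently
oriented gradients and coastlines do not cancel out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import WorldGrid

__all__ = [
    "GIBRALTAR_LON",
    "RegionMask",
    "Centroid",
    "atlantic_mediterranean_split",
    "region_from_bounds",
    "weighted_centroid",
    "centroid_shift",
]

#: longitude of the Strait of Gibraltar used for the default region split
GIBRALTAR_LON = -5.6
_MED_LAT = (30.0, 46.0)


@dataclass(frozen=True)
class RegionMask:
    """Named boolean region on the analysis grid."""

    region_id: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.mask.dtype != bool:
            object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


@dataclass(frozen=True)
class Centroid:
    """ESI-weighted barycentre of a region's retained cells."""

    lon: float
    lat: float
    region_id: str
    scenario: str = "contemporary"
    decade: str = "contemporary"


def region_from_bounds(
    grid: WorldGrid,
    region_id: str,
    lon_bounds: tuple[float, float] | None = None,
    lat_bounds: tuple[float, float] | None = None,
) -> RegionMask:
    """Custom rectangular region (cell-centre membership)."""
    lon2, lat2 = np.meshgrid(grid.lon_centers, grid.lat_centers)
    mask = np.ones(grid.shape, dtype=bool)
    if lon_bounds is not None:
        mask &= (lon2 >= lon_bounds[0]) & (lon2 <= lon_bounds[1])
    if lat_bounds is not None:
        mask &= (lat2 >= lat_bounds[0]) & (lat2 <= lat_bounds[1])
    return RegionMask(region_id=region_id, mask=mask)


def atlantic_mediterranean_split(
    grid: WorldGrid,
    ocean_mask: np.ndarray | None = None,
) -> tuple[RegionMask, RegionMask]:
    """Default disjoint split: Mediterranean east of Gibraltar, rest Atlantic.

    Mediterranean = cells east of -5.6 degE within 30-46 degN; the
    Atlantic facade is every other (ocean) cell.
    """
    lon2, lat2 = np.meshgrid(grid.lon_centers, grid.lat_centers)
    med = (lon2 > GIBRALTAR_LON) & (lat2 >= _MED_LAT[0]) & (lat2 <= _MED_LAT[1])
    atl = ~med
    if ocean_mask is not None:
        med = med & ocean_mask
        atl = atl & ocean_mask
    return RegionMask("atlantic_facade", atl), RegionMask("mediterranean", med)


def weighted_centroid(
    esi: np.ndarray,
    grid: WorldGrid,
    region: RegionMask,
    scenario: str = "contemporary",
    decade: str = "contemporary",
    cos_lat_weights: bool = False,
    esi_cutoff: float = 0.0,
) -> Centroid:
    """ESI-weighted barycentre over a region's retained (non-NaN) cells.

    lon = sum(ESI_c * lon_c) / sum(ESI_c), same for lat. Masked cells and
    cells at or below ``esi_cutoff`` contribute nothing. Optional
    cos-latitude area weighting is off by default (cells, not areas).
    """
    esi = np.asarray(esi, dtype=float)
    if esi.shape != grid.shape or region.mask.shape != grid.shape:
        raise ValueError("ESI field / region mask not aligned with grid")
    lon2, lat2 = np.meshgrid(grid.lon_centers, grid.lat_centers)
    w = np.where(region.mask & np.isfinite(esi), esi, 0.0)
    w = np.where(w > esi_cutoff, w, 0.0)
    if cos_lat_weights:
        w = w * np.cos(np.deg2rad(lat2))
    total = w.sum()
    if total <= 0:
        raise ValueError(f"all-zero ESI within region {region.region_id!r}")
    return Centroid(
        lon=float((w * lon2).sum() / total),
        lat=float((w * lat2).sum() / total),
        region_id=region.region_id,
        scenario=scenario,
        decade=decade,
    )


def centroid_shift(contemporary: Centroid, future: Centroid) -> tuple[float, float]:
    """(delta lon, delta lat) in degrees; east/north positive."""
    if contemporary.region_id != future.region_id:
        raise ValueError(
            f"region mismatch: {contemporary.region_id!r} vs {future.region_id!r}"
        )
    return (future.lon - contemporary.lon, future.lat - contemporary.lat)
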