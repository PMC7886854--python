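"""Aligned environmental predictor stacks and factor pre-treatment.

A :class:`LayerStack` holds one 2-D field per environmental factor on a
shared :class:`~esdm.grid.WorldGrid`, plus an ocean mask and (optionally)
the monthly bottom-temperature series the thermal indices derive from.

Pre-treatment covers: deriving thermal indices from monthly series,
bilinear regridding, a pairwise-correlation collinearity screen, and a
permutation-based factor importance measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from .grid import WorldGrid

__all__ = [
    "LayerStack",
    "THERMAL_FACTORS",
    "derive_thermal_indices",
    "regrid_bilinear",
    "collinearity_screen",
    "permutation_importance",
    "candidate_factor_sets",
]

#: Factors expressed in degrees Celsius (share the 0.5 degC filtration bin width).
THERMAL_FACTORS = ("SBT", "SBTrange", "SBTvar")


@dataclass
class LayerStack:
    """Aligned environmental fields on one grid.

    ``factors`` maps factor name to a (ny, nx) float array; land cells are
    NaN. ``ocean_mask`` is True over ocean. ``monthly_sbt`` (optional) is a
    (n_years, 12, ny, nx) series from which the thermal indices derive.
    """

    grid: WorldGrid
    factors: dict[str, np.ndarray]
    ocean_mask: np.ndarray
    period: str = "contemporary"
    monthly_sbt: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ocean_mask.shape != self.grid.shape:
            raise ValueError("ocean_mask shape does not match grid")
        for name, arr in self.factors.items():
            if arr.shape != self.grid.shape:
                raise ValueError(f"factor {name!r} shape {arr.shape} != grid {self.grid.shape}")

    @property
    def factor_names(self) -> list[str]:
        return list(self.factors)

    @property
    def ocean_cells(self) -> np.ndarray:
        """Flat cell ids of all ocean cells."""
        return np.flatnonzero(self.ocean_mask.ravel())

    def env_at_cells(self, cell_ids, factor_names: Sequence[str]) -> np.ndarray:
        """(n_cells, n_factors) matrix of factor values at flat cell ids."""
        cols = [self.grid.values_at_cells(self.factors[f], cell_ids) for f in factor_names]
        return np.column_stack(cols)

    def background_env(self, factor_names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Environment of every ocean cell: (cell_ids, value matrix)."""
        cells = self.ocean_cells
        return cells, self.env_at_cells(cells, factor_names)

    def with_factors(self, new_factors: Mapping[str, np.ndarray], **meta) -> "LayerStack":
        """Copy of the stack with some factor fields replaced."""
        factors = dict(self.factors)
        factors.update({k: np.asarray(v, dtype=float) for k, v in new_factors.items()})
        out_meta = dict(self.meta)
        out_meta.update(meta)
        return LayerStack(
            grid=self.grid,
            factors=factors,
            ocean_mask=self.ocean_mask,
            period=self.period,
            monthly_sbt=self.monthly_sbt,
            meta=out_meta,
        )

    def to_dataset(self):
        """Export to an xarray Dataset (CF-style lon/lat coordinates)."""
        import xarray as xr

        coords = {"lat": self.grid.lat_centers, "lon": self.grid.lon_centers}
        data = {name: (("lat", "lon"), arr) for name, arr in self.factors.items()}
        data["ocean_mask"] = (("lat", "lon"), self.ocean_mask.astype(np.int8))
        ds = xr.Dataset(data, coords=coords)
        ds.attrs["period"] = self.period
        for k, v in self.meta.items():
            if isinstance(v, (str, int, float)):
                ds.attrs[k] = v
        return ds


def derive_thermal_indices(
    monthly_sbt_by_year: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Derive (SBT, SBTrange, SBTvar) from a monthly bottom-temperature series.

    Parameters
    ----------
    monthly_sbt_by_year
        Array of shape (n_years, 12, ...) — at least one full year of
        12 monthly fields.

    Returns
    -------
    SBT : mean of the 12 months, averaged across years.
    SBTrange : warmest-month minus coldest-month within each year, averaged
        across years.
    SBTvar : variance across the 12 months within each year, averaged
        across years.
    """
    arr = np.asarray(monthly_sbt_by_year, dtype=float)
    if arr.ndim < 2 or arr.shape[1] != 12:
        raise ValueError(f"expected shape (n_years, 12, ...), got {arr.shape}")
    if arr.shape[0] < 1:
        raise ValueError("need at least one year of monthly data")
    if np.isnan(arr).all(axis=(0, 1)).all():
        raise ValueError("monthly series is entirely missing")
    sbt = arr.mean(axis=1).mean(axis=0)
    rng = (arr.max(axis=1) - arr.min(axis=1)).mean(axis=0)
    var = arr.var(axis=1).mean(axis=0)
    return sbt, rng, var


def regrid_bilinear(
    field2d: np.ndarray,
    source_grid: WorldGrid,
    target_grid: WorldGrid,
) -> np.ndarray:
    """Bilinearly interpolate a field from one grid to another.

    Interpolation is linear in both lon and lat from the four surrounding
    source cell centres. Target cells falling on source NaNs (e.g. an
    ocean cell flanked by land on the coarse grid) fall back to the
    nearest valid source centre. Raises if the target centres lie outside
    the source centre coverage.
    """
    field2d = np.asarray(field2d, dtype=float)
    if field2d.shape != source_grid.shape:
        raise ValueError("field shape does not match source grid")

    interp = RegularGridInterpolator(
        (source_grid.lat_centers, source_grid.lon_centers),
        field2d,
        method="linear",
        bounds_error=True,
    )
    tlon, tlat = np.meshgrid(target_grid.lon_centers, target_grid.lat_centers)
    pts = np.column_stack([tlat.ravel(), tlon.ravel()])
    out = interp(pts).reshape(target_grid.shape)

    # nearest-valid fallback for cells contaminated by source NaNs
    bad = np.isnan(out)
    if bad.any() and np.isfinite(field2d).any():
        slon, slat = np.meshgrid(source_grid.lon_centers, source_grid.lat_centers)
        valid = np.isfinite(field2d)
        tree = cKDTree(np.column_stack([slat[valid], slon[valid]]))
        _, idx = tree.query(pts[bad.ravel()])
        out[bad] = field2d[valid][idx]
    return out


def _correlation_components(corr: np.ndarray, threshold: float) -> list[list[int]]:
    """Connected components of the |r| > threshold graph (indices)."""
    n = corr.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps: list[list[int]] = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in range(n):
                if not seen[j] and abs(corr[i, j]) > threshold:
                    seen[j] = True
                    stack.append(j)
        comps.append(sorted(comp))
    return comps


def collinearity_screen(
    stack: LayerStack,
    presence_cells: np.ndarray,
    factor_names: Sequence[str],
    importance: Mapping[str, float],
    threshold: float = 0.7,
    always_keep: str = "SBT",
) -> list[str]:
    """Drop intercorrelated factors, keeping the most important of each group.

    Pearson correlations are computed over *presence-cell* factor values
    only. Factors are grouped into connected components of the
    ``|r| > threshold`` graph; within each group only the factor with the
    highest ``importance`` survives, except that ``always_keep`` (SBT)
    survives its group unconditionally.
    """
    presence_cells = np.asarray(presence_cells)
    if presence_cells.size < 3:
        raise ValueError("need at least 3 presence cells to screen collinearity")
    X = stack.env_at_cells(presence_cells, factor_names)
    sd = X.std(axis=0)
    degenerate = [f for f, s in zip(factor_names, sd) if s == 0]
    if degenerate:
        raise ValueError(f"zero-variance factor(s) over presence cells: {degenerate}")
    corr = np.corrcoef(X, rowvar=False)
    if corr.ndim == 0:  # single factor
        corr = np.array([[1.0]])
    retained: list[str] = []
    for comp in _correlation_components(corr, threshold):
        names = [factor_names[i] for i in comp]
        if always_keep in names:
            keeper = always_keep
        else:
            keeper = max(names, key=lambda f: importance.get(f, 0.0))
        retained.append(keeper)
    # preserve input ordering
    return [f for f in factor_names if f in retained]


def permutation_importance(
    predict: Callable[[np.ndarray], np.ndarray],
    stack: LayerStack,
    factor_names: Sequence[str],
    factor: str,
    n_perm: int = 10,
    seed: int | None = 0,
) -> float:
    """Importance of one factor for a fitted suitability model.

    Defined as ``1 - mean Pearson r`` between the reference suitability
    map over ocean cells and maps recomputed after permuting the factor's
    values across cells. A factor the model ignores scores ~0; the sole
    driving factor scores well above 0.
    """
    if factor not in factor_names:
        raise ValueError(f"factor {factor!r} not among model factors {list(factor_names)}")
    rng = np.random.default_rng(seed)
    _, X = stack.background_env(factor_names)
    ref = np.asarray(predict(X), dtype=float)
    col = list(factor_names).index(factor)
    rs = []
    for _ in range(n_perm):
        Xp = X.copy()
        Xp[:, col] = rng.permutation(Xp[:, col])
        pred = np.asarray(predict(Xp), dtype=float)
        if np.std(pred) == 0 or np.std(ref) == 0:
            rs.append(1.0 if np.allclose(pred, ref) else 0.0)
        else:
            rs.append(stats.pearsonr(ref, pred).statistic)
    return float(np.clip(1.0 - np.mean(rs), 0.0, 1.0))


def candidate_factor_sets(
    available: Iterable[str] = ("SBT", "SBTrange", "SBTvar", "SSS"),
    include_coast_filter: bool = True,
) -> list[tuple[tuple[str, ...], bool]]:
    """Enumerate candidate (factor set, distance-to-coast flag) combinations.

    SBT is always included; one of SBTrange/SBTvar and SSS may enter as
    supplementary factors; the 50 km distance-to-coast filter is toggled
    independently.
    """
    available = set(available)
    bases: list[tuple[str, ...]] = [("SBT",)]
    for thermal in ("SBTrange", "SBTvar"):
        if thermal in available:
            bases.append(("SBT", thermal))
    with_sss: list[tuple[str, ...]] = []
    if "SSS" in available:
        with_sss = [b + ("SSS",) for b in bases]
    sets = bases + with_sss
    flags = (False, True) if include_coast_filter else (False,)
    return [(s, flag) for s in sets for flag in flags]
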