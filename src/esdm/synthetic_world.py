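"""Synthetic world generator: grids, climates, true niches, occurrences.

Provides everything the downstream pipeline needs to be exercised without
external downloads: smooth latitudinal/longitudinal temperature and
salinity gradients on a cell-centred grid, a known Gaussian-in-environment
"true niche", occurrence sampling proportional to true suitability (with
optional spatial sampling bias), and GCM-like scenario fields built as
contemporary + per-cell additive bias + scenario-dependent warming trend.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .env_stack import LayerStack, derive_thermal_indices
from .grid import WorldGrid

__all__ = [
    "TrueNiche",
    "ScenarioForcing",
    "WorldParams",
    "DECADES",
    "RCP_TREND_PER_DECADE",
    "DEFAULT_GCM_IDS",
    "build_grid",
    "default_grid",
    "generate_contemporary_stack",
    "make_forcing",
    "generate_gcm_stack",
    "sample_occurrences",
    "true_suitability_field",
]

KM_PER_DEGREE = 111.2

#: Decade labels and their offset (in decades) from the scenario baseline.
DECADES: dict[str, float] = {
    "baseline": 0.0,
    "2030-2039": 2.0,
    "2050-2059": 4.0,
    "2090-2099": 8.0,
}

#: Default warming trends (degC per decade), ordered RCP2.6 <= 4.5 <= 8.5.
RCP_TREND_PER_DECADE: dict[str, float] = {
    "RCP2.6": 0.08,
    "RCP4.5": 0.20,
    "RCP8.5": 0.45,
}

DEFAULT_GCM_IDS = ("GCM-A", "GCM-B", "GCM-C", "GCM-D", "GCM-E")


@dataclass(frozen=True)
class TrueNiche:
    """Separable Gaussian niche in environment space.

    suitability(x) = s_max * exp(-sum_f (x_f - mu_f)^2 / (2 sigma_f^2))
    """

    mu: dict[str, float]
    sigma: dict[str, float]
    s_max: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.s_max <= 1:
            raise ValueError("s_max must be in (0, 1]")
        if set(self.mu) != set(self.sigma):
            raise ValueError("mu and sigma must cover the same factors")
        for f, s in self.sigma.items():
            if s <= 0:
                raise ValueError(f"sigma[{f!r}] must be positive")

    @property
    def factor_names(self) -> list[str]:
        return list(self.mu)

    def suitability(self, env: dict[str, np.ndarray] | pd.DataFrame) -> np.ndarray:
        """Evaluate the niche on per-factor value arrays (broadcastable)."""
        z2 = 0.0
        for f in self.mu:
            x = np.asarray(env[f], dtype=float)
            z2 = z2 + ((x - self.mu[f]) / self.sigma[f]) ** 2
        return self.s_max * np.exp(-0.5 * z2)


@dataclass(frozen=True)
class ScenarioForcing:
    """Additive per-cell bias plus a scenario warming trend for one GCM."""

    gcm_id: str
    rcp_id: str
    bias: np.ndarray  # (ny, nx) additive SBT bias, degC
    trend_per_decade: float  # degC per decade

    def __post_init__(self) -> None:
        if self.rcp_id not in RCP_TREND_PER_DECADE:
            raise ValueError(
                f"unknown RCP {self.rcp_id!r}; expected one of {sorted(RCP_TREND_PER_DECADE)}"
            )


@dataclass(frozen=True)
class WorldParams:
    """Knobs for the contemporary synthetic climate."""

    sbt_south: float = 25.0  # degC at the southern edge
    sbt_north: float = 5.0  # degC at the northern edge
    seasonal_amp_min: float = 0.5  # degC, western edge
    seasonal_amp_max: float = 7.0  # degC, eastern edge
    sss_west: float = 34.0
    sss_east: float = 38.0
    noise_sd: float = 0.25  # inter-annual monthly noise, degC
    n_years: int = 10
    land_columns: int = 5  # eastern strip of land cells
    shelf_depth: float = 50.0  # m at the coast
    max_depth: float = 2500.0  # m at the far edge


def build_grid(extent: tuple[float, float, float, float], resolution: float = 0.1) -> WorldGrid:
    """Build a grid from (lon_min, lon_max, lat_min, lat_max) and a resolution."""
    lon_min, lon_max, lat_min, lat_max = extent
    return WorldGrid(lon_min, lon_max, lat_min, lat_max, resolution)


def default_grid() -> WorldGrid:
    """Desk-scale default: 60 x 40 cells at 0.1 degrees."""
    return build_grid((0.0, 6.0, 40.0, 44.0), 0.1)


def _land_mask(grid: WorldGrid, land_columns: int) -> np.ndarray:
    land = np.zeros(grid.shape, dtype=bool)
    if land_columns > 0:
        land[:, grid.nx - land_columns :] = True
    return land


def generate_contemporary_stack(
    grid: WorldGrid,
    params: WorldParams | None = None,
    seed: int = 0,
) -> LayerStack:
    """Generate the contemporary environmental stack on a grid.

    The stack carries a monthly SBT series (so the thermal indices are
    derived, not injected), an SSS gradient, bathymetry deepening away
    from an eastern coastline (beyond 1000 m offshore, so depth-based
    cleaning is exercised), and distance to coast in km.
    """
    params = params or WorldParams()
    rng = np.random.default_rng(seed)
    ny, nx = grid.shape

    lat_frac = ((np.arange(ny) + 0.5) / ny)[:, None] * np.ones((1, nx))
    lon_frac = np.ones((ny, 1)) * ((np.arange(nx) + 0.5) / nx)[None, :]

    base_sbt = params.sbt_south + (params.sbt_north - params.sbt_south) * lat_frac
    amp = params.seasonal_amp_min + (params.seasonal_amp_max - params.seasonal_amp_min) * lon_frac

    months = np.arange(12)
    cycle = np.cos(2 * np.pi * (months - 7) / 12.0)  # warmest in August
    monthly = (
        base_sbt[None, None, :, :]
        + amp[None, None, :, :] * cycle[None, :, None, None]
        + rng.normal(0.0, params.noise_sd, size=(params.n_years, 12, ny, nx))
    )

    sbt, sbt_range, sbt_var = derive_thermal_indices(monthly)

    # diagonal SSS gradient + smooth noise, deliberately not collinear
    # with either thermal gradient
    sss = params.sss_west + (params.sss_east - params.sss_west) * (
        0.5 * lat_frac + 0.5 * lon_frac
    )
    sss = sss + gaussian_filter(rng.normal(0.0, 4.0, size=(ny, nx)), sigma=4)

    land = _land_mask(grid, params.land_columns)
    ocean = ~land

    # distance to coast (km); bathymetry: broad shelf, convex drop-off so
    # only a far-offshore fringe exceeds the 1000 m cleaning cutoff
    if land.any():
        dist_cells = distance_transform_edt(ocean)
        dist_km = dist_cells * grid.resolution * KM_PER_DEGREE
        max_dist = max(dist_km.max(), 1.0)
        depth = params.shelf_depth + (params.max_depth - params.shelf_depth) * (
            dist_km / max_dist
        ) ** 5
    else:
        dist_km = np.full(grid.shape, 1e6)
        depth = np.full(grid.shape, params.max_depth)

    factors = {
        "SBT": sbt,
        "SBTrange": sbt_range,
        "SBTvar": sbt_var,
        "SSS": sss,
        "bathymetry": depth,
        "dist_to_coast": dist_km,
    }
    for name in factors:
        factors[name] = np.where(ocean, factors[name], np.nan)

    return LayerStack(
        grid=grid,
        factors=factors,
        ocean_mask=ocean,
        period="contemporary",
        monthly_sbt=monthly,
        meta={"seed": seed},
    )


def make_forcing(
    grid: WorldGrid,
    gcm_id: str,
    rcp_id: str,
    bias_scale: float = 1.0,
    seed: int | None = None,
) -> ScenarioForcing:
    """Build a preset forcing: smooth seeded bias field + RCP warming trend."""
    if seed is None:
        seed = abs(hash(gcm_id)) % (2**31)
    rng = np.random.default_rng(seed)
    bias = gaussian_filter(rng.normal(0.0, 1.0, size=grid.shape), sigma=4)
    sd = bias.std()
    if sd > 0:
        bias = bias / sd * bias_scale
    bias = bias + rng.normal(0.0, 0.2)  # per-GCM mean offset
    return ScenarioForcing(
        gcm_id=gcm_id,
        rcp_id=rcp_id,
        bias=bias,
        trend_per_decade=RCP_TREND_PER_DECADE[rcp_id],
    )


def generate_gcm_stack(
    contemporary: LayerStack,
    forcing: ScenarioForcing,
    decade: str,
    seed: int = 0,
) -> LayerStack:
    """Scenario stack: contemporary SBT + bias + trend x (decades since baseline).

    The warming is applied to the monthly series and the thermal indices
    re-derived, so SBTrange/SBTvar respond consistently. SSS, bathymetry
    and distance to coast are held constant. The baseline decade carries
    the bias only.
    """
    if decade not in DECADES:
        raise ValueError(f"unknown decade {decade!r}; expected one of {sorted(DECADES)}")
    if contemporary.monthly_sbt is None:
        raise ValueError("contemporary stack lacks a monthly SBT series")
    if forcing.bias.shape != contemporary.grid.shape:
        raise ValueError("forcing bias field does not match the grid")

    warming = forcing.trend_per_decade * DECADES[decade]
    delta = forcing.bias[None, None, :, :] + warming
    monthly = contemporary.monthly_sbt + delta
    sbt, sbt_range, sbt_var = derive_thermal_indices(monthly)
    ocean = contemporary.ocean_mask

    factors = dict(contemporary.factors)
    factors["SBT"] = np.where(ocean, sbt, np.nan)
    factors["SBTrange"] = np.where(ocean, sbt_range, np.nan)
    factors["SBTvar"] = np.where(ocean, sbt_var, np.nan)

    return LayerStack(
        grid=contemporary.grid,
        factors=factors,
        ocean_mask=ocean,
        period=f"{forcing.gcm_id}/{forcing.rcp_id}/{decade}",
        monthly_sbt=monthly,
        meta={
            "gcm_id": forcing.gcm_id,
            "rcp_id": forcing.rcp_id,
            "decade": decade,
            "warming": warming,
        },
    )


def true_suitability_field(stack: LayerStack, niche: TrueNiche) -> np.ndarray:
    """Per-cell true suitability (NaN on land)."""
    missing = [f for f in niche.factor_names if f not in stack.factors]
    if missing:
        raise ValueError(f"niche factors missing from stack: {missing}")
    suit = niche.suitability(stack.factors)
    return np.where(stack.ocean_mask, suit, np.nan)


def sample_occurrences(
    stack: LayerStack,
    niche: TrueNiche,
    n_target: int,
    bias_field: np.ndarray | None = None,
    seed: int = 0,
    species: str = "Synthetus exemplaris",
    sources: tuple[str, ...] = ("obis", "gbif", "sealifebase"),
    year_range: tuple[int, int] = (1990, 2017),
) -> pd.DataFrame:
    """Sample presence records proportional to true suitability.

    Per-cell counts are Poisson with intensity proportional to
    suitability x sampling bias, scaled so the expected total is
    ``n_target``. Records land at positions jittered uniformly within
    their cell, with dates uniform over the contemporary period.
    """
    rng = np.random.default_rng(seed)
    suit = true_suitability_field(stack, niche)
    intensity = np.where(stack.ocean_mask, np.nan_to_num(suit), 0.0)
    if bias_field is not None:
        bias_field = np.asarray(bias_field, dtype=float)
        if bias_field.shape != stack.grid.shape:
            raise ValueError("bias_field shape does not match grid")
        if (bias_field < 0).any():
            raise ValueError("bias_field must be non-negative")
        intensity = intensity * bias_field
    total = intensity.sum()
    if total <= 0:
        raise ValueError("suitability x bias is zero over every ocean cell")

    # expected count reaches n_target only when the niche optimum is
    # attainable on the grid; an off-grid optimum thins the sample
    suit_ocean = suit[stack.ocean_mask]
    expected_total = n_target * float(np.nanmax(suit_ocean)) / niche.s_max
    counts = rng.poisson(intensity / total * expected_total)
    cells = np.repeat(np.arange(stack.grid.n_cells), counts.ravel())
    n = cells.size
    lon_c, lat_c = stack.grid.cell_center(cells)
    res = stack.grid.resolution
    lon = lon_c + rng.uniform(-0.5, 0.5, size=n) * res
    lat = lat_c + rng.uniform(-0.5, 0.5, size=n) * res

    y0, y1 = year_range
    days = rng.integers(0, (y1 - y0 + 1) * 365, size=n)
    dates = pd.Timestamp(f"{y0}-01-01") + pd.to_timedelta(days, unit="D")

    return pd.DataFrame(
        {
            "species": species,
            "decimalLongitude": lon,
            "decimalLatitude": lat,
            "eventDate": dates.strftime("%Y-%m-%d"),
            "source": rng.choice(sources, size=n),
        }
    )
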