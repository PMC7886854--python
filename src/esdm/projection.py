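"""Scenario projection: delta correction, multi-GCM ESI, filters, anomalies.

GCM fields are bias-corrected cell-by-cell against the observation
baseline (delta change), future suitability is predicted per GCM and
averaged per RCP x decade, the hierarchical depth/distance-to-coast mask
is applied a posteriori, and anomalies are future-minus-contemporary ESI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .env_stack import LayerStack, THERMAL_FACTORS
from .sdm_core import SuitabilityMap, ensemble_predict

__all__ = [
    "ScenarioSpec",
    "TaylorStats",
    "RCP_IDS",
    "PROJECTION_DECADES",
    "taylor_stats",
    "delta_correct",
    "delta_correct_stack",
    "project_future",
    "hierarchical_filter",
    "apply_hierarchical_filter",
    "anomaly",
]

RCP_IDS = ("RCP2.6", "RCP4.5", "RCP8.5")
PROJECTION_DECADES = ("2030-2039", "2050-2059", "2090-2099")


@dataclass(frozen=True)
class ScenarioSpec:
    """One GCM x RCP x decade projection slot."""

    gcm_id: str
    rcp_id: str
    decade: str

    def __post_init__(self) -> None:
        if self.rcp_id not in RCP_IDS:
            raise ValueError(f"unknown RCP {self.rcp_id!r}; expected one of {RCP_IDS}")
        if self.decade not in PROJECTION_DECADES:
            raise ValueError(
                f"unknown decade {self.decade!r}; expected one of {PROJECTION_DECADES}"
            )


@dataclass(frozen=True)
class TaylorStats:
    """Taylor-diagram statistics of a model field against observations."""

    pearson_r: float
    sd_ratio: float
    centered_rmsd: float


def taylor_stats(obs_field: np.ndarray, model_field: np.ndarray) -> TaylorStats:
    """Pearson r, SD ratio and centered RMSD over jointly valid cells."""
    obs = np.asarray(obs_field, dtype=float).ravel()
    mod = np.asarray(model_field, dtype=float).ravel()
    if obs.shape != mod.shape:
        raise ValueError("fields are not aligned")
    valid = np.isfinite(obs) & np.isfinite(mod)
    if valid.sum() < 2:
        raise ValueError("need at least 2 jointly valid cells")
    o, m = obs[valid], mod[valid]
    oc, mc = o - o.mean(), m - m.mean()
    so, sm = o.std(), m.std()
    if so == 0 or sm == 0:
        r = 1.0 if np.allclose(oc, mc) else 0.0
    else:
        r = float(np.dot(oc, mc) / (len(o) * so * sm))
    return TaylorStats(
        pearson_r=r,
        sd_ratio=float(sm / so) if so > 0 else np.inf,
        centered_rmsd=float(np.sqrt(np.mean((mc - oc) ** 2))),
    )


def delta_correct(
    gcm_field: np.ndarray,
    obs_baseline: np.ndarray,
    gcm_baseline: np.ndarray,
) -> np.ndarray:
    """Per-cell delta-change correction of one scenario field.

    corrected(cell) = gcm(cell) - (gcm_baseline(cell) - obs_baseline(cell)).
    Applying it to the GCM baseline itself reproduces the observation
    baseline exactly (r = 1, zero SD difference, zero RMSD).
    """
    gcm_field = np.asarray(gcm_field, dtype=float)
    obs_baseline = np.asarray(obs_baseline, dtype=float)
    gcm_baseline = np.asarray(gcm_baseline, dtype=float)
    if not (gcm_field.shape == obs_baseline.shape == gcm_baseline.shape):
        raise ValueError("fields are not aligned")
    valid = np.isfinite(gcm_field)
    missing = valid & (~np.isfinite(obs_baseline) | ~np.isfinite(gcm_baseline))
    if missing.any():
        raise ValueError(f"baseline missing for {int(missing.sum())} cell(s)")
    return gcm_field - (gcm_baseline - obs_baseline)


def delta_correct_stack(
    scenario: LayerStack,
    obs_baseline: LayerStack,
    gcm_baseline: LayerStack,
    factors: tuple[str, ...] = THERMAL_FACTORS,
) -> LayerStack:
    """Delta-correct the time-varying factors of a scenario stack.

    Only the named (thermal) factors are corrected; SSS and the static
    fields are inherited from the observation baseline, which also pins
    them constant in time.
    """
    corrected = {
        f: delta_correct(scenario.factors[f], obs_baseline.factors[f], gcm_baseline.factors[f])
        for f in factors
        if f in scenario.factors
    }
    out = scenario.with_factors(corrected, delta_corrected=True)
    # factors "kept constant in time" come straight from the observations
    static = {
        f: obs_baseline.factors[f] for f in obs_baseline.factors if f not in corrected
    }
    return out.with_factors(static)


def project_future(
    members,
    corrected_stacks: dict[str, LayerStack],
    factor_names,
    rcp_id: str,
    decade: str,
) -> SuitabilityMap:
    """Project ESI for one RCP x decade from per-GCM corrected stacks.

    ESI is predicted per GCM with the full member set, then averaged
    across GCMs; the SD pools all member x replicate x GCM predictions.
    """
    if not corrected_stacks:
        raise ValueError("no corrected scenario stacks supplied")
    per_gcm = []
    all_preds = []
    grid = None
    for gcm_id, stack in sorted(corrected_stacks.items()):
        smap = ensemble_predict(members, stack, factor_names, scenario=gcm_id, decade=decade)
        per_gcm.append(smap.esi)
        grid = stack.grid
        cells, X = stack.background_env(factor_names)
        all_preds.append(
            np.vstack([np.asarray(m.predict(X), dtype=float) for m in members])
        )
    stacked = np.stack(per_gcm)
    n_valid = np.isfinite(stacked).sum(axis=0)
    esi = np.where(
        n_valid > 0, np.nansum(stacked, axis=0) / np.maximum(n_valid, 1), np.nan
    )
    pooled = np.vstack(all_preds)  # (members*gcms, n_ocean_cells)
    sd = np.full(grid.shape, np.nan)
    sd.ravel()[cells] = pooled.std(axis=0, ddof=0)
    return SuitabilityMap(
        grid=grid,
        esi=esi,
        sd=sd,
        scenario=rcp_id,
        decade=decade,
        meta={"n_gcms": len(corrected_stacks), "n_members": len(list(members))},
    )


def hierarchical_filter(
    field2d: np.ndarray,
    bathymetry: np.ndarray,
    dist_to_coast: np.ndarray,
    depth_max: float = 300.0,
    coast_km: float = 50.0,
    coast_enabled: bool = False,
) -> np.ndarray:
    """A-posteriori geographic mask on a suitability field.

    A cell is retained iff its depth is at most ``depth_max`` m, or the
    coast filter is enabled and the cell lies within ``coast_km`` of the
    coast; all other cells become NaN (missing, not zero).
    """
    field2d = np.asarray(field2d, dtype=float)
    bathymetry = np.asarray(bathymetry, dtype=float)
    if bathymetry.shape != field2d.shape:
        raise ValueError("bathymetry not aligned with the field")
    keep = bathymetry <= depth_max
    if coast_enabled:
        dist = np.asarray(dist_to_coast, dtype=float)
        if dist.shape != field2d.shape:
            raise ValueError("dist_to_coast not aligned with the field")
        keep = keep | (dist <= coast_km)
    keep = keep & np.isfinite(bathymetry)
    return np.where(keep, field2d, np.nan)


def apply_hierarchical_filter(
    smap: SuitabilityMap,
    stack: LayerStack,
    depth_max: float = 300.0,
    coast_km: float = 50.0,
    coast_enabled: bool = False,
) -> SuitabilityMap:
    """Hierarchical filter applied to both the ESI and SD fields of a map."""
    esi = hierarchical_filter(
        smap.esi, stack.factors["bathymetry"], stack.factors["dist_to_coast"],
        depth_max, coast_km, coast_enabled,
    )
    sd = hierarchical_filter(
        smap.sd, stack.factors["bathymetry"], stack.factors["dist_to_coast"],
        depth_max, coast_km, coast_enabled,
    )
    return SuitabilityMap(
        grid=smap.grid,
        esi=esi,
        sd=sd,
        scenario=smap.scenario,
        decade=smap.decade,
        mask_applied=True,
        meta=dict(smap.meta),
    )


def anomaly(future: SuitabilityMap, contemporary: SuitabilityMap) -> np.ndarray:
    """Future minus contemporary ESI per retained cell (range within [-1, 1])."""
    if future.grid.shape != contemporary.grid.shape:
        raise ValueError("maps are on different grids")
    fmask = np.isfinite(future.esi)
    cmask = np.isfinite(contemporary.esi)
    if not np.array_equal(fmask, cmask):
        raise ValueError("maps carry different masks; filter both identically first")
    return future.esi - contemporary.esi
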