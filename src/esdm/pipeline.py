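"""End-to-end orchestration of the modelling pipeline.

Stages mirror the methods sequence: simulate -> clean -> fit/evaluate ->
project -> centroids -> report. Intermediate results are kept on a
:class:`RunState`; CSV/JSON outputs are written into a run directory with
the config hash and seed registry embedded for provenance. Every stage is
deterministic given the config seeds.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, geography, niche_sampling, occurrence_pipeline, projection
from . import synthetic_world as sw
from .config import RunConfig
from .env_stack import (
    LayerStack,
    candidate_factor_sets,
    collinearity_screen,
    permutation_importance,
)
from .sdm_core import fit_nppen
from .grid import WorldGrid
from .niche_sampling import HULL_QUANTILES, default_bin_widths
from .sdm_core import SuitabilityMap, ensemble_predict
from .synthetic_world import TrueNiche

__all__ = ["RunState", "EnsembleModel", "run_pipeline"]

log = logging.getLogger("esdm")


@dataclass
class EnsembleModel:
    """Selected members (algorithm x CV replicate) plus their configuration."""

    members: list
    member_labels: list[str]
    factor_names: tuple[str, ...]
    quantiles: tuple[float, float]
    coast_filter: bool
    depth_max: float
    cbi_by_algorithm: dict[str, float]

    def predict_map(self, stack: LayerStack, scenario="contemporary", decade="contemporary"):
        return ensemble_predict(self.members, stack, self.factor_names, scenario, decade)


@dataclass
class RunState:
    """Mutable bag of per-stage results for one run."""

    config: RunConfig
    grid: WorldGrid | None = None
    stack: LayerStack | None = None
    niche: TrueNiche | None = None
    occurrences_raw: pd.DataFrame | None = None
    occurrences_clean: pd.DataFrame | None = None
    rejections: pd.DataFrame | None = None
    occurrence_set: occurrence_pipeline.OccurrenceSet | None = None
    ensemble: EnsembleModel | None = None
    selection_report: pd.DataFrame | None = None
    contemporary_map: SuitabilityMap | None = None
    future_maps: dict = field(default_factory=dict)  # (rcp, decade) -> SuitabilityMap
    anomalies: dict = field(default_factory=dict)
    centroids: pd.DataFrame | None = None
    counts: dict = field(default_factory=dict)


def _provenance(cfg: RunConfig) -> dict:
    return {"config_hash": cfg.config_hash(), "seeds": dict(cfg.seeds)}


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash()} seeds={json.dumps(cfg.seeds, sort_keys=True)}\n")
        df.to_csv(fh, index=False)


def stage_simulate(state: RunState, outdir: Path | None = None) -> RunState:
    cfg = state.config
    state.grid = sw.build_grid(
        (
            cfg.grid["lon_min"], cfg.grid["lon_max"],
            cfg.grid["lat_min"], cfg.grid["lat_max"],
        ),
        cfg.grid.get("resolution", 0.1),
    )
    state.stack = sw.generate_contemporary_stack(state.grid, seed=cfg.seeds["world"])
    state.niche = TrueNiche(
        mu=cfg.niche["mu"], sigma=cfg.niche["sigma"], s_max=cfg.niche.get("s_max", 1.0)
    )
    state.occurrences_raw = sw.sample_occurrences(
        state.stack, state.niche, cfg.n_occurrences,
        seed=cfg.seeds["occurrences"], species=cfg.species,
    )
    state.counts["raw_records"] = len(state.occurrences_raw)
    log.info("simulate: %d raw occurrence records", len(state.occurrences_raw))
    if outdir:
        _write_csv(state.occurrences_raw, outdir / "occurrences_raw.csv", cfg)
        state.stack.to_dataset().to_netcdf(outdir / "contemporary_stack.nc")
    return state


def stage_clean(state: RunState, outdir: Path | None = None) -> RunState:
    cfg = state.config
    kept, rejected = occurrence_pipeline.clean_records(
        state.occurrences_raw,
        state.grid,
        land_mask=~state.stack.ocean_mask,
        bathymetry=np.nan_to_num(state.stack.factors["bathymetry"], nan=0.0),
        depth_cutoff_m=cfg.filters.get("depth_cutoff", 1000.0),
    )
    state.occurrences_clean = kept
    state.rejections = rejected
    state.occurrence_set = occurrence_pipeline.grid_occurrences(kept, state.grid)
    state.counts.update(
        kept_records=len(kept),
        rejected_records=len(rejected),
        rejection_reasons=rejected["reason"].value_counts().to_dict() if len(rejected) else {},
        presence_cells=state.occurrence_set.n_cells,
    )
    log.info(
        "clean: kept %d / rejected %d -> %d presence cells",
        len(kept), len(rejected), state.occurrence_set.n_cells,
    )
    if outdir:
        _write_csv(kept, outdir / "occurrences_clean.csv", cfg)
        _write_csv(rejected, outdir / "rejections.csv", cfg)
    return state


def _presence_env(state: RunState, factor_names) -> pd.DataFrame:
    cells = state.occurrence_set.cells
    X = state.stack.env_at_cells(cells, factor_names)
    df = pd.DataFrame(X, columns=list(factor_names))
    df["cell"] = cells
    return df.dropna().reset_index(drop=True)


def _background_env(state: RunState, factor_names) -> pd.DataFrame:
    cells, X = state.stack.background_env(factor_names)
    df = pd.DataFrame(X, columns=list(factor_names))
    df["cell"] = cells
    return df.dropna().reset_index(drop=True)


def _pre_screen_factors(state: RunState) -> list[str]:
    """Collinearity screen of the candidate factors over presence cells.

    Importance of each factor comes from permuting it under an NPPEN
    model fitted on all candidates; within each intercorrelated group
    only the most important factor survives (SBT unconditionally).
    """
    cfg = state.config
    factors = list(cfg.factor_candidates)
    cells = state.occurrence_set.cells
    X = state.stack.env_at_cells(cells, factors)
    keep_rows = np.all(np.isfinite(X), axis=1)
    model = fit_nppen(X[keep_rows], factor_names=factors)
    importance = {
        f: permutation_importance(model.predict, state.stack, factors, f, seed=cfg.seeds["cv"])
        for f in factors
    }
    retained = collinearity_screen(state.stack, cells[keep_rows], factors, importance)
    state.counts["factor_importance"] = {k: round(v, 4) for k, v in importance.items()}
    log.info("pre-treatment: importance=%s retained=%s", importance, retained)
    return retained


def stage_fit(state: RunState, outdir: Path | None = None) -> RunState:
    """Evaluate every candidate configuration and select the ensemble."""
    cfg = state.config
    candidate_factors = _pre_screen_factors(state) if cfg.pre_screen else cfg.factor_candidates
    state.counts["screened_factors"] = list(candidate_factors)
    factor_sets = [
        (fs, coast)
        for fs, coast in candidate_factor_sets(
            candidate_factors, include_coast_filter=cfg.include_coast_candidates
        )
    ]
    quantiles = [tuple(q) for q in cfg.hull_quantiles] or list(HULL_QUANTILES)
    candidates = []
    for factors, coast in factor_sets:
        presence = _presence_env(state, factors)
        background = _background_env(state, factors)
        widths = default_bin_widths(factors) | {
            k: v for k, v in cfg.bin_widths.items() if k in factors
        }
        for q in quantiles:
            try:
                dataset = niche_sampling.build_niche_dataset(
                    presence, background, factors, q=q, bin_widths=widths,
                    seed=cfg.seeds["pseudo_absence"],
                )
            except ValueError as e:
                log.info("fit: skipping factors=%s q=%s (%s)", factors, q, e)
                continue
            splits = evaluation.make_cv_splits(
                dataset, n_rep=cfg.cv["n_rep"], frac=cfg.cv["frac"], seed=cfg.seeds["cv"]
            )
            for alg in cfg.algorithms:
                cand = evaluation.evaluate_candidate(
                    alg, dataset, splits, background, state.stack,
                    coast_filter=coast,
                    window_width=cfg.cbi["window_width"],
                    n_windows=cfg.cbi["n_windows"],
                )
                candidates.append((cand, dataset, splits))
                log.info(
                    "fit: %s factors=%s q=%s coast=%s CBI=%.3f curves=%s",
                    alg, "+".join(factors), q, coast, cand.mean_cbi, cand.curves_pass,
                )

    best_members, report = evaluation.select_ensemble(
        [c for c, _, _ in candidates], threshold=cfg.cbi["threshold"]
    )
    state.selection_report = report

    # refit retained algorithms on every CV calibration set: the ensemble
    # spreads over algorithms x cross-validation replicates
    members, labels = [], []
    cbi_by_alg = {}
    best = best_members[0]
    for cand, dataset, splits in candidates:
        if cand not in best_members:
            continue
        cbi_by_alg[cand.algorithm_id] = cand.mean_cbi
        for split in splits:
            m = evaluation._fit_algorithm(cand.algorithm_id, dataset, split.cal_idx, split.seed)
            members.append(m)
            labels.append(f"{cand.algorithm_id}/rep{split.replicate_id}")
    state.ensemble = EnsembleModel(
        members=members,
        member_labels=labels,
        factor_names=best.factor_names,
        quantiles=best.quantiles,
        coast_filter=best.coast_filter,
        depth_max=cfg.filters["depth_max"],
        cbi_by_algorithm=cbi_by_alg,
    )
    state.counts["ensemble_members"] = len(members)

    smap = state.ensemble.predict_map(state.stack)
    state.contemporary_map = projection.apply_hierarchical_filter(
        smap, state.stack,
        depth_max=cfg.filters["depth_max"],
        coast_km=cfg.filters["coast_km"],
        coast_enabled=state.ensemble.coast_filter,
    )
    log.info(
        "fit: selected factors=%s q=%s with %d members",
        "+".join(best.factor_names), best.quantiles, len(members),
    )
    if outdir:
        _write_csv(report, outdir / "selection_report.csv", cfg)
        state.contemporary_map.to_dataset().to_netcdf(outdir / "esi_contemporary.nc")
    return state


def stage_project(state: RunState, outdir: Path | None = None) -> RunState:
    cfg = state.config
    ens = state.ensemble
    scen = cfg.scenarios
    gcm_seed = cfg.seeds["gcm"]
    for rcp in scen["rcp_ids"]:
        # per-GCM baseline and future stacks, delta-corrected against obs
        for decade in scen["decades"]:
            corrected = {}
            for k, gcm in enumerate(scen["gcm_ids"]):
                forcing = sw.make_forcing(
                    state.grid, gcm, rcp,
                    bias_scale=scen.get("bias_scale", 1.0), seed=gcm_seed + k,
                )
                baseline = sw.generate_gcm_stack(state.stack, forcing, "baseline")
                future = sw.generate_gcm_stack(state.stack, forcing, decade)
                corrected[gcm] = projection.delta_correct_stack(future, state.stack, baseline)
            smap = projection.project_future(
                ens.members, corrected, ens.factor_names, rcp_id=rcp, decade=decade
            )
            smap = projection.apply_hierarchical_filter(
                smap, state.stack,
                depth_max=cfg.filters["depth_max"],
                coast_km=cfg.filters["coast_km"],
                coast_enabled=ens.coast_filter,
            )
            state.future_maps[(rcp, decade)] = smap
            state.anomalies[(rcp, decade)] = projection.anomaly(smap, state.contemporary_map)
            log.info("project: %s %s done (%d GCMs)", rcp, decade, len(corrected))
            if outdir:
                tag = f"{rcp.replace('.', '')}_{decade}"
                smap.to_dataset().to_netcdf(outdir / f"esi_{tag}.nc")
    return state


def stage_centroids(state: RunState, outdir: Path | None = None) -> RunState:
    cfg = state.config
    region = geography.RegionMask("domain", state.stack.ocean_mask)
    rows = []
    c0 = geography.weighted_centroid(state.contemporary_map.esi, state.grid, region)
    rows.append(
        {"region": region.region_id, "rcp": "contemporary", "decade": "contemporary",
         "lon": c0.lon, "lat": c0.lat, "dlon": 0.0, "dlat": 0.0}
    )
    for (rcp, decade), smap in sorted(state.future_maps.items()):
        c = geography.weighted_centroid(smap.esi, state.grid, region, scenario=rcp, decade=decade)
        dlon, dlat = geography.centroid_shift(c0, c)
        rows.append(
            {"region": region.region_id, "rcp": rcp, "decade": decade,
             "lon": c.lon, "lat": c.lat, "dlon": dlon, "dlat": dlat}
        )
    state.centroids = pd.DataFrame(rows)
    if outdir:
        _write_csv(state.centroids, outdir / "centroids.csv", cfg)
    return state


def stage_report(state: RunState, outdir: Path | None = None) -> dict:
    cfg = state.config
    report = {
        "provenance": _provenance(cfg),
        "species": cfg.species,
        "counts": state.counts,
        "selected_factors": list(state.ensemble.factor_names) if state.ensemble else None,
        "selected_quantiles": list(state.ensemble.quantiles) if state.ensemble else None,
        "cbi_by_algorithm": state.ensemble.cbi_by_algorithm if state.ensemble else None,
    }
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


_STAGES = ("simulate", "clean", "fit", "project", "centroids", "report")


def run_pipeline(config: RunConfig, outdir: str | Path | None = None, until: str = "report") -> RunState:
    """Run the pipeline up to (and including) a stage; returns the state."""
    if until not in _STAGES:
        raise ValueError(f"unknown stage {until!r}; expected one of {_STAGES}")
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    state = RunState(config=config)
    t0 = time.time()
    for stage_name in _STAGES[: _STAGES.index(until) + 1]:
        fn = globals()[f"stage_{stage_name}"]
        fn(state, out)
    log.info("pipeline finished through %s in %.1f s", until, time.time() - t0)
    return state
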