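# esdm

Ensemble species distribution modelling pipeline, driven end to end by a
synthetic-world generator so every stage is testable offline:

- **synthetic_world** — cell-centred 0.1° grids, gradient climates with
  monthly bottom-temperature series, a known Gaussian-in-environment true
  niche, occurrence sampling proportional to suitability (with optional
  spatial sampling bias), and GCM-like scenario fields built as
  contemporary + per-cell additive bias + RCP-dependent warming trend.
- **occurrence_pipeline** — record cleaning (duplicates, on-land,
  out-of-range coordinates, flag-based exclusions, precautionary 1000 m
  bathymetry cutoff) with machine-readable rejection reasons, and
  aggregation to unique presence cells.
- **env_stack** — aligned predictor stacks; thermal indices (mean SBT,
  intra-annual range, inter-month variance — per year, then averaged);
  bilinear regridding; a Pearson |r| > 0.7 collinearity screen keeping the
  most important factor per correlated group; permutation-based factor
  importance (1 − r between reference and factor-permuted suitability maps).
- **niche_sampling** — environmental filtration (one presence per 0.5 °C ×
  0.5 bin), restricted convex hulls (per-dimension quantile trims 2.5–97.5 /
  5–95 / 10–90), and pseudo-absence sampling strictly outside the hull in
  equal number to the filtered presences.
- **sdm_core** — NPPEN implemented from scratch (empirical survival
  function of squared Mahalanobis distance to the presence centroid,
  ridged covariance, presence-only calibration) plus seven classifier
  members (GLM, GAM, GBM, ANN, FDA, MARS, RF) behind one
  `predict(X) -> [0, 1]` contract; unweighted ensemble mean with pooled SD.
- **evaluation** — stratified 10× random 70/30 cross-validation, the
  Continuous Boyce Index (width-0.1 windows, 101 midpoints, Spearman of
  midpoint vs presence/expected ratio), response-curve multimodality
  screening, and CBI > 0.5 ensemble selection with a Table-style report.
- **projection** — Taylor statistics, per-cell delta-change bias
  correction (corrected baseline reproduces observations exactly),
  multi-GCM × RCP × decade ESI projection, hierarchical depth ≤ 300 m /
  coast ≤ 50 km masking, and future-minus-contemporary anomalies.
- **geography** — region masks (Atlantic façade / Mediterranean split at
  the Gibraltar meridian, or custom boxes) and ESI-weighted distributional
  centroids with shift decomposition.

## CLI

```bash
esdm init-config config.yaml          # write the default configuration
esdm run --config config.yaml --out runs/demo --seed 1
# or stage by stage:
esdm simulate --out runs/demo
esdm clean    --out runs/demo
esdm fit      --out runs/demo
esdm project  --out runs/demo
esdm centroids --out runs/demo
```

A full default run (60×40 grid, 500 occurrences, 30 candidate models,
5 GCMs × 3 RCPs × 3 decades) takes a few seconds on one CPU. Outputs
(cleaned/rejected occurrence CSVs, selection report, ESI NetCDF maps,
centroid tracks, JSON report) embed the config hash and seed registry;
reruns with the same seeds are byte-identical.

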