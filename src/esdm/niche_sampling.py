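"""Environmental filtration and convex-hull pseudo-absence selection.

Presences are thinned to one point per multidimensional environmental bin
(0.5 degC for thermal factors, 0.5 for salinity by default), removing the
imprint of spatially heterogeneous sampling effort. Pseudo-absences are
then drawn uniformly from background (ocean-cell) environments lying
strictly outside a *restricted convex hull* of the filtered presences —
the hull of the points remaining after trimming outer per-dimension
quantiles — in equal number to the presences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .env_stack import THERMAL_FACTORS

__all__ = [
    "DEFAULT_BIN_WIDTHS",
    "HULL_QUANTILES",
    "RestrictedHull",
    "NicheDataset",
    "default_bin_widths",
    "environmental_filter",
    "build_restricted_hull",
    "sample_pseudo_absences",
    "build_niche_dataset",
]

#: filtration bin widths: 0.5 degC for thermal factors, 0.5 for SSS
DEFAULT_BIN_WIDTHS: dict[str, float] = {f: 0.5 for f in THERMAL_FACTORS} | {"SSS": 0.5}

#: outer-quantile pairs (percent) tested for the restricted hull
HULL_QUANTILES: tuple[tuple[float, float], ...] = ((2.5, 97.5), (5.0, 95.0), (10.0, 90.0))

_INSIDE_TOL = 1e-9


def default_bin_widths(factor_names) -> dict[str, float]:
    """Bin widths for a factor set (0.5 everywhere by default)."""
    return {f: DEFAULT_BIN_WIDTHS.get(f, 0.5) for f in factor_names}


def _env_matrix(points: pd.DataFrame, factor_names) -> np.ndarray:
    return points[list(factor_names)].to_numpy(dtype=float)


def environmental_filter(
    points: pd.DataFrame,
    bin_widths: dict[str, float],
) -> pd.DataFrame:
    """Keep one point per occupied multidimensional environmental bin.

    ``points`` must carry one column per factor in ``bin_widths`` plus a
    ``cell`` column; the keeper within a bin is the first point in
    deterministic cell-id order. Idempotent by construction.
    """
    for f, w in bin_widths.items():
        if w <= 0:
            raise ValueError(f"bin width for {f!r} must be positive, got {w}")
        if f not in points.columns:
            raise ValueError(f"points lack factor column {f!r}")
    if points.empty:
        return points.copy()
    df = points.sort_values("cell", kind="stable").reset_index(drop=True)
    bins = pd.DataFrame(
        {f: np.floor(df[f].to_numpy(dtype=float) / w).astype(np.int64) for f, w in bin_widths.items()}
    )
    keep = ~bins.duplicated(keep="first")
    return df[keep.to_numpy()].reset_index(drop=True)


@dataclass
class RestrictedHull:
    """Convex hull of quantile-trimmed presence environments.

    For dimensionality >= 2, ``equations`` are Qhull facet half-spaces
    (A x + b <= 0 inside). In 1-D the hull degenerates to the interval
    between the trimmed minimum and maximum. Boundary points count as
    inside (tolerance 1e-9 in factor units).
    """

    quantiles: tuple[float, float]
    factor_names: tuple[str, ...]
    lower: np.ndarray  # per-dimension trimmed quantile bounds
    upper: np.ndarray
    n_retained: int
    equations: np.ndarray | None = None  # (n_facets, d+1) for d >= 2
    interval: tuple[float, float] | None = None  # for d == 1
    vertices: np.ndarray | None = None  # hull-vertex coordinates

    @property
    def ndim(self) -> int:
        return len(self.factor_names)

    def contains(self, X: np.ndarray) -> np.ndarray:
        """Boolean point-in-hull test (boundary counts as inside)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.ndim:
            raise ValueError(f"points have {X.shape[1]} dims, hull has {self.ndim}")
        if self.ndim == 1:
            lo, hi = self.interval
            return (X[:, 0] >= lo - _INSIDE_TOL) & (X[:, 0] <= hi + _INSIDE_TOL)
        return np.all(X @ self.equations[:, :-1].T + self.equations[:, -1] <= _INSIDE_TOL, axis=1)


def build_restricted_hull(
    points: pd.DataFrame | np.ndarray,
    q: tuple[float, float],
    factor_names=None,
) -> RestrictedHull:
    """Build the restricted convex hull of presence environments.

    Points outside the ``[q_low, q_high]`` empirical quantiles in *any*
    dimension are dropped; the hull is the convex hull of the remainder.
    ``q = (0, 100)`` leaves the cloud untrimmed.
    """
    q_low, q_high = q
    if not (0 <= q_low < q_high <= 100):
        raise ValueError(f"invalid quantile pair {q}")
    if isinstance(points, pd.DataFrame):
        if factor_names is None:
            factor_names = [c for c in points.columns if c != "cell"]
        X = _env_matrix(points, factor_names)
    else:
        X = np.atleast_2d(np.asarray(points, dtype=float))
        if factor_names is None:
            factor_names = [f"f{i}" for i in range(X.shape[1])]
    d = X.shape[1]

    lower = np.percentile(X, q_low, axis=0)
    upper = np.percentile(X, q_high, axis=0)
    keep = np.all((X >= lower) & (X <= upper), axis=1)
    Xt = X[keep]
    if Xt.shape[0] < d + 1:
        raise ValueError(
            f"only {Xt.shape[0]} points remain after trimming to q={q}; need >= {d + 1}"
        )

    base = dict(
        quantiles=(float(q_low), float(q_high)),
        factor_names=tuple(factor_names),
        lower=lower,
        upper=upper,
        n_retained=int(Xt.shape[0]),
    )
    if d == 1:
        return RestrictedHull(
            **base,
            interval=(float(Xt.min()), float(Xt.max())),
            vertices=np.array([[Xt.min()], [Xt.max()]]),
        )
    try:
        hull = ConvexHull(Xt)
    except QhullError as e:  # degenerate cloud (e.g. collinear points)
        raise ValueError(f"degenerate presence cloud, convex hull failed: {e}") from e
    return RestrictedHull(**base, equations=hull.equations, vertices=Xt[hull.vertices])


def sample_pseudo_absences(
    background: pd.DataFrame,
    hull: RestrictedHull,
    n: int,
    bin_widths: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw ``n`` pseudo-absences outside the restricted hull.

    The background pool (all ocean-cell environments) is first
    deduplicated at the filtration bin widths, then restricted to points
    strictly outside the hull; ``n`` points are sampled uniformly without
    replacement. Raises with the deficit if fewer than ``n`` points are
    eligible (the caller may widen the trimming quantiles).
    """
    factor_names = list(hull.factor_names)
    bin_widths = bin_widths or default_bin_widths(factor_names)
    pool = environmental_filter(background, {f: bin_widths[f] for f in factor_names})
    outside = ~hull.contains(_env_matrix(pool, factor_names))
    pool = pool[outside]
    if len(pool) < n:
        raise ValueError(
            f"only {len(pool)} eligible background points outside the hull, "
            f"need {n} (deficit {n - len(pool)}); consider a wider quantile trim"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return pool.iloc[np.sort(idx)].reset_index(drop=True)


@dataclass
class NicheDataset:
    """Filtered presences + matched pseudo-absences for one factor set."""

    presences: pd.DataFrame
    absences: pd.DataFrame
    factor_names: tuple[str, ...]
    hull: RestrictedHull

    def __post_init__(self) -> None:
        if len(self.presences) != len(self.absences):
            raise ValueError(
                f"presence/pseudo-absence parity violated: "
                f"{len(self.presences)} vs {len(self.absences)}"
            )

    @property
    def n(self) -> int:
        return len(self.presences)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with a ``role`` column (serializable to CSV)."""
        pres = self.presences.copy()
        pres.insert(0, "role", "presence")
        absn = self.absences.copy()
        absn.insert(0, "role", "pseudo_absence")
        return pd.concat([pres, absn], ignore_index=True)

    def design(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) for classifier calibration; y=1 presence, 0 absence."""
        X = np.vstack(
            [
                _env_matrix(self.presences, self.factor_names),
                _env_matrix(self.absences, self.factor_names),
            ]
        )
        y = np.concatenate([np.ones(len(self.presences)), np.zeros(len(self.absences))])
        return X, y


def build_niche_dataset(
    presence_env: pd.DataFrame,
    background_env: pd.DataFrame,
    factor_names,
    q: tuple[float, float] = (10.0, 90.0),
    bin_widths: dict[str, float] | None = None,
    seed: int = 0,
) -> NicheDataset:
    """Filter presences, build the restricted hull, and draw pseudo-absences."""
    factor_names = tuple(factor_names)
    bin_widths = bin_widths or default_bin_widths(factor_names)
    widths = {f: bin_widths[f] for f in factor_names}
    filtered = environmental_filter(presence_env, widths)
    hull = build_restricted_hull(filtered, q, factor_names)
    absences = sample_pseudo_absences(background_env, hull, len(filtered), widths, seed=seed)
    return NicheDataset(
        presences=filtered, absences=absences, factor_names=factor_names, hull=hull
    )
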