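"""Ensemble members: the NPPEN profile model and standard classifiers.

NPPEN (non-parametric probabilistic ecological niche) is fitted on the
filtered presences only. It scores a candidate environment by the
proportion of reference presences whose Mahalanobis distance from the
presence centroid is at least as large as the candidate's — an empirical
survival function of squared Mahalanobis distance, so the centroid scores
1 and environments beyond the reference cloud score 0.

Classifier members (GLM, GAM, GBM, ANN, FDA, MARS, RF) calibrate on
presences + pseudo-absences through standard scikit-learn estimators and
expose one contract: ``predict(X) -> suitability in [0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler

from .env_stack import LayerStack
from .grid import WorldGrid

__all__ = [
    "ALGORITHM_IDS",
    "NppenModel",
    "ClassifierMember",
    "SuitabilityMap",
    "fit_nppen",
    "predict_nppen",
    "fit_member",
    "ensemble_predict",
]

ALGORITHM_IDS = ("NPPEN", "GLM", "GAM", "GBM", "ANN", "FDA", "MARS", "RF")

_COND_LIMIT = 1e10


@dataclass
class NppenModel:
    """Fitted NPPEN state: presence centroid, covariance, reference distances."""

    mean: np.ndarray  # (d,)
    cov: np.ndarray  # (d, d), ridged if ill-conditioned
    cov_inv: np.ndarray
    ref_d2: np.ndarray  # squared Mahalanobis distances of reference points
    ref_d2_sorted: np.ndarray = field(init=False)
    factor_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.ref_d2_sorted = np.sort(self.ref_d2)

    @property
    def n(self) -> int:
        return self.ref_d2.size

    @property
    def ndim(self) -> int:
        return self.mean.size

    def mahalanobis_sq(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        diff = X - self.mean
        return np.einsum("ij,jk,ik->i", diff, self.cov_inv, diff)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_nppen(self, X)


def fit_nppen(X: np.ndarray, factor_names=None, leave_one_out: bool = False) -> NppenModel:
    """Fit NPPEN on filtered presence environments.

    Requires n > d and no zero-variance factor. The covariance gets a
    ridge of ``1e-6 * trace(V) / d`` on the diagonal when ill-conditioned
    (condition number > 1e10 or singular), so duplicated columns do not
    break the fit. With ``leave_one_out`` each reference distance is
    computed against the mean/covariance of the other n-1 points.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    if n <= d:
        raise ValueError(f"NPPEN needs more points than dimensions (n={n}, d={d})")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [i for i, s in enumerate(sd) if s == 0]
        raise ValueError(f"zero-variance factor column(s): {bad}")

    mean = X.mean(axis=0)
    cov = np.atleast_2d(np.cov(X, rowvar=False))
    if not np.all(np.isfinite(cov)) or np.linalg.cond(cov) > _COND_LIMIT:
        cov = cov + np.eye(d) * (1e-6 * np.trace(cov) / d)
    cov_inv = np.linalg.inv(cov)

    if leave_one_out:
        ref_d2 = np.empty(n)
        idx = np.arange(n)
        for i in range(n):
            Xi = X[idx != i]
            mi = Xi.mean(axis=0)
            Vi = np.atleast_2d(np.cov(Xi, rowvar=False))
            if not np.all(np.isfinite(Vi)) or np.linalg.cond(Vi) > _COND_LIMIT:
                Vi = Vi + np.eye(d) * (1e-6 * np.trace(Vi) / d)
            diff = X[i] - mi
            ref_d2[i] = diff @ np.linalg.solve(Vi, diff)
    else:
        diff = X - mean
        ref_d2 = np.einsum("ij,jk,ik->i", diff, cov_inv, diff)

    return NppenModel(
        mean=mean,
        cov=cov,
        cov_inv=cov_inv,
        ref_d2=ref_d2,
        factor_names=tuple(factor_names) if factor_names is not None else None,
    )


def predict_nppen(model: NppenModel, X: np.ndarray) -> np.ndarray:
    """ESI(x) = fraction of reference points with D2_i >= D2(x)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.ndim:
        raise ValueError(f"expected {model.ndim}-dim points, got {X.shape[1]}")
    d2 = model.mahalanobis_sq(X)
    # count of ref_d2 >= d2(x), exact under ties
    below = np.searchsorted(model.ref_d2_sorted, d2, side="left")
    return (model.n - below) / model.n


class _HingeFeatures(BaseEstimator, TransformerMixin):
    """Piecewise-linear (hinge) basis at per-feature quantile knots.

    A small MARS-style forward basis without interactions: for each
    feature and knot t it emits max(x - t, 0) and max(t - x, 0).
    """

    def __init__(self, n_knots: int = 5):
        self.n_knots = n_knots

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        qs = np.linspace(0, 100, self.n_knots + 2)[1:-1]
        self.knots_ = [np.percentile(X[:, j], qs) for j in range(X.shape[1])]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        cols = [X]
        for j, knots in enumerate(self.knots_):
            for t in knots:
                cols.append(np.maximum(X[:, j] - t, 0.0)[:, None])
                cols.append(np.maximum(t - X[:, j], 0.0)[:, None])
        return np.hstack(cols)


def _build_estimator(algorithm_id: str, seed: int, hyperparams: dict | None) -> Pipeline:
    hp = hyperparams or {}
    if algorithm_id == "GLM":
        # logistic regression on linear + quadratic terms
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("poly", PolynomialFeatures(degree=hp.get("degree", 2), include_bias=False)),
                ("clf", LogisticRegression(max_iter=2000, C=hp.get("C", 1.0))),
            ]
        )
    if algorithm_id == "GAM":
        # additive smooth terms: per-feature spline basis + logistic link
        return Pipeline(
            [
                ("spline", SplineTransformer(n_knots=hp.get("n_knots", 6), degree=3)),
                ("clf", LogisticRegression(max_iter=2000, C=hp.get("C", 1.0))),
            ]
        )
    if algorithm_id == "GBM":
        return Pipeline(
            [
                (
                    "clf",
                    GradientBoostingClassifier(
                        n_estimators=hp.get("n_estimators", 100),
                        max_depth=hp.get("max_depth", 3),
                        random_state=seed,
                    ),
                )
            ]
        )
    if algorithm_id == "ANN":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "clf",
                    MLPClassifier(
                        hidden_layer_sizes=hp.get("hidden_layer_sizes", (16,)),
                        max_iter=hp.get("max_iter", 2000),
                        random_state=seed,
                    ),
                ),
            ]
        )
    if algorithm_id == "FDA":
        # flexible discriminant analysis: LDA on a nonlinear spline basis
        return Pipeline(
            [
                ("spline", SplineTransformer(n_knots=hp.get("n_knots", 5), degree=3)),
                ("clf", LinearDiscriminantAnalysis()),
            ]
        )
    if algorithm_id == "MARS":
        return Pipeline(
            [
                ("hinge", _HingeFeatures(n_knots=hp.get("n_knots", 5))),
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(max_iter=2000, C=hp.get("C", 1.0))),
            ]
        )
    if algorithm_id == "RF":
        return Pipeline(
            [
                (
                    "clf",
                    RandomForestClassifier(
                        n_estimators=hp.get("n_estimators", 200),
                        min_samples_leaf=hp.get("min_samples_leaf", 2),
                        random_state=seed,
                    ),
                )
            ]
        )
    raise ValueError(f"unknown algorithm id {algorithm_id!r}; expected one of {ALGORITHM_IDS}")


@dataclass
class ClassifierMember:
    """One fitted presence/pseudo-absence classifier."""

    algorithm_id: str
    pipeline: Pipeline
    factor_names: tuple[str, ...] | None = None
    replicate_id: int | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        proba = self.pipeline.predict_proba(X)
        cls = list(self.pipeline.classes_)
        return np.clip(proba[:, cls.index(1)], 0.0, 1.0)


def fit_member(
    algorithm_id: str,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    hyperparams: dict | None = None,
    factor_names=None,
) -> ClassifierMember:
    """Fit one classifier member on a presence(1)/pseudo-absence(0) design."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate dataset: a single class present")
    est = _build_estimator(algorithm_id, seed, hyperparams)
    est.fit(np.asarray(X, dtype=float), y.astype(int))
    return ClassifierMember(
        algorithm_id=algorithm_id,
        pipeline=est,
        factor_names=tuple(factor_names) if factor_names is not None else None,
    )


@dataclass
class SuitabilityMap:
    """Per-cell ESI in [0, 1] with the pooled member/replicate SD."""

    grid: WorldGrid
    esi: np.ndarray  # (ny, nx), NaN where masked
    sd: np.ndarray
    scenario: str = "contemporary"
    decade: str = "contemporary"
    mask_applied: bool = False
    meta: dict = field(default_factory=dict)

    def ocean_values(self, ocean_mask: np.ndarray) -> np.ndarray:
        return self.esi[ocean_mask]

    def to_dataset(self):
        import xarray as xr

        ds = xr.Dataset(
            {"esi": (("lat", "lon"), self.esi), "esi_sd": (("lat", "lon"), self.sd)},
            coords={"lat": self.grid.lat_centers, "lon": self.grid.lon_centers},
        )
        ds.attrs.update(scenario=self.scenario, decade=self.decade)
        return ds


def ensemble_predict(
    members,
    stack: LayerStack,
    factor_names,
    scenario: str = "contemporary",
    decade: str = "contemporary",
) -> SuitabilityMap:
    """Unweighted member x replicate mean ESI (and pooled SD) per ocean cell."""
    members = list(members)
    if not members:
        raise ValueError("ensemble has no members")
    missing = [f for f in factor_names if f not in stack.factors]
    if missing:
        raise ValueError(f"stack lacks factor field(s): {missing}")
    cells, X = stack.background_env(factor_names)
    preds = np.vstack([np.asarray(m.predict(X), dtype=float) for m in members])
    esi_flat = preds.mean(axis=0)
    sd_flat = preds.std(axis=0, ddof=0)

    esi = np.full(stack.grid.shape, np.nan)
    sd = np.full(stack.grid.shape, np.nan)
    esi.ravel()[cells] = esi_flat
    sd.ravel()[cells] = sd_flat
    return SuitabilityMap(
        grid=stack.grid,
        esi=esi,
        sd=sd,
        scenario=scenario,
        decade=decade,
        meta={"n_members": len(members)},
    )
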