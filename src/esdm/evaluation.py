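"""Cross-validation, the Continuous Boyce Index, and ensemble selection.

Candidate models (factor set x hull quantile x algorithm) are scored by
the mean held-out Continuous Boyce Index over ten random stratified 70/30
splits, screened for spurious (multimodal) response curves, and the
best-scoring configuration's validated members form the ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .env_stack import LayerStack
from .niche_sampling import NicheDataset, _env_matrix
from .sdm_core import ClassifierMember, NppenModel, fit_member, fit_nppen

__all__ = [
    "CvSplit",
    "CbiResult",
    "CandidateResult",
    "make_cv_splits",
    "continuous_boyce_index",
    "response_curve",
    "screen_curve",
    "evaluate_candidate",
    "select_ensemble",
]


@dataclass(frozen=True)
class CvSplit:
    """One stratified random 70/30 calibration/evaluation split."""

    replicate_id: int
    cal_idx: np.ndarray  # indices into NicheDataset.to_frame() row order
    eval_idx: np.ndarray
    seed: int


def make_cv_splits(
    dataset: NicheDataset,
    n_rep: int = 10,
    frac: float = 0.7,
    seed: int = 0,
) -> list[CvSplit]:
    """Ten independent random splits, stratified by presence/absence role.

    Indices address rows of ``dataset.to_frame()`` (presences first, then
    absences). Each replicate partitions the data exhaustively.
    """
    n_pres, n_abs = dataset.n, len(dataset.absences)
    if n_pres < 2 or n_abs < 2:
        raise ValueError("each class needs at least 2 points to split 70/30")
    rng = np.random.default_rng(seed)
    splits = []
    for rep in range(1, n_rep + 1):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        rep_rng = np.random.default_rng(rep_seed)
        parts_cal, parts_eval = [], []
        for offset, n_cls in ((0, n_pres), (n_pres, n_abs)):
            k = int(round(frac * n_cls))
            k = min(max(k, 1), n_cls - 1)  # both classes appear in both parts
            perm = rep_rng.permutation(n_cls) + offset
            parts_cal.append(perm[:k])
            parts_eval.append(perm[k:])
        splits.append(
            CvSplit(
                replicate_id=rep,
                cal_idx=np.sort(np.concatenate(parts_cal)),
                eval_idx=np.sort(np.concatenate(parts_eval)),
                seed=rep_seed,
            )
        )
    return splits


@dataclass
class CbiResult:
    """Continuous Boyce Index with the windows that produced it."""

    cbi: float
    window_width: float
    midpoints: np.ndarray
    pe_ratio: np.ndarray


def continuous_boyce_index(
    pred_presence: np.ndarray,
    pred_background: np.ndarray,
    window_width: float = 0.1,
    n_windows: int = 101,
) -> CbiResult:
    """Continuous Boyce Index of suitability predictions.

    For window midpoints m on a regular grid over [0, 1], P(m) is the
    fraction of presence predictions in [m - w/2, m + w/2] and E(m) the
    same for the background; windows with E = 0 are dropped and the index
    is the Spearman rank correlation between m and P/E. Ranges over
    [-1, 1]; 1 means suitability ranks presence density perfectly.
    """
    p = np.asarray(pred_presence, dtype=float)
    b = np.asarray(pred_background, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one presence prediction")
    if np.nanmin(np.concatenate([p, b])) < 0 or np.nanmax(np.concatenate([p, b])) > 1:
        raise ValueError("predictions must lie in [0, 1]")

    mids = np.linspace(0.0, 1.0, n_windows)
    half = window_width / 2.0
    P = np.array([np.mean((p >= m - half) & (p <= m + half)) for m in mids])
    E = np.array([np.mean((b >= m - half) & (b <= m + half)) for m in mids])
    valid = E > 0
    if not valid.any():
        raise ValueError("every window has zero expected (background) fraction")
    ratio = P[valid] / E[valid]
    if np.all(ratio == ratio[0]):  # constant ratio: no ranking signal
        cbi = 0.0
    else:
        cbi = float(stats.spearmanr(mids[valid], ratio).statistic)
    return CbiResult(cbi=cbi, window_width=window_width, midpoints=mids[valid], pe_ratio=ratio)


def response_curve(
    member,
    factor_names,
    factor: str,
    stack: LayerStack,
    presence_env: pd.DataFrame | None = None,
    n_points: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Predictions along one factor's observed range.

    The focal factor sweeps its observed ocean-cell range; the other
    factors are held at their presence medians (ocean medians if no
    presences are supplied).
    """
    factor_names = list(factor_names)
    if factor not in factor_names:
        raise ValueError(f"factor {factor!r} not in model factors {factor_names}")
    _, bg = stack.background_env(factor_names)
    col = factor_names.index(factor)
    xs = np.linspace(np.nanmin(bg[:, col]), np.nanmax(bg[:, col]), n_points)
    if presence_env is not None:
        med = np.median(_env_matrix(presence_env, factor_names), axis=0)
    else:
        med = np.median(bg, axis=0)
    X = np.tile(med, (n_points, 1))
    X[:, col] = xs
    return xs, np.asarray(member.predict(X), dtype=float)


def screen_curve(
    curve: np.ndarray,
    smoothing_window: int = 5,
) -> tuple[bool, str]:
    """Pass/fail screen for spurious (multimodal) response curves.

    The curve is smoothed with a centred moving average; it fails when
    the smoothed curve has two or more interior local maxima.
    """
    y = np.asarray(curve, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response curve contains non-finite values")
    if smoothing_window > 1 and y.size >= smoothing_window:
        kernel = np.ones(smoothing_window) / smoothing_window
        pad = smoothing_window // 2
        ypad = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
        y = np.convolve(ypad, kernel, mode="valid")[: curve.size]

    # interior maxima via sign changes of the (tie-compressed) slope
    dy = np.diff(y)
    signs = np.sign(dy[dy != 0])
    n_max = int(np.sum((signs[:-1] > 0) & (signs[1:] < 0)))
    if n_max >= 2:
        return False, f"multimodal: {n_max} interior local maxima"
    return True, "ok"


@dataclass
class CandidateResult:
    """Evaluation record of one algorithm under one configuration."""

    algorithm_id: str
    factor_names: tuple[str, ...]
    quantiles: tuple[float, float]
    coast_filter: bool
    cbi_per_replicate: list[float]
    curves_pass: bool
    curve_reasons: dict[str, str] = field(default_factory=dict)

    @property
    def mean_cbi(self) -> float:
        return float(np.mean(self.cbi_per_replicate))


def _fit_algorithm(algorithm_id, dataset, cal_idx, seed):
    frame = dataset.to_frame()
    X = _env_matrix(frame, dataset.factor_names)
    y = (frame["role"] == "presence").to_numpy().astype(int)
    Xc, yc = X[cal_idx], y[cal_idx]
    if algorithm_id == "NPPEN":
        return fit_nppen(Xc[yc == 1], factor_names=dataset.factor_names)
    return fit_member(algorithm_id, Xc, yc, seed=seed, factor_names=dataset.factor_names)


def evaluate_candidate(
    algorithm_id: str,
    dataset: NicheDataset,
    splits: list[CvSplit],
    background_env: pd.DataFrame,
    stack: LayerStack,
    coast_filter: bool = False,
    window_width: float = 0.1,
    n_windows: int = 101,
) -> CandidateResult:
    """Cross-validate one algorithm on one niche dataset.

    Per replicate, the member is calibrated on the 70% part and the CBI
    computed from its predictions at held-out presences versus all
    ocean-cell background environments; response curves of a full-data
    fit are screened for multimodality.
    """
    frame = dataset.to_frame()
    X = _env_matrix(frame, dataset.factor_names)
    y = (frame["role"] == "presence").to_numpy().astype(int)
    bg = _env_matrix(background_env, dataset.factor_names)

    cbis = []
    for split in splits:
        member = _fit_algorithm(algorithm_id, dataset, split.cal_idx, split.seed)
        eval_pres = split.eval_idx[y[split.eval_idx] == 1]
        res = continuous_boyce_index(
            member.predict(X[eval_pres]),
            member.predict(bg),
            window_width=window_width,
            n_windows=n_windows,
        )
        cbis.append(res.cbi)

    full = _fit_algorithm(algorithm_id, dataset, np.arange(len(frame)), splits[0].seed)
    reasons, ok = {}, True
    for f in dataset.factor_names:
        _, curve = response_curve(full, dataset.factor_names, f, stack, dataset.presences)
        passed, why = screen_curve(curve)
        reasons[f] = why
        ok = ok and passed

    return CandidateResult(
        algorithm_id=algorithm_id,
        factor_names=dataset.factor_names,
        quantiles=dataset.hull.quantiles,
        coast_filter=coast_filter,
        cbi_per_replicate=cbis,
        curves_pass=ok,
        curve_reasons=reasons,
    )


def ensemble_cv_cbi(
    algorithm_ids,
    dataset: NicheDataset,
    splits: list[CvSplit],
    background_env: pd.DataFrame,
    window_width: float = 0.1,
    n_windows: int = 101,
) -> list[float]:
    """Held-out CBI of the ensemble-mean prediction, one value per split.

    Per replicate every algorithm is calibrated on the 70% part; the
    unweighted mean of their predictions is scored at held-out presences
    against the ocean-cell background.
    """
    frame = dataset.to_frame()
    X = _env_matrix(frame, dataset.factor_names)
    y = (frame["role"] == "presence").to_numpy().astype(int)
    bg = _env_matrix(background_env, dataset.factor_names)
    out = []
    for split in splits:
        members = [_fit_algorithm(a, dataset, split.cal_idx, split.seed) for a in algorithm_ids]
        eval_pres = split.eval_idx[y[split.eval_idx] == 1]
        pp = np.mean([m.predict(X[eval_pres]) for m in members], axis=0)
        pb = np.mean([m.predict(bg) for m in members], axis=0)
        out.append(
            continuous_boyce_index(pp, pb, window_width=window_width, n_windows=n_windows).cbi
        )
    return out


class EmptySelectionError(RuntimeError):
    """No candidate met the CBI threshold with clean response curves."""


def select_ensemble(
    candidates: list[CandidateResult],
    threshold: float = 0.5,
) -> tuple[list[CandidateResult], pd.DataFrame]:
    """Select the final ensemble configuration.

    Members with mean CBI > threshold and passing curves are retained;
    the (factor set, quantile, coast-filter) configuration whose retained
    members have the highest mean CBI wins. Ties break toward fewer
    factors, then the widest quantile trim (10-90 first). Returns the
    winning members and a selection report mirroring a model-selection
    table (factors, algorithms, quantiles, filters, CBI).
    """
    rows = []
    for c in candidates:
        rows.append(
            {
                "factors": "+".join(c.factor_names),
                "algorithm": c.algorithm_id,
                "quantiles": f"{c.quantiles[0]:g}-{c.quantiles[1]:g}",
                "coast_filter": c.coast_filter,
                "mean_cbi": c.mean_cbi,
                "curves_pass": c.curves_pass,
                "validated": c.mean_cbi > threshold and c.curves_pass,
            }
        )
    report = pd.DataFrame(rows)

    valid = [c for c in candidates if c.mean_cbi > threshold and c.curves_pass]
    if not valid:
        raise EmptySelectionError(
            f"no candidate passed (CBI > {threshold} with unimodal curves) "
            f"out of {len(candidates)}"
        )

    configs: dict[tuple, list[CandidateResult]] = {}
    for c in valid:
        configs.setdefault((c.factor_names, c.quantiles, c.coast_filter), []).append(c)

    def sort_key(item):
        (factors, q, _coast), members = item
        mean_cbi = np.mean([m.mean_cbi for m in members])
        # maximize CBI; ties -> fewer factors, then wider trim (larger q_low)
        return (-mean_cbi, len(factors), -q[0])

    best_key, best_members = sorted(configs.items(), key=sort_key)[0]
    report["selected"] = [
        (c.factor_names, c.quantiles, c.coast_filter) == best_key and c in best_members
        for c in candidates
    ]
    return best_members, report
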