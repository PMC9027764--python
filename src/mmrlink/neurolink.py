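"""Neural-behavioral linking analyses.

Two complementary routes from MMR to behavioral d':

1. an ROI-level ordinary-least-squares model of d' on log MMR, group,
   and their interaction (with per-group simple slopes), and
2. a time-resolved whole-map decoder: for every time sample a linear
   epsilon-SVR predicts d' from the label vector under leave-one-out
   cross-validation, against a pooled permutation null thresholded at
   its 99th percentile; a final model over the significant samples
   yields per-subject predictions and a per-label contribution map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from ._svr import fit_linear_svr
from .mmr import MMRMatrix

__all__ = [
    "ROIRegressionResult",
    "DecodeConfig",
    "DecodeResult",
    "FinalModel",
    "fit_roi_interaction_model",
    "loo_svr_predictions",
    "timewise_svr_r2",
    "permutation_null_pool",
    "final_svr",
    "decode_pipeline",
]

_TERM_NAMES = ("intercept", "mmr", "group", "mmr_x_group")


@dataclass
class ROIRegressionResult:
    roi: str
    coef: dict[str, float]
    se: dict[str, float]
    pvalues: dict[str, float]
    r_squared: float
    f_pvalue: float
    simple_slopes: dict[str, float]  # slope of d' on log MMR per group code
    n: int


def fit_roi_interaction_model(
    dprime: np.ndarray,
    log_mmr: np.ndarray,
    group: np.ndarray,
    roi: str = "roi",
) -> ROIRegressionResult:
    """OLS of d' on [1, log_mmr, group, log_mmr * group].

    ``group`` is binary, 0 = nonnative, 1 = native; the interaction
    coefficient therefore equals the native-group slope minus the
    nonnative-group slope.  Coefficient t tests use n - 4 df.
    """
    dprime = np.asarray(dprime, dtype=float)
    log_mmr = np.asarray(log_mmr, dtype=float)
    group = np.asarray(group, dtype=float)
    n = dprime.size
    if not (log_mmr.size == n and group.size == n):
        raise ValueError("dprime, log_mmr, group must have equal length")
    if n < 5:
        raise ValueError("need n >= 5 subjects")
    levels = np.unique(group)
    if not np.array_equal(levels, [0.0, 1.0]):
        raise ValueError("group must contain both levels coded 0 and 1")
    if np.any(~np.isfinite(dprime)) or np.any(~np.isfinite(log_mmr)):
        raise ValueError("inputs contain missing or non-finite values")

    X = np.column_stack([np.ones(n), log_mmr, group, log_mmr * group])
    rank = np.linalg.matrix_rank(X)
    if rank < 4:
        # name the first column whose removal restores full rank
        for j in range(1, 4):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValueError(
                    f"design matrix rank deficient: column {_TERM_NAMES[j]!r} "
                    "is collinear"
                )
        raise ValueError("design matrix rank deficient")

    fit = sm.OLS(dprime, X).fit()
    coef = dict(zip(_TERM_NAMES, fit.params))
    return ROIRegressionResult(
        roi=roi,
        coef=coef,
        se=dict(zip(_TERM_NAMES, fit.bse)),
        pvalues=dict(zip(_TERM_NAMES, fit.pvalues)),
        r_squared=float(fit.rsquared),
        f_pvalue=float(fit.f_pvalue),
        simple_slopes={
            "group0": coef["mmr"],
            "group1": coef["mmr"] + coef["mmr_x_group"],
        },
        n=n,
    )


def loo_svr_predictions(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    epsilon: float = 0.1,
    return_weights: bool = False,
):
    """Leave-one-out linear-SVR predictions over subjects (rows of X)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need >= 4 subjects for leave-one-out decoding")
    preds = np.empty(n)
    weights = np.empty((n, X.shape[1])) if return_weights else None
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        w, b = fit_linear_svr(X[train], y[train], C=C, epsilon=epsilon)
        preds[i] = X[i] @ w + b
        if return_weights:
            weights[i] = w
    if return_weights:
        return preds, weights
    return preds


def _r2_pooled(y: np.ndarray, preds: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("d' vector is constant: R^2 undefined (SS_tot = 0)")
    return 1.0 - float(np.sum((y - preds) ** 2)) / ss_tot


def _features(data) -> np.ndarray:
    if isinstance(data, MMRMatrix):
        return data.data
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected (n_subjects, n_labels, n_times)")
    return arr


def timewise_svr_r2(
    mmr, dprime: np.ndarray, C: float = 1.0, epsilon: float = 0.1
) -> np.ndarray:
    """Coefficient of determination of pooled LOO-SVR predictions, per
    time sample.  Values can be negative (worse than the mean predictor)."""
    data = _features(mmr)
    y = np.asarray(dprime, dtype=float)
    if y.size != data.shape[0]:
        raise ValueError("dprime length must equal number of subjects")
    n_times = data.shape[2]
    out = np.empty(n_times)
    for t in range(n_times):
        preds = loo_svr_predictions(data[:, :, t], y, C=C, epsilon=epsilon)
        out[t] = _r2_pooled(y, preds)
    return out


def permutation_null_pool(
    mmr,
    dprime: np.ndarray,
    n_perm_per_time: int = 100,
    seed: int = 0,
    C: float = 1.0,
    epsilon: float = 0.1,
    percentile: float = 99.0,
) -> tuple[np.ndarray, float]:
    """Pooled permutation null of the per-time LOO-SVR R^2.

    For every time sample, d' is shuffled across subjects
    ``n_perm_per_time`` times (features fixed) and the full LOO refit is
    run for each shuffle.  Returns the pool (length T * n_perm_per_time)
    and its empirical ``percentile`` threshold.
    """
    if n_perm_per_time < 1:
        raise ValueError("n_perm_per_time must be >= 1")
    data = _features(mmr)
    y = np.asarray(dprime, dtype=float)
    rng = np.random.default_rng(seed)
    n_times = data.shape[2]
    pool = np.empty(n_times * n_perm_per_time)
    k = 0
    for t in range(n_times):
        X = data[:, :, t]
        for _ in range(n_perm_per_time):
            y_perm = y[rng.permutation(y.size)]
            preds = loo_svr_predictions(X, y_perm, C=C, epsilon=epsilon)
            pool[k] = _r2_pooled(y_perm, preds)
            k += 1
    threshold = float(np.percentile(pool, percentile))
    return pool, threshold


@dataclass
class FinalModel:
    predictions: np.ndarray | None
    pearson_r: float | None
    p_one_sided: float | None
    p_two_sided: float | None
    weight_map: np.ndarray | None
    significant_times: np.ndarray

    @property
    def empty(self) -> bool:
        return self.predictions is None


def final_svr(
    mmr,
    dprime: np.ndarray,
    significant_times: np.ndarray,
    C: float = 1.0,
    epsilon: float = 0.1,
    feature_mode: str = "mean",
) -> FinalModel:
    """Final decoder over the significant time samples.

    ``feature_mode="mean"`` (default) averages each label's MMR over the
    significant samples, keeping n_labels features; ``"concat"``
    concatenates the label vectors of every significant sample.  The
    weight map is the mean absolute SVR coefficient per label across
    LOO folds (averaged over time samples in concat mode).
    """
    significant_times = np.asarray(significant_times, dtype=int)
    if significant_times.size == 0:
        return FinalModel(
            predictions=None,
            pearson_r=None,
            p_one_sided=None,
            p_two_sided=None,
            weight_map=None,
            significant_times=significant_times,
        )
    data = _features(mmr)
    y = np.asarray(dprime, dtype=float)
    n_labels = data.shape[1]
    if feature_mode == "mean":
        X = data[:, :, significant_times].mean(axis=2)
    elif feature_mode == "concat":
        X = data[:, :, significant_times].reshape(data.shape[0], -1)
    else:
        raise ValueError(f"unknown feature_mode {feature_mode!r}")
    preds, weights = loo_svr_predictions(X, y, C=C, epsilon=epsilon, return_weights=True)
    abs_w = np.abs(weights).mean(axis=0)
    if feature_mode == "concat":
        abs_w = abs_w.reshape(n_labels, significant_times.size, order="C").mean(axis=1)
    if np.std(preds) == 0.0:
        r, p2 = 0.0, 1.0
    else:
        r, p2 = stats.pearsonr(y, preds)
    # directional test: positive correlation between actual and predicted
    p1 = p2 / 2.0 if r > 0 else 1.0 - p2 / 2.0
    return FinalModel(
        predictions=preds,
        pearson_r=float(r),
        p_one_sided=float(p1),
        p_two_sided=float(p2),
        weight_map=abs_w,
        significant_times=significant_times,
    )


@dataclass
class DecodeConfig:
    C: float = 1.0
    epsilon: float = 0.1
    n_perm_per_time: int = 100
    percentile: float = 99.0
    feature_mode: str = "mean"
    seed: int = 0


@dataclass
class DecodeResult:
    r2_timecourse: np.ndarray
    null_pool: np.ndarray
    threshold: float
    significant_times: np.ndarray
    final: FinalModel
    config: DecodeConfig = field(default_factory=DecodeConfig)


def decode_pipeline(mmr, dprime: np.ndarray, config: DecodeConfig | None = None) -> DecodeResult:
    """Observed R^2 timecourse -> pooled null -> significant samples ->
    final model.  Run separately per group by the caller."""
    if config is None:
        config = DecodeConfig()
    r2 = timewise_svr_r2(mmr, dprime, C=config.C, epsilon=config.epsilon)
    pool, threshold = permutation_null_pool(
        mmr,
        dprime,
        n_perm_per_time=config.n_perm_per_time,
        seed=config.seed,
        C=config.C,
        epsilon=config.epsilon,
        percentile=config.percentile,
    )
    significant = np.flatnonzero(r2 > threshold)
    final = final_svr(
        mmr,
        dprime,
        significant,
        C=config.C,
        epsilon=config.epsilon,
        feature_mode=config.feature_mode,
    )
    return DecodeResult(
        r2_timecourse=r2,
        null_pool=pool,
        threshold=threshold,
        significant_times=significant,
        final=final,
        config=config,
    )
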