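"""Multivariate Granger causality between two regions' multichannel responses.

Per participant, each region's trial-averaged response to every object
(stimulus onset to offset) is concatenated into one long multichannel
series, with a separator marker between objects so that no autoregressive
window spans two temporally discontinuous responses.  Each region is
reduced to its leading principal components, and nested vector
autoregressions (target's own lags vs. own lags plus the predictor
region's lags) are fit by least squares in both directions; model order is
chosen per direction by BIC up to a 50-ms maximum lag.  The directional
statistic is the difference of the two nested-model F statistics
(positive = forward direction dominant), tested against zero across
participants with a Wilcoxon signed-rank test.

For multivariate targets the F statistic generalizes the classical nested
regression F through the generalized-variance (residual-covariance
determinant) ratio,

    F = ((|E_r| / |E_f|)^(1/k) - 1) * df2 / df1,

which reduces exactly to the classical single-equation F when the target is
univariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import EpochedDataset

logger = logging.getLogger(__name__)


@dataclass
class SeparatedSeries:
    """Multichannel series composed of contiguous blocks with separators between them.

    ``data`` is channels x length with NaN columns at separator positions;
    ``blocks`` lists the (start, stop) column range of each contiguous block
    (stop exclusive).
    """

    data: np.ndarray
    sampling_rate: float
    blocks: list[tuple[int, int]]

    @property
    def n_separators(self) -> int:
        return len(self.blocks) - 1

    @classmethod
    def from_array(cls, data: np.ndarray, sampling_rate: float = 250.0) -> "SeparatedSeries":
        data = np.atleast_2d(np.asarray(data, dtype=float))
        return cls(data=data, sampling_rate=sampling_rate, blocks=[(0, data.shape[1])])


@dataclass
class GrangerResult:
    """Directional Granger statistics for one participant or a group."""

    f_forward: float
    f_backward: float
    lag_forward_ms: float
    lag_backward_ms: float
    f_difference: float
    per_participant: list = field(default_factory=list)
    group: dict | None = None


def concat_object_series(
    dataset: EpochedDataset,
    region: str,
    window_ms: tuple[float, float] = (0.0, 300.0),
) -> SeparatedSeries:
    """Concatenate per-object trial-averaged responses with one separator between objects."""
    idx = dataset.montage.require_region(region, min_channels=1)
    tmask = (dataset.times >= window_ms[0]) & (dataset.times <= window_ms[1])
    n_tp = int(tmask.sum())
    objects = dataset.object_ids()
    uniq = np.unique(objects)
    n_obj = len(uniq)

    length = n_obj * n_tp + (n_obj - 1)
    data = np.full((len(idx), length), np.nan)
    blocks = []
    pos = 0
    for k, obj in enumerate(uniq):
        block = dataset.data[objects == obj][:, idx, :][:, :, tmask].mean(axis=0)
        data[:, pos : pos + n_tp] = block
        blocks.append((pos, pos + n_tp))
        pos += n_tp + 1  # skip one separator column
    return SeparatedSeries(data=data, sampling_rate=dataset.sampling_rate, blocks=blocks)


def _as_series(x, sampling_rate: float) -> SeparatedSeries:
    if isinstance(x, SeparatedSeries):
        return x
    return SeparatedSeries.from_array(x, sampling_rate)


def _pca_reduce(series: SeparatedSeries, n_components: int) -> np.ndarray:
    """Project channels onto leading principal components (channels x length, NaNs kept)."""
    valid = ~np.isnan(series.data[0])
    X = series.data[:, valid]
    Xc = X - X.mean(axis=1, keepdims=True)
    if X.shape[0] <= n_components:
        out = np.full_like(series.data, np.nan)
        out[:, valid] = Xc
        return out
    u, s, vt = np.linalg.svd(Xc.T, full_matrices=False)  # obs = time, vars = channels
    scores = (u[:, :n_components] * s[:n_components]).T  # components x time
    out = np.full((n_components, series.data.shape[1]), np.nan)
    out[:, valid] = scores
    return out


def _lag_design(
    target: np.ndarray,
    predictor: np.ndarray,
    p: int,
    blocks: list[tuple[int, int]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Regression rows whose lag window stays inside one block.

    Returns (Y, X_restricted, X_full); X_restricted has an intercept and the
    target's own lags, X_full adds the predictor's lags.
    """
    ts = np.concatenate([np.arange(s + p, e) for s, e in blocks if e - s > p])
    if len(ts) == 0:
        raise ValueError(f"no valid regression rows at order {p}")
    Y = target[:, ts].T
    own = np.concatenate([target[:, ts - l] for l in range(1, p + 1)], axis=0).T
    cross = np.concatenate([predictor[:, ts - l] for l in range(1, p + 1)], axis=0).T
    ones = np.ones((len(ts), 1))
    return Y, np.hstack([ones, own]), np.hstack([ones, own, cross])


def _fit_logdet(Y: np.ndarray, X: np.ndarray) -> float:
    """Log-determinant of the residual sum-of-squares-and-cross-products matrix."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta
    E = R.T @ R
    # regularize exact zeros so noiseless fixtures do not produce -inf
    sign, logdet = np.linalg.slogdet(E + 1e-300 * np.eye(E.shape[0]))
    return float(logdet)


def _direction_stats(
    predictor: np.ndarray,
    target: np.ndarray,
    max_order: int,
    blocks: list[tuple[int, int]],
) -> tuple[float, int]:
    """Best-BIC order and nested F for predictor -> target."""
    k_y = target.shape[0]
    k_x = predictor.shape[0]
    best = None
    for p in range(1, max_order + 1):
        n_regressors = 1 + p * (k_y + k_x)
        try:
            Y, Xr, Xf = _lag_design(target, predictor, p, blocks)
        except ValueError:
            break
        n = Y.shape[0]
        df2 = n - n_regressors
        if df2 < k_y + 1:
            break
        logdet_f = _fit_logdet(Y, Xf)
        bic = n * (logdet_f - k_y * np.log(n)) + k_y * n_regressors * np.log(n)
        if best is None or bic < best[0]:
            logdet_r = _fit_logdet(Y, Xr)
            df1 = p * k_x
            ratio = np.exp((logdet_r - logdet_f) / k_y)
            f = max(ratio - 1.0, 0.0) * df2 / df1
            best = (bic, f, p, n, n_regressors)
    if best is None:
        min_len = 1 + (k_y + k_x + 2)  # at least order 1 with residual dof
        raise ValueError(
            f"insufficient valid rows for any VAR order; need block lengths giving at "
            f"least ~{min_len} rows beyond the regressor count"
        )
    _, f, p, n, n_regressors = best
    if n < 10 * n_regressors:
        logger.warning(
            "only %d regression rows for %d regressors per equation (<10x) at order %d",
            n, n_regressors, p,
        )
    return f, p


def mvgc(
    series_x,
    series_y,
    max_lag_ms: float = 50.0,
    n_components: int = 10,
    sampling_rate: float = 250.0,
) -> GrangerResult:
    """Bidirectional multivariate Granger causality for one participant.

    ``f_forward`` tests x -> y (x's past improving prediction of y);
    ``f_difference = f_forward - f_backward`` is positive when the forward
    direction dominates.
    """
    sx = _as_series(series_x, sampling_rate)
    sy = _as_series(series_y, sampling_rate)
    if sx.data.shape[1] != sy.data.shape[1] or sx.blocks != sy.blocks:
        raise ValueError("series must share length and separator positions")
    fs = sx.sampling_rate
    max_order = max(1, int(round(max_lag_ms * fs / 1000.0)))

    x = _pca_reduce(sx, n_components)
    y = _pca_reduce(sy, n_components)
    xv = np.nan_to_num(x)
    yv = np.nan_to_num(y)

    f_fwd, p_fwd = _direction_stats(xv, yv, max_order, sx.blocks)
    f_bwd, p_bwd = _direction_stats(yv, xv, max_order, sx.blocks)
    step = 1000.0 / fs
    return GrangerResult(
        f_forward=f_fwd,
        f_backward=f_bwd,
        lag_forward_ms=p_fwd * step,
        lag_backward_ms=p_bwd * step,
        f_difference=f_fwd - f_bwd,
    )


def signed_rank_statistic(diffs: np.ndarray) -> float:
    """Wilcoxon signed-rank W = sum of ranks of positive differences (zeros dropped)."""
    d = np.asarray(diffs, dtype=float)
    nz = d != 0
    if nz.sum() < len(d):
        logger.info("dropped %d zero differences from the signed-rank test", int((~nz).sum()))
    d = d[nz]
    if len(d) == 0:
        raise ValueError("all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    return float(ranks[d > 0].sum())


def group_granger(
    cohort: list[EpochedDataset],
    region_pair: tuple[str, str] = ("dorsal", "ventral"),
    max_lag_ms: float = 50.0,
    n_components: int = 10,
    window_ms: tuple[float, float] = (0.0, 300.0),
) -> GrangerResult:
    """Per-participant F-differences plus the group Wilcoxon signed-rank test."""
    if len(cohort) < 6:
        raise ValueError("group Granger analysis requires at least 6 participants")
    per = []
    for ds in cohort:
        sx = concat_object_series(ds, region_pair[0], window_ms)
        sy = concat_object_series(ds, region_pair[1], window_ms)
        per.append(mvgc(sx, sy, max_lag_ms=max_lag_ms, n_components=n_components))
    diffs = np.array([r.f_difference for r in per])
    W = signed_rank_statistic(diffs)
    nz = diffs[diffs != 0]
    res = stats.wilcoxon(nz, alternative="two-sided", method="auto")
    d = float(diffs.mean() / diffs.std(ddof=1)) if diffs.std(ddof=1) > 0 else float("inf")
    group = {"W": W, "p": float(res.pvalue), "d": d, "n": len(diffs)}
    return GrangerResult(
        f_forward=float(np.mean([r.f_forward for r in per])),
        f_backward=float(np.mean([r.f_backward for r in per])),
        lag_forward_ms=float(np.mean([r.lag_forward_ms for r in per])),
        lag_backward_ms=float(np.mean([r.lag_backward_ms for r in per])),
        f_difference=float(diffs.mean()),
        per_participant=per,
        group=group,
    )
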