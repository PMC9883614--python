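"""Time-generalized representational similarity between two regions.

Per timepoint, the pairwise cosine similarity of the trial-averaged
multichannel responses to each object forms a 20 x 20 representational
(dis)similarity matrix (RDM).  Correlating region A's RDM at time t1 with
region B's RDM at time t2 for all (t1, t2) yields the time-generalization
matrix.  With A = dorsal on the rows and B = ventral on the columns, a cell
above the diagonal (column time later than row time) captures the dorsal
pattern predicting a *future* ventral pattern.

Directionality statistics:

- ``mirror_statistic``: for every cell above the diagonal, subtract its
  mirror across the diagonal; the per-participant mean difference is tested
  against zero with a one-sample t-test.  Positive = dorsal predicts future
  ventral timepoints better than the reverse.
- ``rank_and_roll``: cells ranked by correlation; rolling one-sided binomial
  tests of the dorsal-leading proportion in the top 50, 100, ... cells
  against the analytic null proportion (T-1)/(2T); mean prediction delay of
  the dorsal-leading cells among the top k.
- ``partial_timegen``: partial correlations controlling a third region's
  RDM at the row timepoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import EpochedDataset

logger = logging.getLogger(__name__)


@dataclass
class RDMSeries:
    """Per-timepoint object-by-object cosine-similarity matrices for one region."""

    rdm: np.ndarray  # timepoints x objects x objects
    times: np.ndarray
    objects: np.ndarray
    region: str

    @property
    def n_times(self) -> int:
        return self.rdm.shape[0]


def compute_rdm_series(
    dataset: EpochedDataset,
    region: str,
    window_ms: tuple[float, float] = (-48.0, 300.0),
) -> RDMSeries:
    """Cosine-similarity RDM of trial-averaged object responses at every timepoint."""
    idx = dataset.montage.require_region(region, min_channels=2)
    tmask = (dataset.times >= window_ms[0]) & (dataset.times <= window_ms[1])
    times = dataset.times[tmask]
    objects = dataset.object_ids()
    uniq = np.unique(objects)

    resp = np.stack(
        [dataset.data[objects == obj][:, idx, :][:, :, tmask].mean(axis=0) for obj in uniq]
    )  # objects x channels x timepoints
    resp = resp.transpose(2, 0, 1)  # timepoints x objects x channels
    norms = np.linalg.norm(resp, axis=2)
    if np.any(norms == 0):
        t_bad, o_bad = np.argwhere(norms == 0)[0]
        raise ValueError(
            f"zero-norm response vector for object {uniq[o_bad]} at t={times[t_bad]:g} ms"
        )
    unit = resp / norms[:, :, None]
    rdm = np.einsum("tic,tjc->tij", unit, unit)
    return RDMSeries(rdm=rdm, times=times, objects=uniq, region=region)


def _upper_vectors(rdms: RDMSeries) -> np.ndarray:
    """Vectorized upper triangles (diagonal included) per timepoint."""
    n = rdms.rdm.shape[1]
    iu = np.triu_indices(n, k=0)
    return rdms.rdm[:, iu[0], iu[1]]


def _zscore_rows(V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-standardized vectors and a mask of zero-variance rows."""
    mu = V.mean(axis=1, keepdims=True)
    sd = V.std(axis=1, keepdims=True)
    zero = sd[:, 0] == 0
    sd[zero] = 1.0
    return (V - mu) / sd, zero


def timegen_matrix(rdms_a: RDMSeries, rdms_b: RDMSeries) -> np.ndarray:
    """Correlation of region A's RDM at every t with region B's RDM at every t'.

    Entry (i, j) is the Pearson correlation between the vectorized upper
    triangles at A-time i and B-time j.  Zero-variance RDM vectors produce
    zero entries (logged).
    """
    if rdms_a.rdm.shape != rdms_b.rdm.shape or not np.allclose(rdms_a.times, rdms_b.times):
        raise ValueError("RDM series must share the object set and time grid")
    Va, zero_a = _zscore_rows(_upper_vectors(rdms_a))
    Vb, zero_b = _zscore_rows(_upper_vectors(rdms_b))
    if zero_a.any() or zero_b.any():
        logger.info(
            "zero-variance RDM vectors at %d (A) and %d (B) timepoints; entries set to 0",
            int(zero_a.sum()), int(zero_b.sum()),
        )
    m = Va.shape[1]
    M = (Va @ Vb.T) / m
    M[zero_a, :] = 0.0
    M[:, zero_b] = 0.0
    return M


def timegen_cohort(
    cohort: list[EpochedDataset],
    region_a: str = "dorsal",
    region_b: str = "ventral",
    window_ms: tuple[float, float] = (-48.0, 300.0),
    average_participants: bool = False,
):
    """Time-generalization matrices for a cohort.

    Returns a participants x T x T array, or a single T x T matrix computed
    from participant-averaged RDM series when ``average_participants`` is set.
    """
    rdms_a = [compute_rdm_series(ds, region_a, window_ms) for ds in cohort]
    rdms_b = [compute_rdm_series(ds, region_b, window_ms) for ds in cohort]
    if average_participants:
        avg_a = RDMSeries(
            rdm=np.mean([r.rdm for r in rdms_a], axis=0),
            times=rdms_a[0].times, objects=rdms_a[0].objects, region=region_a,
        )
        avg_b = RDMSeries(
            rdm=np.mean([r.rdm for r in rdms_b], axis=0),
            times=rdms_b[0].times, objects=rdms_b[0].objects, region=region_b,
        )
        return timegen_matrix(avg_a, avg_b)
    return np.stack([timegen_matrix(a, b) for a, b in zip(rdms_a, rdms_b)])


def mirror_statistic(matrices: np.ndarray) -> dict:
    """Mirrored-subtraction directionality statistic.

    For each participant matrix (rows = region A time, columns = region B
    time), every cell above the diagonal minus its mirror below the
    diagonal is averaged; the per-participant means are tested against zero
    (one-sample t-test, two-sided p).  Positive = A predicts B's future.
    """
    M = np.asarray(matrices, dtype=float)
    if M.ndim == 2:
        M = M[None]
    if M.shape[1] != M.shape[2]:
        raise ValueError("time-generalization matrices must be square")
    iu = np.triu_indices(M.shape[1], k=1)
    per = (M[:, iu[0], iu[1]] - M[:, iu[1], iu[0]]).mean(axis=1)
    if len(per) < 2:
        raise ValueError("t statistic undefined for fewer than 2 participants")
    t, p = stats.ttest_1samp(per, 0.0)
    sd = per.std(ddof=1)
    return {
        "per_participant": per,
        "mean": float(per.mean()),
        "t": float(t),
        "p": float(p),
        "d": float(per.mean() / sd) if sd > 0 else float("inf"),
        "n": len(per),
    }


def rolling_null_proportion(n_times: int) -> float:
    """Expected dorsal-leading fraction among all cells of a T x T matrix: (T-1)/(2T)."""
    return (n_times - 1) / (2.0 * n_times)


def rank_and_roll(
    matrix: np.ndarray,
    times: np.ndarray,
    window_increment: int = 50,
    top_k: int = 10,
) -> dict:
    """Rank-ordered cell labels, rolling binomial trace, and top-k mean delay.

    Cells are labeled ``a_to_b`` (column time later than row time),
    ``b_to_a``, or ``diagonal``, sorted by correlation descending (ties:
    earlier row time, then earlier column time).  For each window end
    50, 100, ... a one-sided binomial test compares the a_to_b count against
    the analytic null proportion (T-1)/(2T).
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    T = M.shape[0]
    rows, cols = np.meshgrid(np.arange(T), np.arange(T), indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    vals = M.ravel()
    order = np.lexsort((times[cols], times[rows], -vals))
    rows, cols, vals = rows[order], cols[order], vals[order]
    labels = np.where(cols > rows, "a_to_b", np.where(cols < rows, "b_to_a", "diagonal"))
    delays = times[cols] - times[rows]

    p0 = rolling_null_proportion(T)
    rolling = []
    for end in range(window_increment, len(vals) + 1, window_increment):
        k = int((labels[:end] == "a_to_b").sum())
        test = stats.binomtest(k, end, p0, alternative="greater")
        rolling.append({"window_end": end, "proportion": k / end, "p": float(test.pvalue)})

    top_fwd = labels[:top_k] == "a_to_b"
    mean_delay = float(delays[:top_k][top_fwd].mean()) if top_fwd.any() else float("nan")
    ranked = [
        {"row_time_ms": float(times[r]), "col_time_ms": float(times[c]),
         "value": float(v), "label": str(l)}
        for r, c, v, l in zip(rows, cols, vals, labels)
    ]
    return {
        "ranked": ranked,
        "rolling": rolling,
        "null_proportion": p0,
        "top_k": top_k,
        "top_k_forward_count": int(top_fwd.sum()),
        "mean_delay_ms": mean_delay,
    }


def partial_timegen(rdms_a: RDMSeries, rdms_b: RDMSeries, rdms_cov: RDMSeries) -> np.ndarray:
    """Partial correlations controlling the covariate region's RDM at the row time.

    Entry (i, j) is the partial correlation between A's RDM vector at time i
    and B's RDM vector at time j, controlling for the covariate's RDM vector
    at time i.  Cells where the covariate is collinear with either vector
    are set to 0 (logged).
    """
    if not (np.allclose(rdms_a.times, rdms_b.times) and np.allclose(rdms_a.times, rdms_cov.times)):
        raise ValueError("RDM series must share the time grid")
    Va, zero_a = _zscore_rows(_upper_vectors(rdms_a))
    Vb, zero_b = _zscore_rows(_upper_vectors(rdms_b))
    Vc, zero_c = _zscore_rows(_upper_vectors(rdms_cov))
    m = Va.shape[1]
    r_ab = (Va @ Vb.T) / m          # (i, j)
    r_ac = (Va * Vc).sum(axis=1) / m  # per row time i
    r_cb = (Vc @ Vb.T) / m          # (i, j): cov at i vs B at j

    denom = np.sqrt(np.clip(1 - r_ac[:, None] ** 2, 0, None) * np.clip(1 - r_cb**2, 0, None))
    bad = denom < 1e-12
    denom[bad] = 1.0
    out = (r_ab - r_ac[:, None] * r_cb) / denom
    if bad.any():
        logger.info("%d cells with collinear covariate set to 0", int(bad.sum()))
        out[bad] = 0.0
    out[zero_a, :] = 0.0
    out[:, zero_b] = 0.0
    return out
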