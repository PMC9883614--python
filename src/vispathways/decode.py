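"""Time-resolved category decoding with exemplar-level generalization.

A linear support-vector classifier is trained, at every timepoint, on the
multichannel patterns of single trials from a subset of each category's
exemplars and tested on trials of the held-out exemplars, forcing the
classifier to generalize across exemplars rather than memorize them.
Cross-validation folds are seeded random draws of the joint per-category
exemplar split (by default 3 train / 2 test exemplars per category, 100
folds drawn without replacement from the 10^4 possible joint splits).

Group statistics:

- ``bootstrap_ci``: percentile confidence intervals of the mean accuracy
  from participant resampling.
- ``bootstrap_onsets``: distribution over bootstrap resamples of the
  earliest post-stimulus timepoint whose one-sided t-test against chance is
  significant for a minimum number of consecutive timepoints.
- ``precedence_binomial``: exact binomial test of how often one region's
  onset precedes another's across paired resamples.

Control analyses: leave-one-category-out decoding (chance 1/3), channel
resampling with replacement, and residualization of the regions of
interest against principal components of the rest of the montage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from sklearn import config_context
from sklearn.svm import LinearSVC

try:  # fast path: skip estimator bookkeeping in the hot per-timepoint loop
    from sklearn.svm._base import _fit_liblinear
except ImportError:  # pragma: no cover
    _fit_liblinear = None

from .containers import EpochedDataset

logger = logging.getLogger(__name__)


def _svm_fit_predict(
    X_tr: np.ndarray, y_tr: np.ndarray, X_te: np.ndarray, C: float
) -> np.ndarray:
    """Linear max-margin (L2, squared hinge) classifier: fit and predict labels."""
    if _fit_liblinear is not None:
        W, b, _ = _fit_liblinear(
            X_tr, y_tr, C, True, 1.0, None, "l2", False, 0, 1000, 1e-3,
            multi_class="ovr", loss="squared_hinge",
        )
        scores = X_te @ W.T + b
        classes = np.unique(y_tr)
        if len(classes) == 2:
            return np.where(scores[:, 0] > 0, classes[1], classes[0])
        return classes[scores.argmax(axis=1)]
    clf = LinearSVC(C=C, dual=False, tol=1e-3)
    clf.fit(X_tr, y_tr)
    return clf.predict(X_te)


@dataclass
class DecodingResult:
    """Per-participant, per-timepoint decoding accuracy for one region."""

    accuracy: np.ndarray  # participants x timepoints, in [0, 1]
    chance: float
    times: np.ndarray
    region: str
    participants: tuple[str, ...] = ()


@dataclass
class OnsetDistribution:
    """Bootstrap distribution of decoding-onset latencies (NaN = no onset found)."""

    onsets_ms: np.ndarray
    n_boot: int
    alpha: float
    consecutive: int

    @property
    def median_onset_ms(self) -> float:
        valid = self.onsets_ms[~np.isnan(self.onsets_ms)]
        return float(np.median(valid)) if len(valid) else float("nan")

    @property
    def detection_rate(self) -> float:
        return float(np.mean(~np.isnan(self.onsets_ms)))


# ---------------------------------------------------------------------------
# Exemplar-split cross-validated decoding
# ---------------------------------------------------------------------------

def _joint_exemplar_splits(
    n_categories: int, n_exemplars: int, n_folds: int, rng: np.random.Generator
) -> list[list[tuple[int, ...]]]:
    """Seeded draws (without replacement) of joint per-category train-exemplar splits."""
    if n_exemplars < 3:
        raise ValueError("each category needs at least 3 exemplars")
    n_test = 2 if n_exemplars >= 5 else 1
    n_train = n_exemplars - n_test
    per_cat = list(combinations(range(n_exemplars), n_train))
    base = len(per_cat)
    total = base**n_categories
    if n_folds >= total:
        chosen = np.arange(total)
    else:
        chosen = rng.choice(total, size=n_folds, replace=False)
    splits = []
    for code in chosen:
        split = []
        for _ in range(n_categories):
            code, rem = divmod(int(code), base)
            split.append(per_cat[rem])
        splits.append(split)
    return splits


def _decode_array(
    data: np.ndarray,
    categories: np.ndarray,
    exemplars: np.ndarray,
    n_folds: int,
    fold_seed: int,
    C: float = 1.0,
) -> np.ndarray:
    """Mean cross-validated accuracy per timepoint for trials x channels x timepoints."""
    cats = np.unique(categories)
    n_cat = len(cats)
    cat_index = {c: i for i, c in enumerate(cats)}
    y = np.asarray([cat_index[c] for c in categories])

    exs = np.unique(exemplars)
    n_ex = len(exs)
    ex_index = {e: i for i, e in enumerate(exs)}
    e = np.asarray([ex_index[x] for x in exemplars])

    rng = np.random.default_rng(fold_seed)
    splits = _joint_exemplar_splits(n_cat, n_ex, n_folds, rng)
    n_tp = data.shape[2]
    acc = np.zeros(n_tp)

    with config_context(assume_finite=True):
        for split in splits:
            train_mask = np.zeros(len(y), dtype=bool)
            for ci, train_ex in enumerate(split):
                train_mask |= (y == ci) & np.isin(e, train_ex)
            test_mask = ~train_mask
            y_tr, y_te = y[train_mask], y[test_mask]
            X_tr_all, X_te_all = data[train_mask], data[test_mask]
            for t in range(n_tp):
                X_tr = X_tr_all[:, :, t]
                X_te = X_te_all[:, :, t]
                mu = X_tr.mean(axis=0)
                sd = X_tr.std(axis=0)
                sd[sd == 0] = 1.0
                pred = _svm_fit_predict((X_tr - mu) / sd, y_tr, (X_te - mu) / sd, C)
                acc[t] += np.mean(pred == y_te)
    return acc / len(splits)


def decode_timecourse(
    dataset: EpochedDataset,
    region: str,
    categories: list[int] | None = None,
    n_folds: int = 100,
    fold_seed: int = 0,
    channel_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Per-timepoint exemplar-generalizing category decoding accuracy for one region."""
    if categories is not None:
        dataset = dataset.select_categories(categories)
    if channel_indices is None:
        channel_indices = dataset.montage.require_region(region, min_channels=2)
    data = dataset.data[:, channel_indices, :]
    return _decode_array(data, dataset.categories, dataset.exemplars, n_folds, fold_seed)


def decode_cohort(
    cohort: list[EpochedDataset],
    region: str,
    categories: list[int] | None = None,
    n_folds: int = 100,
    fold_seed: int = 0,
) -> DecodingResult:
    """Decoding timecourses for every participant in a cohort."""
    ref = cohort[0] if categories is None else cohort[0].select_categories(categories)
    n_cat = len(np.unique(ref.categories))
    acc = np.stack(
        [
            decode_timecourse(
                ds, region, categories=categories, n_folds=n_folds,
                fold_seed=int(np.random.default_rng([fold_seed, p]).integers(2**31)),
            )
            for p, ds in enumerate(cohort)
        ]
    )
    return DecodingResult(
        accuracy=acc,
        chance=1.0 / n_cat,
        times=cohort[0].times,
        region=region,
        participants=tuple(ds.participant_id for ds in cohort),
    )


# ---------------------------------------------------------------------------
# Bootstrap statistics on decoding accuracy
# ---------------------------------------------------------------------------

def bootstrap_ci(
    result: DecodingResult, n_boot: int = 10000, seed: int = 0, ci: float = 95.0
) -> dict:
    """Percentile CIs of mean accuracy from participant resampling, plus above-chance flags."""
    A = result.accuracy
    n_p = A.shape[0]
    if n_p < 2:
        raise ValueError("bootstrap CI requires at least 2 participants")
    if n_boot < 100:
        logger.warning("n_boot=%d is small; CIs will be coarse", n_boot)
    rng = np.random.default_rng(seed)
    means = np.empty((n_boot, A.shape[1]))
    chunk = max(1, min(n_boot, int(2e7 / (n_p * A.shape[1]))))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.integers(0, n_p, size=(b, n_p))
        means[done : done + b] = A[idx].mean(axis=1)
        done += b
    lo = np.percentile(means, (100 - ci) / 2, axis=0)
    hi = np.percentile(means, 100 - (100 - ci) / 2, axis=0)
    return {
        "mean": A.mean(axis=0),
        "ci_low": lo,
        "ci_high": hi,
        "above_chance": lo > result.chance,
        "times": result.times,
    }


def _first_onset(sig: np.ndarray, consecutive: int) -> int:
    """Index of the first run of >= ``consecutive`` True values, or -1."""
    if consecutive <= 1:
        hits = np.flatnonzero(sig)
        return int(hits[0]) if len(hits) else -1
    window = np.lib.stride_tricks.sliding_window_view(sig, consecutive)
    runs = window.all(axis=1)
    hits = np.flatnonzero(runs)
    return int(hits[0]) if len(hits) else -1


def _onsets_from_accuracy(
    A: np.ndarray,
    times: np.ndarray,
    chance: float,
    alpha: float,
    consecutive: int,
) -> float:
    """Onset latency from one accuracy matrix (participants x timepoints).

    One-sided t-test against chance at every timepoint >= 0 ms; the onset is
    the first timepoint opening a run of ``consecutive`` significant
    timepoints.  Returns NaN when no such run exists.
    """
    post = times >= 0
    sub = A[:, post]
    n = sub.shape[0]
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1)
    sig = np.zeros(sub.shape[1], dtype=bool)
    nz = sd > 0
    if nz.any():
        tstat = (mean[nz] - chance) / (sd[nz] / np.sqrt(n))
        sig[nz] = stats.t.sf(tstat, df=n - 1) < alpha
    if (~nz).any():
        sig[~nz] = mean[~nz] > chance
    i = _first_onset(sig, consecutive)
    return float(times[post][i]) if i >= 0 else float("nan")


def bootstrap_onsets(
    result: DecodingResult,
    n_boot: int = 10000,
    alpha: float = 0.05,
    consecutive: int = 2,
    seed: int = 0,
) -> OnsetDistribution:
    """Bootstrap (participants with replacement) distribution of decoding onsets."""
    A = result.accuracy
    n_p = A.shape[0]
    if n_p < 3:
        raise ValueError("bootstrap onsets require at least 3 participants")
    post = result.times >= 0
    times_post = result.times[post]
    Apost = A[:, post]
    rng = np.random.default_rng(seed)
    onsets = np.full(n_boot, np.nan)
    zero_var_hits = 0

    chunk = max(1, min(n_boot, int(2e7 / max(1, n_p * Apost.shape[1]))))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.integers(0, n_p, size=(b, n_p))
        sub = Apost[idx]  # b x n_p x T
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = (mean - result.chance) / (sd / np.sqrt(n_p))
        sig = stats.t.sf(tstat, df=n_p - 1) < alpha
        zero = sd == 0
        if zero.any():
            zero_var_hits += int(zero.sum())
            sig[zero] = mean[zero] > result.chance
        if consecutive > 1:
            window = np.lib.stride_tricks.sliding_window_view(sig, consecutive, axis=1)
            runs = window.all(axis=2)
        else:
            runs = sig
        any_run = runs.any(axis=1)
        first = runs.argmax(axis=1)
        vals = np.full(b, np.nan)
        vals[any_run] = times_post[first[any_run]]
        onsets[done : done + b] = vals
        done += b
    if zero_var_hits:
        logger.info(
            "%d timepoint t-tests had zero between-participant variance; "
            "treated as significant iff mean > chance",
            zero_var_hits,
        )
    return OnsetDistribution(onsets_ms=onsets, n_boot=n_boot, alpha=alpha, consecutive=consecutive)


def precedence_binomial(onsets_a: np.ndarray, onsets_b: np.ndarray) -> dict:
    """How often region A's onset precedes region B's across paired resamples.

    Pairs where both onsets are missing, or where the onsets tie, are
    excluded; a single missing onset counts as the other region preceding.
    Returns the proportion of A-first resamples and a two-sided exact
    binomial p-value against 0.5.
    """
    a = np.asarray(onsets_a, dtype=float)
    b = np.asarray(onsets_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("onset arrays must be paired by resample index")
    av = np.where(np.isnan(a), np.inf, a)
    bv = np.where(np.isnan(b), np.inf, b)
    informative = ~(np.isinf(av) & np.isinf(bv)) & (av != bv)
    n = int(informative.sum())
    if n == 0:
        raise ValueError("no informative resamples: all pairs tied or missing")
    k = int((av[informative] < bv[informative]).sum())
    test = stats.binomtest(k, n, 0.5, alternative="two-sided")
    return {"proportion_a_first": k / n, "p_value": float(test.pvalue), "n_informative": n}


# ---------------------------------------------------------------------------
# Control analyses
# ---------------------------------------------------------------------------

def leave_category_out(
    cohort: list[EpochedDataset],
    region_pair: tuple[str, str],
    n_resample: int = 1000,
    seed: int = 0,
    n_folds: int = 100,
    alpha: float = 0.05,
    consecutive: int = 2,
) -> dict:
    """Onset and precedence statistics with each category removed in turn (chance 1/3)."""
    all_cats = sorted(np.unique(cohort[0].categories).tolist())
    if len(all_cats) - 1 < 3:
        raise ValueError("need at least 3 categories remaining after removal")
    per_subset: dict[int, dict] = {}
    pooled = {region: [] for region in region_pair}
    for j, removed in enumerate(all_cats):
        kept = [c for c in all_cats if c != removed]
        entry = {"removed": removed}
        for r, region in enumerate(region_pair):
            res = decode_cohort(cohort, region, categories=kept, n_folds=n_folds, fold_seed=seed + j)
            dist = bootstrap_onsets(
                res, n_boot=n_resample, alpha=alpha, consecutive=consecutive,
                seed=int(np.random.default_rng([seed, j, r]).integers(2**31)),
            )
            entry[region] = dist
            pooled[region].append(dist.onsets_ms)
        entry["precedence"] = precedence_binomial(
            entry[region_pair[0]].onsets_ms, entry[region_pair[1]].onsets_ms
        )
        per_subset[removed] = entry
    pooled_a = np.concatenate(pooled[region_pair[0]])
    pooled_b = np.concatenate(pooled[region_pair[1]])
    return {
        "per_subset": per_subset,
        "pooled_onsets": {region_pair[0]: pooled_a, region_pair[1]: pooled_b},
        "pooled_precedence": precedence_binomial(pooled_a, pooled_b),
        "pooled_medians": {
            region_pair[0]: float(np.nanmedian(pooled_a)) if np.any(~np.isnan(pooled_a)) else float("nan"),
            region_pair[1]: float(np.nanmedian(pooled_b)) if np.any(~np.isnan(pooled_b)) else float("nan"),
        },
    }


def channel_resample(
    cohort: list[EpochedDataset],
    region_pair: tuple[str, str],
    n_resample: int = 1000,
    seed: int = 0,
    n_folds: int = 100,
    alpha: float = 0.05,
    consecutive: int = 2,
) -> dict:
    """Precedence statistics over with-replacement resamples of each region's channels."""
    rng = np.random.default_rng(seed)
    times = cohort[0].times
    onsets = {region: np.full(n_resample, np.nan) for region in region_pair}
    chance = 1.0 / len(np.unique(cohort[0].categories))
    for r in range(n_resample):
        for region in region_pair:
            acc = []
            for p, ds in enumerate(cohort):
                idx = ds.montage.require_region(region, min_channels=2)
                draw = idx[rng.integers(0, len(idx), size=len(idx))]
                acc.append(
                    decode_timecourse(
                        ds, region, n_folds=n_folds,
                        fold_seed=int(np.random.default_rng([seed, r, p]).integers(2**31)),
                        channel_indices=draw,
                    )
                )
            onsets[region][r] = _onsets_from_accuracy(
                np.stack(acc), times, chance, alpha, consecutive
            )
    return {
        "onsets": onsets,
        "precedence": precedence_binomial(onsets[region_pair[0]], onsets[region_pair[1]]),
    }


def residualize(
    cohort: list[EpochedDataset],
    roi_regions: tuple[str, ...] = ("dorsal", "ventral"),
    variance_retained: float = 0.95,
) -> list[EpochedDataset]:
    """Replace ROI channels by their residuals after regression on rest-of-montage PCs.

    Per participant, PCA is run on the trial-concatenated timeseries of all
    channels outside the regions of interest, components are retained up to
    ``variance_retained``, and each ROI channel is replaced by its residual
    after least-squares projection onto the retained component timecourses.
    """
    out = []
    for ds in cohort:
        roi_idx = np.concatenate([ds.montage.region_indices(r) for r in roi_regions])
        rest_idx = np.setdiff1d(np.arange(ds.n_channels), roi_idx)
        if len(rest_idx) == 0:
            raise ValueError("no channels outside the regions of interest")
        n_tr, _, n_tp = ds.data.shape
        rest = ds.data[:, rest_idx, :].transpose(0, 2, 1).reshape(n_tr * n_tp, len(rest_idx))
        rest = rest - rest.mean(axis=0, keepdims=True)
        u, s, _ = np.linalg.svd(rest, full_matrices=False)
        var = s**2
        frac = np.cumsum(var) / var.sum() if var.sum() > 0 else np.ones_like(var)
        k = int(np.searchsorted(frac, variance_retained - 1e-12) + 1)
        uk = u[:, :k]

        data = ds.data.copy()
        for ch in roi_idx:
            y = ds.data[:, ch, :].reshape(n_tr * n_tp)
            yc = y - y.mean()
            resid = yc - uk @ (uk.T @ yc)
            data[:, ch, :] = resid.reshape(n_tr, n_tp)
        out.append(
            EpochedDataset(
                data=data,
                times=ds.times,
                categories=ds.categories,
                exemplars=ds.exemplars,
                montage=ds.montage,
                sampling_rate=ds.sampling_rate,
                participant_id=ds.participant_id,
            )
        )
    return out
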