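"""Validation that region channel groups are functionally distinct.

Two analyses: (1) PCA over channels of the trial-averaged response, with
Euclidean distances between channel loading vectors, hierarchical
clustering, and a purity score quantifying how well the data-driven
clusters line up with the montage regions; (2) two signal-to-noise ratio
definitions (whole-timecourse mean/sd, and stimulus-period mean over
baseline sd).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from .containers import EpochedDataset


@dataclass
class DistinctnessReport:
    """Channel-space functional-similarity analysis of a cohort."""

    channel_distance_matrix: np.ndarray  # channels x channels, averaged over participants
    linkage: np.ndarray  # scipy linkage merge list
    cluster_labels: np.ndarray  # per channel, tree cut at n_regions
    purity: float
    regions: tuple[str, ...]  # montage region per channel


def _channel_loadings(dataset: EpochedDataset, variance_retained: float) -> np.ndarray:
    """Per-channel coordinates in the retained principal-component basis.

    PCA observations are the timepoints of the trial-averaged response;
    variables are channels.  Channel coordinates are scaled by the singular
    values, so with all components retained the pairwise Euclidean
    distances equal distances between the centered channel timecourses.
    """
    avg = dataset.data.mean(axis=0).T  # timepoints x channels
    if avg.shape[0] < 2:
        raise ValueError("need at least 2 timepoints for PCA")
    avg = avg - avg.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(avg, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        return np.zeros((avg.shape[1], 1))
    frac = np.cumsum(var) / total
    k = int(np.searchsorted(frac, variance_retained - 1e-12) + 1)
    return (vt[:k].T * s[:k])  # channels x k


def functional_distinctness(
    cohort: list[EpochedDataset],
    variance_retained: float = 0.95,
    n_clusters: int | None = None,
) -> DistinctnessReport:
    """PCA-loading distances, average-linkage clustering, and region purity.

    Distances between channel loading vectors are computed per participant
    and averaged across the cohort; average-linkage hierarchical clustering
    of the mean distance matrix is cut at the number of montage regions.
    Each channel is assigned to the cluster with the nearest mean distance
    to its members, clusters are matched one-to-one to regions to maximize
    agreement, and purity is the agreeing fraction.
    """
    montage = cohort[0].montage
    regions = tuple(montage.regions)
    present = montage.present_regions()
    if len(present) < 2:
        raise ValueError("need at least 2 regions in the montage")
    n_ch = montage.n_channels

    dist_sum = np.zeros((n_ch, n_ch))
    for ds in cohort:
        loadings = _channel_loadings(ds, variance_retained)
        diff = loadings[:, None, :] - loadings[None, :, :]
        dist_sum += np.sqrt((diff**2).sum(axis=2))
    dist = dist_sum / len(cohort)
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)

    n_clusters = n_clusters or len(present)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust") - 1

    # Nearest-cluster assignment: mean distance to each cluster's members.
    mean_to_cluster = np.stack(
        [dist[:, labels == c].mean(axis=1) for c in range(labels.max() + 1)], axis=1
    )
    assigned = mean_to_cluster.argmin(axis=1)

    # One-to-one cluster->region matching maximizing agreement.
    region_names = sorted(set(regions))
    contingency = np.zeros((assigned.max() + 1, len(region_names)))
    for ch in range(n_ch):
        contingency[assigned[ch], region_names.index(regions[ch])] += 1
    rows, cols = linear_sum_assignment(-contingency)
    purity = contingency[rows, cols].sum() / n_ch

    return DistinctnessReport(
        channel_distance_matrix=dist,
        linkage=link,
        cluster_labels=labels,
        purity=float(purity),
        regions=regions,
    )


def snr_timecourse(dataset: EpochedDataset, region: str) -> float:
    """Mean of the trial-averaged timecourse over its sd, averaged over region channels."""
    idx = dataset.montage.require_region(region, min_channels=1)
    avg = dataset.data[:, idx, :].mean(axis=0)  # channels x timepoints
    sd = avg.std(axis=1)
    if np.any(sd == 0):
        raise ValueError(f"zero-variance trial-averaged channel in region {region!r}")
    return float((avg.mean(axis=1) / sd).mean())


def snr_baseline(
    dataset: EpochedDataset,
    region: str,
    stimulus_window_ms: tuple[float, float] = (0.0, 300.0),
) -> float:
    """Stimulus-period mean over pre-stimulus baseline sd, averaged over region channels."""
    idx = dataset.montage.require_region(region, min_channels=1)
    pre = dataset.times < 0
    if not pre.any():
        raise ValueError("epoch contains no pre-stimulus samples")
    stim = (dataset.times >= stimulus_window_ms[0]) & (dataset.times <= stimulus_window_ms[1])
    avg = dataset.data[:, idx, :].mean(axis=0)
    sd = avg[:, pre].std(axis=1)
    if np.any(sd == 0):
        raise ValueError(f"zero baseline variance in region {region!r}")
    return float((avg[:, stim].mean(axis=1) / sd).mean())
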