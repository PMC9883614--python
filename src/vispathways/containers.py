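"""Core data containers and on-disk formats.

Epoched multichannel EEG-like data travel through the pipeline as
:class:`EpochedDataset` (trials x channels x timepoints plus per-trial
category/exemplar labels), with a :class:`ChannelMontage` mapping channels
to cortical regions (occipital, dorsal, ventral, frontal).  Continuous
recordings, used by the preprocessing stage, are held in
:class:`ContinuousRecording`.

On disk a dataset is an HDF5 container (``/data``, ``/times``; attributes
``sampling_rate``, ``participant_id``) plus a CSV trial table
(``trial_index, category_id, exemplar_id``) and a JSON montage sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

REGIONS = ("occipital", "dorsal", "ventral", "frontal", "other")
HEMISPHERES = ("left", "right", "midline")


class ConfigurationError(ValueError):
    """Raised when a montage, generator, or pipeline configuration is invalid."""


@dataclass(frozen=True)
class ChannelMontage:
    """Channel identifiers with a region and hemisphere per channel."""

    channel_ids: tuple[str, ...]
    regions: tuple[str, ...]
    hemispheres: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ConfigurationError("duplicate channel ids in montage")
        if not (len(self.channel_ids) == len(self.regions) == len(self.hemispheres)):
            raise ConfigurationError("montage field lengths differ")
        for r in self.regions:
            if r not in REGIONS:
                raise ConfigurationError(f"unknown region {r!r}; expected one of {REGIONS}")
        for h in self.hemispheres:
            if h not in HEMISPHERES:
                raise ConfigurationError(f"unknown hemisphere {h!r}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def region_indices(self, region: str) -> np.ndarray:
        """Indices of channels assigned to ``region`` (order preserved)."""
        if region not in REGIONS:
            raise ConfigurationError(f"unknown region {region!r}")
        idx = np.flatnonzero(np.asarray(self.regions) == region)
        return idx

    def require_region(self, region: str, min_channels: int = 2) -> np.ndarray:
        idx = self.region_indices(region)
        if len(idx) < min_channels:
            raise ConfigurationError(
                f"region {region!r} has {len(idx)} channels; "
                f"analysis requires at least {min_channels}"
            )
        return idx

    def present_regions(self) -> list[str]:
        return [r for r in REGIONS if len(self.region_indices(r)) > 0]

    def subset(self, indices: Sequence[int]) -> "ChannelMontage":
        indices = list(indices)
        return ChannelMontage(
            channel_ids=tuple(self.channel_ids[i] for i in indices),
            regions=tuple(self.regions[i] for i in indices),
            hemispheres=tuple(self.hemispheres[i] for i in indices),
        )

    def to_dict(self) -> dict:
        return {
            "channel_ids": list(self.channel_ids),
            "regions": list(self.regions),
            "hemispheres": list(self.hemispheres),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ChannelMontage":
        return cls(
            channel_ids=tuple(d["channel_ids"]),
            regions=tuple(d["regions"]),
            hemispheres=tuple(d["hemispheres"]),
        )


@dataclass
class EpochedDataset:
    """Epoched trials: data[trial, channel, timepoint] with per-trial labels.

    ``times`` is in milliseconds relative to stimulus onset and must lie on a
    regular grid of step ``1000 / sampling_rate``.
    """

    data: np.ndarray
    times: np.ndarray
    categories: np.ndarray
    exemplars: np.ndarray
    montage: ChannelMontage
    sampling_rate: float
    participant_id: str = "p00"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.categories = np.asarray(self.categories, dtype=int)
        self.exemplars = np.asarray(self.exemplars, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x timepoints")
        n_tr, n_ch, n_tp = self.data.shape
        if len(self.times) != n_tp:
            raise ValueError("times length does not match timepoint dimension")
        if n_ch != self.montage.n_channels:
            raise ValueError("channel dimension does not match montage")
        if len(self.categories) != n_tr or len(self.exemplars) != n_tr:
            raise ValueError("label lengths do not match trial dimension")
        step = 1000.0 / self.sampling_rate
        diffs = np.diff(self.times)
        if len(diffs) and not np.allclose(diffs, step, atol=1e-9):
            raise ValueError("times must increase with constant step 1000/sampling_rate")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def object_ids(self) -> np.ndarray:
        """Unique object id per trial: one object = one (category, exemplar) pair."""
        n_ex = int(self.exemplars.max()) + 1 if len(self.exemplars) else 0
        return self.categories * n_ex + self.exemplars

    def select_trials(self, mask: np.ndarray) -> "EpochedDataset":
        return EpochedDataset(
            data=self.data[mask],
            times=self.times,
            categories=self.categories[mask],
            exemplars=self.exemplars[mask],
            montage=self.montage,
            sampling_rate=self.sampling_rate,
            participant_id=self.participant_id,
        )

    def select_categories(self, categories: Sequence[int]) -> "EpochedDataset":
        mask = np.isin(self.categories, list(categories))
        return self.select_trials(mask)

    def select_channels(self, indices: Sequence[int]) -> "EpochedDataset":
        indices = list(indices)
        return EpochedDataset(
            data=self.data[:, indices, :],
            times=self.times,
            categories=self.categories,
            exemplars=self.exemplars,
            montage=self.montage.subset(indices),
            sampling_rate=self.sampling_rate,
            participant_id=self.participant_id,
        )

    def region_data(self, region: str, min_channels: int = 2) -> np.ndarray:
        idx = self.montage.require_region(region, min_channels)
        return self.data[:, idx, :]


@dataclass
class ContinuousRecording:
    """Continuous multichannel recording with stimulus events.

    ``events`` rows are (sample_index, category_id, exemplar_id).
    """

    data: np.ndarray
    sampling_rate: float
    events: np.ndarray
    montage: ChannelMontage

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.events = np.asarray(self.events, dtype=int).reshape(-1, 3)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.events) and (
            self.events[:, 0].min() < 0 or self.events[:, 0].max() >= self.data.shape[1]
        ):
            raise ValueError("event sample indices outside recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# On-disk container: HDF5 arrays + CSV trial table + JSON montage sidecar
# ---------------------------------------------------------------------------

def save_dataset(dataset: EpochedDataset, directory: str | Path, stem: str | None = None) -> dict:
    """Write one dataset as ``<stem>.h5`` + ``<stem>_trials.csv`` + ``<stem>_montage.json``.

    Returns a manifest dict of the written paths.
    """
    import h5py

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or dataset.participant_id
    h5_path = directory / f"{stem}.h5"
    csv_path = directory / f"{stem}_trials.csv"
    json_path = directory / f"{stem}_montage.json"

    with h5py.File(h5_path, "w") as f:
        f.create_dataset("data", data=dataset.data)
        f.create_dataset("times", data=dataset.times)
        f.attrs["sampling_rate"] = dataset.sampling_rate
        f.attrs["participant_id"] = dataset.participant_id

    pd.DataFrame(
        {
            "trial_index": np.arange(dataset.n_trials),
            "category_id": dataset.categories,
            "exemplar_id": dataset.exemplars,
        }
    ).to_csv(csv_path, index=False)

    json_path.write_text(json.dumps(dataset.montage.to_dict(), indent=1))
    return {"h5": str(h5_path), "trials": str(csv_path), "montage": str(json_path)}


def load_dataset(directory: str | Path, stem: str) -> EpochedDataset:
    """Load a dataset written by :func:`save_dataset`."""
    import h5py

    directory = Path(directory)
    with h5py.File(directory / f"{stem}.h5", "r") as f:
        data = f["data"][()]
        times = f["times"][()]
        sampling_rate = float(f.attrs["sampling_rate"])
        participant_id = str(f.attrs["participant_id"])
    trials = pd.read_csv(directory / f"{stem}_trials.csv")
    montage = ChannelMontage.from_dict(json.loads((directory / f"{stem}_montage.json").read_text()))
    return EpochedDataset(
        data=data,
        times=times,
        categories=trials["category_id"].to_numpy(),
        exemplars=trials["exemplar_id"].to_numpy(),
        montage=montage,
        sampling_rate=sampling_rate,
        participant_id=participant_id,
    )
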