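"""Shared fixtures: small synthetic cohorts and hand-built datasets."""

import numpy as np
import pytest

from vispathways import (
    ChannelMontage,
    EpochedDataset,
    GeneratorConfig,
    RegionSignal,
    baseline_correct,
    simulate_cohort,
)


def make_dataset(
    data: np.ndarray,
    regions: list[str],
    categories: np.ndarray,
    exemplars: np.ndarray,
    sampling_rate: float = 250.0,
    t0_ms: float = -48.0,
) -> EpochedDataset:
    """Wrap an array in an EpochedDataset with a minimal montage."""
    n_ch = data.shape[1]
    montage = ChannelMontage(
        channel_ids=tuple(f"ch{i}" for i in range(n_ch)),
        regions=tuple(regions),
        hemispheres=("midline",) * n_ch,
    )
    step = 1000.0 / sampling_rate
    times = t0_ms + step * np.arange(data.shape[2])
    return EpochedDataset(
        data=data, times=times, categories=categories, exemplars=exemplars,
        montage=montage, sampling_rate=sampling_rate,
    )


@pytest.fixture(scope="session")
def mini_config() -> GeneratorConfig:
    """Small cohort with distinct dorsal/ventral onsets, no coupling, short epochs."""
    return GeneratorConfig(
        n_participants=3,
        n_reps=4,
        seed=123,
        epoch_window_ms=(-48.0, 152.0),
        region_sizes={"dorsal": 3, "ventral": 3, "occipital": 2, "frontal": 2},
        region_signals={
            "dorsal": RegionSignal(onset_ms=60.0, amplitude=1.0),
            "ventral": RegionSignal(onset_ms=88.0, amplitude=1.0),
        },
        couplings=(),
    )


@pytest.fixture(scope="session")
def mini_cohort(mini_config):
    return [baseline_correct(ds) for ds in simulate_cohort(mini_config)]
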