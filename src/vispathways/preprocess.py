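"""Preprocessing chain for continuous recordings.

Stages: zero-phase band-pass filtering (0.1-40 Hz defaults), anti-aliased
integer-factor downsampling (1000 -> 250 Hz in the emulated acquisition),
average re-referencing, bad-channel detection (flatline or low correlation
with every other channel), epoching around stimulus events, and
amplitude-threshold artifact rejection.

Filtering is forward-backward (zero-phase) with a 4th-order Butterworth
design so that no latency shift can corrupt downstream onset estimates.
Bad channels are dropped rather than interpolated.  Baseline correction
(mean of the pre-stimulus samples subtracted per trial and channel)
defaults on.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from .containers import ContinuousRecording, EpochedDataset

logger = logging.getLogger(__name__)


def bandpass(
    recording: ContinuousRecording,
    high_pass_hz: float = 0.1,
    low_pass_hz: float = 40.0,
    order: int = 4,
) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass; length and events preserved."""
    nyq = recording.sampling_rate / 2.0
    if not (0 < high_pass_hz < low_pass_hz < nyq):
        raise ValueError(
            f"cutoffs must satisfy 0 < {high_pass_hz} < {low_pass_hz} < Nyquist ({nyq} Hz)"
        )
    sos = signal.butter(
        order, [high_pass_hz, low_pass_hz], btype="bandpass", fs=recording.sampling_rate, output="sos"
    )
    filtered = signal.sosfiltfilt(sos, recording.data, axis=1)
    return ContinuousRecording(filtered, recording.sampling_rate, recording.events, recording.montage)


def downsample(recording: ContinuousRecording, target_hz: float = 250.0) -> ContinuousRecording:
    """Anti-aliased decimation by an integer factor; event indices rescaled."""
    factor = recording.sampling_rate / target_hz
    if not np.isclose(factor, round(factor)):
        raise ValueError(
            f"sampling rate {recording.sampling_rate} Hz not an integer multiple of {target_hz} Hz"
        )
    factor = int(round(factor))
    if factor == 1:
        return recording
    data = signal.decimate(recording.data, factor, axis=1, ftype="fir", zero_phase=True)
    events = recording.events.copy()
    if len(events):
        events[:, 0] = events[:, 0] // factor
    return ContinuousRecording(data, target_hz, events, recording.montage)


def rereference_average(recording: ContinuousRecording) -> ContinuousRecording:
    """Subtract the per-sample mean across channels (average reference)."""
    if recording.data.shape[0] < 2:
        raise ValueError("average reference requires at least 2 channels")
    data = recording.data - recording.data.mean(axis=0, keepdims=True)
    return ContinuousRecording(data, recording.sampling_rate, recording.events, recording.montage)


def detect_bad_channels(
    recording: ContinuousRecording,
    flat_seconds: float = 5.0,
    corr_threshold: float = 0.8,
) -> list[str]:
    """Channels flat for >= ``flat_seconds`` or poorly correlated with every other channel."""
    n_flat = int(round(flat_seconds * recording.sampling_rate))
    if recording.n_samples <= n_flat:
        raise ValueError("recording shorter than the flatline criterion window")
    bad: set[int] = set()

    # Flatline: any run of constant samples at least n_flat long.
    for ch in range(recording.data.shape[0]):
        d = np.diff(recording.data[ch]) == 0
        if not d.any():
            continue
        # longest run of True in d corresponds to run_length + 1 constant samples
        changes = np.diff(np.concatenate(([0], d.view(np.int8), [0])))
        starts = np.flatnonzero(changes == 1)
        ends = np.flatnonzero(changes == -1)
        if len(starts) and (ends - starts).max() + 1 >= n_flat:
            bad.add(ch)

    # Correlation: max |corr| with any other channel below threshold.
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(recording.data)
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr)
    max_abs = np.abs(corr).max(axis=1)
    bad.update(np.flatnonzero(max_abs < corr_threshold).tolist())

    names = [recording.montage.channel_ids[i] for i in sorted(bad)]
    if names:
        logger.info("flagged %d bad channels: %s", len(names), names)
    return names


def drop_channels(recording: ContinuousRecording, channel_ids: list[str]) -> ContinuousRecording:
    """Remove the named channels from data and montage."""
    keep = [i for i, cid in enumerate(recording.montage.channel_ids) if cid not in set(channel_ids)]
    return ContinuousRecording(
        recording.data[keep],
        recording.sampling_rate,
        recording.events,
        recording.montage.subset(keep),
    )


def epoch(
    recording: ContinuousRecording,
    window_ms: tuple[float, float] = (-48.0, 500.0),
    baseline_correct: bool = True,
    participant_id: str = "p00",
) -> EpochedDataset:
    """Segment the recording into trials around each event.

    Events whose window would fall outside the recording are dropped (and
    logged).  With ``baseline_correct`` the mean of the pre-stimulus samples
    is subtracted per trial and channel.
    """
    step = 1000.0 / recording.sampling_rate
    t0, t1 = window_ms
    offsets = np.arange(int(round(t0 / step)), int(round(t1 / step)) + 1)
    times = offsets * step

    trials, cats, exs, dropped = [], [], [], 0
    for sample, cat, ex in recording.events:
        lo, hi = sample + offsets[0], sample + offsets[-1]
        if lo < 0 or hi >= recording.n_samples:
            dropped += 1
            continue
        trials.append(recording.data[:, lo : hi + 1])
        cats.append(cat)
        exs.append(ex)
    if dropped:
        logger.warning("dropped %d events too close to the recording edge", dropped)
    if not trials:
        raise ValueError("no events with a full epoch window inside the recording")

    data = np.stack(trials)
    if baseline_correct:
        pre = times < 0
        if pre.any():
            data = data - data[:, :, pre].mean(axis=2, keepdims=True)
    return EpochedDataset(
        data=data,
        times=times,
        categories=np.asarray(cats),
        exemplars=np.asarray(exs),
        montage=recording.montage,
        sampling_rate=recording.sampling_rate,
        participant_id=participant_id,
    )


def reject_epochs_threshold(dataset: EpochedDataset, abs_threshold: float = 100.0) -> EpochedDataset:
    """Drop trials containing any sample with |value| > abs_threshold."""
    if abs_threshold <= 0:
        raise ValueError("abs_threshold must be positive")
    keep = np.abs(dataset.data).max(axis=(1, 2)) <= abs_threshold
    if not keep.any():
        raise ValueError("all trials rejected by the amplitude threshold")
    n_rej = int((~keep).sum())
    if n_rej:
        logger.info("rejected %d/%d trials above |%g|", n_rej, dataset.n_trials, abs_threshold)
    return dataset.select_trials(keep)


def baseline_correct(dataset: EpochedDataset) -> EpochedDataset:
    """Subtract the per-trial, per-channel mean of the pre-stimulus samples."""
    pre = dataset.times < 0
    if not pre.any():
        raise ValueError("no pre-stimulus samples to baseline-correct against")
    data = dataset.data - dataset.data[:, :, pre].mean(axis=2, keepdims=True)
    return EpochedDataset(
        data=data,
        times=dataset.times,
        categories=dataset.categories,
        exemplars=dataset.exemplars,
        montage=dataset.montage,
        sampling_rate=dataset.sampling_rate,
        participant_id=dataset.participant_id,
    )
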