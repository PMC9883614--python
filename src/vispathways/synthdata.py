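"""Synthetic epoched-EEG cohorts with known latencies and directed coupling.

The generator emulates the structure of a visual object-recognition EEG
experiment: 4 categories x 5 exemplars x 84 repetitions per exemplar,
550-ms epochs (12 pre-stimulus samples, 500 ms post-onset) sampled at
250 Hz, with channel groups for occipital, dorsal, ventral, and frontal
regions.  Each region can carry a category-discriminative signal with a
configurable onset latency, and a source region's signal can be injected
into a target region with a configurable lag and gain (directed coupling),
so decoding-onset, Granger-causality, and time-generalization analyses all
have recoverable ground truth.

Signal model per region
-----------------------
Every (category, exemplar) pair owns a time-varying spatial pattern over
the region's channels: a fixed unit-norm category vector mixed with a
slowly drifting, temporally smoothed random trajectory (and a smaller
exemplar-specific perturbation of the same form).  The pattern is gated by
an envelope that is zero before the region's onset, ramps up linearly over
20 ms, and stays on until stimulus offset (300 ms).  The drifting component
makes the representational geometry evolve over time, which is what lets a
lagged copy of the source signal be localized in time by the
time-generalization analyses; a purely static pattern would make every
post-onset timepoint representationally identical.

Noise is additive per trial: white Gaussian mixed with a 1/f ("pink")
component in a configurable proportion, giving an EEG-like spectrum.
Coupling injects the source's *noiseless* signal into the target (through a
fixed random channel-mixing matrix), so the directed ground truth is
unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .containers import (
    REGIONS,
    ChannelMontage,
    ConfigurationError,
    EpochedDataset,
)

DEFAULT_REGION_SIZES: dict[str, int] = {
    "occipital": 14,
    "dorsal": 28,
    "ventral": 28,
    "frontal": 28,
}

#: Stream tags for deriving independent RNGs from (seed, participant_seed).
_STREAM_PATTERN = 1
_STREAM_NOISE = 2
_STREAM_MIXING = 3


def make_montage(region_sizes: Mapping[str, int] | Sequence[tuple[str, int]] | None = None) -> ChannelMontage:
    """Build a montage with the given number of channels per region.

    Channels are named ``<region>_<hemi>_<k>``.  Even counts are split
    half/half across hemispheres; an odd count places the last channel on
    the midline.  Defaults: 14 occipital, 28 dorsal, 28 ventral, 28 frontal
    (14 per hemisphere for the bilateral groups).
    """
    if region_sizes is None:
        region_sizes = DEFAULT_REGION_SIZES
    if not isinstance(region_sizes, Mapping):
        pairs = list(region_sizes)
        keys = [k for k, _ in pairs]
        if len(set(keys)) != len(keys):
            raise ConfigurationError("duplicate region key in region_sizes")
        region_sizes = dict(pairs)

    ids, regions, hemis = [], [], []
    for region, count in region_sizes.items():
        if region not in REGIONS:
            raise ConfigurationError(f"unknown region {region!r}; expected one of {REGIONS}")
        if count < 0:
            raise ConfigurationError(f"negative channel count for region {region!r}")
        half = count // 2
        for k in range(count):
            if k < half:
                hemi, label = "left", "L"
            elif k < 2 * half:
                hemi, label = "right", "R"
            else:
                hemi, label = "midline", "M"
            ids.append(f"{region}_{label}_{k % half if half else k}")
            regions.append(region)
            hemis.append(hemi)
    return ChannelMontage(tuple(ids), tuple(regions), tuple(hemis))


@dataclass(frozen=True)
class RegionSignal:
    """Category-discriminative signal embedded in one region.

    onset_ms
        Latency of the earliest category information, on the sample grid.
    amplitude
        Scale of the category pattern relative to unit-variance noise.
    pattern_seed
        Extra entropy for this region's pattern RNG stream.
    """

    onset_ms: float = 60.0
    amplitude: float = 1.0
    pattern_seed: int = 0


@dataclass(frozen=True)
class Coupling:
    """Lagged linear propagation of one region's signal into another."""

    source: str = "dorsal"
    target: str = "ventral"
    lag_ms: float = 28.0
    gain: float = 0.5


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise: total sd ``white_sd``, split white vs 1/f by ``pink_fraction``."""

    white_sd: float = 1.0
    pink_fraction: float = 0.5


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of a synthetic cohort."""

    n_participants: int = 20
    n_categories: int = 4
    n_exemplars: int = 5
    n_reps: int = 84
    sampling_rate: float = 250.0
    epoch_window_ms: tuple[float, float] = (-48.0, 500.0)
    stimulus_duration_ms: float = 300.0
    region_signals: Mapping[str, RegionSignal] = field(
        default_factory=lambda: {
            "occipital": RegionSignal(onset_ms=60.0),
            "dorsal": RegionSignal(onset_ms=60.0),
            "ventral": RegionSignal(onset_ms=88.0),
            "frontal": RegionSignal(onset_ms=108.0),
        }
    )
    couplings: tuple[Coupling, ...] = (Coupling(),)
    noise: NoiseSpec = NoiseSpec()
    exemplar_scale: float = 0.3
    pattern_drift: float = 0.5
    drift_smooth_ms: float = 8.0
    ramp_ms: float = 20.0
    region_sizes: Mapping[str, int] | None = None
    seed: int = 0

    def montage(self) -> ChannelMontage:
        return make_montage(self.region_sizes)

    def times(self) -> np.ndarray:
        step = 1000.0 / self.sampling_rate
        t0, t1 = self.epoch_window_ms
        n = int(round((t1 - t0) / step)) + 1
        times = t0 + step * np.arange(n)
        if not np.isclose(times[-1], t1):
            raise ConfigurationError("epoch window not a multiple of the sample step")
        return times

    def validate(self) -> None:
        if min(self.n_participants, self.n_categories, self.n_exemplars, self.n_reps) < 1:
            raise ConfigurationError("all counts must be positive")
        t0, t1 = self.epoch_window_ms
        step = 1000.0 / self.sampling_rate
        for region, sig in self.region_signals.items():
            if region not in REGIONS:
                raise ConfigurationError(f"unknown region {region!r} in region_signals")
            if sig.amplitude < 0:
                raise ConfigurationError(f"negative amplitude for region {region!r}")
            if not (t0 <= sig.onset_ms <= t1):
                raise ConfigurationError(
                    f"onset {sig.onset_ms} ms for region {region!r} outside epoch window"
                )
        epoch_len_ms = t1 - t0
        for c in self.couplings:
            if c.lag_ms < 0 or c.lag_ms > 50:
                raise ConfigurationError(f"coupling lag {c.lag_ms} ms outside [0, 50]")
            if c.lag_ms > epoch_len_ms:
                raise ConfigurationError("coupling lag exceeds epoch length")
            if not np.isclose(c.lag_ms % step, 0) and not np.isclose(c.lag_ms % step, step):
                raise ConfigurationError(
                    f"coupling lag {c.lag_ms} ms is not a multiple of the sample step {step} ms"
                )


def _smooth_trajectory(rng: np.random.Generator, n_ch: int, n_tp: int, sigma_samples: float) -> np.ndarray:
    """Temporally smoothed random channel trajectory, unit-norm per timepoint."""
    raw = rng.standard_normal((n_ch, n_tp))
    smooth = ndimage.gaussian_filter1d(raw, sigma=max(sigma_samples, 1e-9), axis=1, mode="nearest")
    norms = np.linalg.norm(smooth, axis=0, keepdims=True)
    norms[norms == 0] = 1.0
    return smooth / norms


def _pattern_timecourse(
    rng: np.random.Generator,
    n_ch: int,
    n_tp: int,
    drift: float,
    sigma_samples: float,
) -> np.ndarray:
    """Unit-norm spatial pattern per timepoint: fixed base mixed with drift."""
    base = rng.standard_normal(n_ch)
    base /= np.linalg.norm(base)
    traj = _smooth_trajectory(rng, n_ch, n_tp, sigma_samples)
    mix = (1.0 - drift) * base[:, None] + drift * traj
    norms = np.linalg.norm(mix, axis=0, keepdims=True)
    norms[norms == 0] = 1.0
    return mix / norms


def _envelope(times: np.ndarray, onset_ms: float, offset_ms: float, ramp_ms: float, step_ms: float) -> np.ndarray:
    """0 before onset, linear 20-ms ramp (nonzero from the onset sample), off after offset."""
    env = np.clip((times - onset_ms + step_ms) / max(ramp_ms, step_ms), 0.0, 1.0)
    env[times < onset_ms] = 0.0
    env[times > offset_ms] = 0.0
    return env


def participant_templates(config: GeneratorConfig, participant_seed: int) -> np.ndarray:
    """Noiseless per-(category, exemplar) templates: array (n_cat, n_ex, n_ch, n_tp).

    Region signals are placed first, then coupling adds the lagged,
    channel-mixed source signal into the target region's channels.
    """
    config.validate()
    montage = config.montage()
    times = config.times()
    n_tp = len(times)
    step = 1000.0 / config.sampling_rate
    sigma = config.drift_smooth_ms / step
    n_cat, n_ex = config.n_categories, config.n_exemplars

    templates = np.zeros((n_cat, n_ex, montage.n_channels, n_tp))
    for region, sig in config.region_signals.items():
        idx = montage.region_indices(region)
        if len(idx) == 0 or sig.amplitude == 0:
            continue
        env = _envelope(times, sig.onset_ms, config.stimulus_duration_ms, config.ramp_ms, step)
        rng = np.random.default_rng(
            [config.seed, participant_seed, _STREAM_PATTERN, sig.pattern_seed, int(idx[0])]
        )
        for c in range(n_cat):
            cat_pat = _pattern_timecourse(rng, len(idx), n_tp, config.pattern_drift, sigma)
            for e in range(n_ex):
                ex_pat = _pattern_timecourse(rng, len(idx), n_tp, config.pattern_drift, sigma)
                pat = cat_pat + config.exemplar_scale * ex_pat
                templates[c, e][idx] = sig.amplitude * env[None, :] * pat

    # Directed coupling: lagged, channel-mixed copy of the source's own signal.
    base = templates.copy()
    for k, coup in enumerate(config.couplings):
        if coup.gain == 0:
            continue
        src = montage.region_indices(coup.source)
        tgt = montage.region_indices(coup.target)
        if len(src) == 0 or len(tgt) == 0:
            raise ConfigurationError(
                f"coupling references region with no channels: {coup.source!r}->{coup.target!r}"
            )
        lag = int(round(coup.lag_ms / step))
        rng = np.random.default_rng([config.seed, participant_seed, _STREAM_MIXING, k])
        mixing = rng.standard_normal((len(tgt), len(src))) / np.sqrt(len(src))
        shifted = np.zeros_like(base[:, :, src, :])
        if lag < n_tp:
            shifted[..., lag:] = base[:, :, src, : n_tp - lag]
        templates[:, :, tgt, :] += coup.gain * np.einsum("ts,cesp->cetp", mixing, shifted)
    return templates


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Unit-variance 1/f noise along the last axis."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    pink = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = pink.std()
    return pink / sd if sd > 0 else pink


def simulate_participant(config: GeneratorConfig, participant_seed: int) -> EpochedDataset:
    """One participant's epoched dataset, reproducible from (config.seed, participant_seed)."""
    templates = participant_templates(config, participant_seed)
    montage = config.montage()
    times = config.times()
    n_cat, n_ex, n_ch, n_tp = templates.shape
    n_trials = n_cat * n_ex * config.n_reps

    cats = np.repeat(np.arange(n_cat), n_ex * config.n_reps)
    exs = np.tile(np.repeat(np.arange(n_ex), config.n_reps), n_cat)

    data = templates[cats, exs]  # (n_trials, n_ch, n_tp) view copy
    noise_rng = np.random.default_rng([config.seed, participant_seed, _STREAM_NOISE])
    sd, pf = config.noise.white_sd, config.noise.pink_fraction
    if sd > 0:
        noise = np.sqrt(1.0 - pf) * noise_rng.standard_normal((n_trials, n_ch, n_tp))
        if pf > 0:
            noise += np.sqrt(pf) * _pink_noise(noise_rng, (n_trials, n_ch, n_tp))
        data = data + sd * noise
    else:
        data = data.copy()

    return EpochedDataset(
        data=data,
        times=times,
        categories=cats,
        exemplars=exs,
        montage=montage,
        sampling_rate=config.sampling_rate,
        participant_id=f"p{participant_seed:02d}",
    )


def simulate_cohort(config: GeneratorConfig) -> list[EpochedDataset]:
    """One dataset per participant; participant_seed = participant index."""
    config.validate()
    return [simulate_participant(config, p) for p in range(config.n_participants)]


def simulate_var(
    coefficients: np.ndarray,
    noise_sd: float,
    n_samples: int,
    seed: int,
    burn_in: int = 200,
) -> np.ndarray:
    """Simulate a stationary VAR(p) process; returns channels x samples.

    ``coefficients`` has shape (p, k, k): x_t = sum_l A[l] @ x_{t-1-l} + eps.
    Raises if the companion matrix is unstable (spectral radius >= 1).
    """
    A = np.asarray(coefficients, dtype=float)
    if A.ndim != 3 or A.shape[1] != A.shape[2]:
        raise ValueError("coefficients must have shape (p, k, k)")
    p, k, _ = A.shape
    companion = np.zeros((p * k, p * k))
    companion[:k, :] = A.transpose(1, 0, 2).reshape(k, p * k)
    if p > 1:
        companion[k:, :-k] = np.eye((p - 1) * k)
    radius = float(np.max(np.abs(np.linalg.eigvals(companion)))) if p * k else 0.0
    if radius >= 1.0:
        raise ValueError(f"unstable VAR coefficients: companion spectral radius {radius:.4f} >= 1")

    rng = np.random.default_rng(seed)
    total = n_samples + burn_in
    x = np.zeros((total, k))
    eps = noise_sd * rng.standard_normal((total, k))
    for t in range(total):
        acc = eps[t].copy()
        for l in range(min(p, t)):
            acc += A[l] @ x[t - 1 - l]
        x[t] = acc
    return x[burn_in:].T
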