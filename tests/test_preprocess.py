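import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from vispathways import (
    ChannelMontage,
    ContinuousRecording,
    bandpass,
    detect_bad_channels,
    downsample,
    epoch,
    reject_epochs_threshold,
    rereference_average,
)
from conftest import make_dataset


def _recording(data, fs=1000.0, events=None, regions=None):
    n_ch = data.shape[0]
    montage = ChannelMontage(
        tuple(f"c{i}" for i in range(n_ch)),
        tuple(regions or ["dorsal"] * n_ch),
        ("midline",) * n_ch,
    )
    return ContinuousRecording(data, fs, np.asarray(events or []).reshape(-1, 3), montage)


class TestBandpass:
    def test_dc_removed(self):
        rec = _recording(np.full((2, 5000), 7.0), fs=250.0)
        out = bandpass(rec)
        assert np.abs(out.data[:, 500:-500]).max() < 7e-6

    def test_stopband_and_passband_match_designed_response(self):
        """Measured sinusoid attenuation agrees with the zero-phase filter's
        magnitude response: >= 20 dB at 60 Hz, within 5% of unity at 10 Hz."""
        fs = 250.0
        t = np.arange(60000) / fs
        sos = sps.butter(4, [0.1, 40.0], btype="bandpass", fs=fs, output="sos")
        trim = 15000  # the 0.1-Hz high-pass transient decays over tens of seconds
        for freq, check in ((60.0, "stop"), (10.0, "pass")):
            rec = _recording(np.sin(2 * np.pi * freq * t)[None, :], fs=fs)
            out = bandpass(rec).data[0, trim:-trim]
            gain = out.std() / rec.data[0, trim:-trim].std()
            _, h = sps.sosfreqz(sos, worN=[freq], fs=fs)
            expected = np.abs(h[0]) ** 2  # forward-backward filtering squares |H|
            if check == "stop":
                assert gain < 10 ** (-20 / 20)
                assert gain == pytest.approx(expected, rel=0.5)
            else:
                assert abs(gain - 1) < 0.05
                assert gain == pytest.approx(expected, rel=0.05)

    def test_invalid_cutoffs_rejected(self):
        rec = _recording(np.zeros((1, 1000)), fs=100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(rec, 0.1, 60.0)


class TestDownsample:
    def test_factor_four(self):
        rec = _recording(np.random.default_rng(0).standard_normal((2, 4000)),
                         events=[[1000, 0, 0]])
        out = downsample(rec, 250.0)
        assert out.data.shape == (2, 1000)
        assert out.sampling_rate == 250.0
        assert out.events[0, 0] == 250

    def test_same_rate_is_identity(self):
        rec = _recording(np.ones((1, 100)), fs=250.0)
        out = downsample(rec, 250.0)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_non_integer_factor_rejected(self):
        rec = _recording(np.zeros((1, 100)), fs=1000.0)
        with pytest.raises(ValueError, match="integer"):
            downsample(rec, 300.0)


class TestRereference:
    def test_column_means_zero(self):
        rec = _recording(np.random.default_rng(1).standard_normal((4, 500)), fs=250.0)
        out = rereference_average(rec)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-12

    def test_already_referenced_unchanged(self):
        data = np.vstack([np.sin(np.arange(500) / 10), -np.sin(np.arange(500) / 10)])
        rec = _recording(data, fs=250.0)
        np.testing.assert_allclose(rereference_average(rec).data, data, atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError, match="2 channels"):
            rereference_average(_recording(np.zeros((1, 100)), fs=250.0))


class TestDetectBadChannels:
    def test_flat_channel_flagged(self):
        rng = np.random.default_rng(2)
        common = rng.standard_normal(2000)
        data = np.vstack([common + 0.05 * rng.standard_normal(2000) for _ in range(3)])
        data[1] = 4.2
        rec = _recording(data, fs=250.0)
        assert detect_bad_channels(rec, flat_seconds=5.0) == ["c1"]

    def test_shared_signal_keeps_all(self):
        rng = np.random.default_rng(3)
        common = rng.standard_normal(3000)
        data = np.vstack([common + 0.05 * rng.standard_normal(3000) for _ in range(4)])
        rec = _recording(data, fs=250.0)
        assert detect_bad_channels(rec) == []

    def test_uncorrelated_channel_flagged(self):
        rng = np.random.default_rng(4)
        common = rng.standard_normal(3000)
        data = np.vstack([common + 0.05 * rng.standard_normal(3000) for _ in range(3)])
        data = np.vstack([data, rng.standard_normal(3000)])  # independent channel
        rec = _recording(data, fs=250.0)
        assert detect_bad_channels(rec, corr_threshold=0.8) == ["c3"]


class TestEpoch:
    def _rec_with_events(self, n_events=10, fs=250.0, first=200, spacing=200):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((2, 4000))
        events = [[first + spacing * i, i % 4, i % 5] for i in range(n_events)]
        return _recording(data, fs=fs, events=events)

    def test_shapes_and_grid(self):
        ds = epoch(self._rec_with_events(10))
        assert ds.data.shape == (10, 2, 138)
        assert ds.times[0] == -48.0 and ds.times[-1] == 500.0

    def test_baseline_correction_zeroes_prestim_mean(self):
        ds = epoch(self._rec_with_events(10), baseline_correct=True)
        pre = ds.times < 0
        assert np.abs(ds.data[:, :, pre].mean(axis=2)).max() < 1e-12

    def test_event_near_edge_dropped(self):
        rec = self._rec_with_events(9)
        rec.events = np.vstack([[5, 0, 0], rec.events])
        ds = epoch(rec)
        assert ds.n_trials == 9

    def test_downsample_then_epoch_matches_decimated_epochs(self):
        """Anti-aliased decimation commutes with epoching away from edges."""
        rng = np.random.default_rng(6)
        data = sps.sosfiltfilt(
            sps.butter(4, 40, btype="low", fs=1000.0, output="sos"),
            rng.standard_normal((2, 16000)),
        )
        events = [[4000, 0, 0], [8000, 1, 0]]
        rec = _recording(data, fs=1000.0, events=events)
        a = epoch(downsample(rec, 250.0), baseline_correct=False)
        b = epoch(rec, window_ms=(-48.0, 500.0), baseline_correct=False)
        b_dec = sps.decimate(b.data, 4, axis=2, ftype="fir", zero_phase=True)
        # compare away from filter edge effects
        np.testing.assert_allclose(a.data[:, :, 5:-5], b_dec[:, :, 5:-5], atol=0.02)


class TestRejectEpochs:
    def _dataset(self):
        rng = np.random.default_rng(7)
        data = rng.standard_normal((8, 2, 20))
        return make_dataset(data, ["dorsal", "dorsal"],
                            categories=np.arange(8) % 4, exemplars=np.arange(8) % 5)

    def test_no_exceedance_is_identity(self):
        ds = self._dataset()
        out = reject_epochs_threshold(ds, abs_threshold=100.0)
        assert out.n_trials == ds.n_trials

    def test_spiked_trial_removed_and_labels_aligned(self):
        rng = np.random.default_rng(8)
        ds = self._dataset()
        spiked = sorted(rng.choice(8, size=3, replace=False))
        for i in spiked:
            ds.data[i, 0, 5] = 1000.0
        out = reject_epochs_threshold(ds, abs_threshold=100.0)
        keep = [i for i in range(8) if i not in spiked]
        np.testing.assert_array_equal(out.categories, ds.categories[keep])
        np.testing.assert_array_equal(out.exemplars, ds.exemplars[keep])

    def test_all_rejected_raises(self):
        ds = self._dataset()
        with pytest.raises(ValueError, match="all trials rejected"):
            reject_epochs_threshold(ds, abs_threshold=1e-9)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.sets(st.integers(min_value=0, max_value=11), max_size=11))
    def test_any_spike_pattern_keeps_labels_aligned(self, spiked):
        """Rejection preserves trial-label alignment for every spike pattern."""
        rng = np.random.default_rng(12)
        data = rng.standard_normal((12, 2, 15))
        ds = make_dataset(data, ["dorsal", "dorsal"],
                          categories=np.arange(12) % 4, exemplars=np.arange(12) % 5)
        for i in spiked:
            ds.data[i, 1, 3] = 500.0
        out = reject_epochs_threshold(ds, abs_threshold=100.0)
        keep = [i for i in range(12) if i not in spiked]
        assert out.n_trials == len(keep)
        np.testing.assert_array_equal(out.categories, ds.categories[keep])
        np.testing.assert_array_equal(out.exemplars, ds.exemplars[keep])
        np.testing.assert_array_equal(out.data, ds.data[keep])
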