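import numpy as np
import pytest

from eegpref import (EventMarker, Montage, RawRecording, bandpass, downsample,
                     extract_epochs, rereference, run_preprocessing,
                     segment_epochs, welch_psd)
from eegpref.errors import MarkerError, ParameterError
from eegpref.features import band_integral

from conftest import single_channel_recording


class TestRereference:
    def test_zero_mean_references_leave_data_unchanged(self, montage):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((22, 200))
        i9, i10 = montage.index("TP9"), montage.index("TP10")
        data[i10] = -data[i9]  # reference mean identically zero
        rec = RawRecording(data=data.copy(), fs=500.0, montage=montage)
        out = rereference(rec)
        np.testing.assert_allclose(out.data, data, atol=1e-12)

    def test_common_mode_is_removed(self, montage):
        rec = RawRecording(data=np.full((22, 50), 5.0), fs=500.0, montage=montage)
        out = rereference(rec)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_single_reference_arithmetic(self):
        m = Montage(channel_names=("C3", "TP9"), regions={})
        rec = RawRecording(data=np.array([[1.0, 2.0], [3.0, 4.0]]), fs=100.0,
                           montage=m)
        out = rereference(rec, refs=("TP9",))
        np.testing.assert_allclose(out.data[1], 0.0)
        np.testing.assert_allclose(out.data[0], [-2.0, -2.0])

    def test_missing_reference_label(self, montage):
        rec = RawRecording(data=np.zeros((22, 10)), fs=500.0, montage=montage)
        with pytest.raises(ParameterError):
            rereference(rec, refs=("A1",))

    def test_idempotent_after_first_pass(self, montage):
        rng = np.random.default_rng(1)
        rec = RawRecording(data=rng.standard_normal((22, 100)), fs=500.0,
                           montage=montage)
        once = rereference(rec)
        twice = rereference(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)


class TestBandpass:
    def test_passband_tone_preserved(self):
        t = np.arange(5000) / 500.0
        rec = single_channel_recording(np.sin(2 * np.pi * 10 * t), 500.0)
        out = bandpass(rec)
        mid = slice(500, 4500)  # avoid edge transients
        rms_ratio = np.std(out.data[0, mid]) / np.std(rec.data[0, mid])
        assert rms_ratio == pytest.approx(1.0, abs=0.02)

    def test_stopband_tone_attenuated(self):
        t = np.arange(5000) / 500.0
        rec = single_channel_recording(np.sin(2 * np.pi * 60 * t), 500.0)
        out = bandpass(rec)
        mid = slice(500, 4500)  # avoid edge transients
        assert np.std(out.data[0, mid]) < 0.1 * np.std(rec.data[0, mid])

    def test_zero_in_zero_out(self):
        rec = single_channel_recording(np.zeros(1000), 500.0)
        np.testing.assert_allclose(bandpass(rec).data, 0.0, atol=1e-12)

    def test_edge_above_nyquist_rejected(self):
        rec = single_channel_recording(np.zeros(1000), 500.0)
        with pytest.raises(ParameterError):
            bandpass(rec, hi=250.0)


class TestExtractEpochs:
    def test_one_epoch_per_run_with_labels(self, small_dataset):
        cfg, recordings, truth = small_dataset
        epochs = extract_epochs(recordings)
        assert epochs.n_epochs == len(recordings)
        assert epochs.epochs.shape == (24, 22, 4000)  # 8 s at 500 Hz
        np.testing.assert_array_equal(epochs.labels, truth["label"].to_numpy())
        assert epochs.meta[0] == ("sub01", "run01")

    def test_missing_stimulus_marker_names_run(self, montage):
        rec = RawRecording(data=np.zeros((22, 5500)), fs=500.0, montage=montage,
                           markers=[EventMarker(1500, "response_like")],
                           subject_id="s9", run_id="r7")
        with pytest.raises(MarkerError, match="s9/r7"):
            extract_epochs([rec])

    def test_duplicate_response_marker_rejected(self, montage):
        rec = RawRecording(data=np.zeros((22, 5500)), fs=500.0, montage=montage,
                           markers=[EventMarker(1000, "stimulus_on"),
                                    EventMarker(1500, "response_like"),
                                    EventMarker(1600, "response_like")])
        with pytest.raises(MarkerError):
            extract_epochs([rec])


class TestDownsample:
    def test_epoch_sample_count(self, small_dataset):
        _, recordings, _ = small_dataset
        epochs = extract_epochs(recordings)
        down = downsample(epochs, 256.0)
        assert down.epochs.shape[-1] == 2048  # 8 s at 256 Hz
        assert down.fs == 256.0

    def test_tone_band_power_preserved(self):
        t = np.arange(4000) / 500.0
        rec = single_channel_recording(np.sin(2 * np.pi * 10 * t), 500.0)
        down = downsample(rec, 256.0)
        p_before = band_integral(welch_psd(rec.data[0], 500.0, win_sec=2.0), 8, 12)
        p_after = band_integral(welch_psd(down.data[0], 256.0, win_sec=2.0), 8, 12)
        assert p_after == pytest.approx(p_before, rel=0.03)

    def test_constant_signal_unchanged(self):
        rec = single_channel_recording(np.full(1000, 3.5), 500.0)
        # constant up to the resampler's sub-0.1% passband ripple
        np.testing.assert_allclose(downsample(rec, 256.0).data, 3.5, atol=0.005)

    def test_target_above_fs_rejected(self):
        rec = single_channel_recording(np.zeros(1000), 500.0)
        with pytest.raises(ParameterError):
            downsample(rec, 500.0)


class TestSegmentEpochs:
    def test_six_segments_of_341_samples(self, small_dataset):
        _, recordings, _ = small_dataset
        epochs = downsample(extract_epochs(recordings), 256.0)
        segments = segment_epochs(epochs, 6)
        assert segments.segments.shape == (24 * 6, 22, 341)  # floor(2048/6)

    def test_single_segment_is_identity(self, small_dataset):
        _, recordings, _ = small_dataset
        epochs = extract_epochs(recordings)
        segments = segment_epochs(epochs, 1)
        np.testing.assert_array_equal(segments.segments, epochs.epochs)

    def test_labels_partition_exactly(self, small_segments, small_dataset):
        _, _, truth = small_dataset
        n_like_epochs = int(truth["label"].sum())
        assert int(small_segments.labels.sum()) == 6 * n_like_epochs
        assert small_segments.n_segments == 6 * len(truth)

    def test_segment_content_matches_epoch_slices(self, small_dataset):
        _, recordings, _ = small_dataset
        epochs = extract_epochs(recordings[:2])
        segments = segment_epochs(epochs, 6)
        seg_len = epochs.epochs.shape[-1] // 6
        np.testing.assert_array_equal(
            segments.segments[1], epochs.epochs[0, :, seg_len:2 * seg_len])
        assert segments.meta[1] == (*epochs.meta[0], 1)


def test_full_chain_equals_staged_calls(small_dataset):
    """run_preprocessing applies exactly re-reference -> bandpass ->
    epoch -> downsample -> segment, in that order."""
    _, recordings, _ = small_dataset
    chained = run_preprocessing(recordings[:4])
    manual = segment_epochs(
        downsample(extract_epochs(
            [bandpass(rereference(r)) for r in recordings[:4]]), 256.0), 6)
    np.testing.assert_allclose(chained.segments, manual.segments, atol=1e-9)
    np.testing.assert_array_equal(chained.labels, manual.labels)


def test_stages_are_skippable_not_reorderable(small_dataset):
    _, recordings, _ = small_dataset
    segs = run_preprocessing(recordings[:2], refs=None, band=None, target_fs=None)
    assert segs.fs == 500.0
    assert segs.segments.shape[-1] == 4000 // 6
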