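"""Welch band power, feature layout, time-frequency maps, EMG envelope."""

import numpy as np
import pytest

from erdswitch.features_spectral import (
    _welch_segmenting,
    emg_power_summary,
    extract_features,
    tf_map,
    welch_psd,
)
from erdswitch.io_epochs import EpochSet
from erdswitch.session_model import Condition, DEFAULT_EEG_CHANNELS, MOTOR_CHANNELS
from erdswitch.synthetic_data import RawRecording

from conftest import FS


class TestWelchPsd:
    def test_five_bins_with_inclusive_endpoints(self):
        t = np.arange(int(2 * FS)) / FS
        f, p = welch_psd(np.sin(2 * np.pi * 10 * t), FS)
        assert f.tolist() == [8.0, 12.0, 16.0, 20.0, 24.0]

    def test_pure_tone_peaks_at_its_bin_with_hann_leakage(self):
        t = np.arange(int(3 * FS)) / FS
        f, p = welch_psd(np.sin(2 * np.pi * 12 * t), FS)
        assert f[np.argmax(p)] == 12.0
        # Hann taper leaks exactly 1/4 of the peak power into the adjacent
        # 4 Hz bins; bins further out are orders of magnitude below
        peak = p[f == 12.0][0]
        assert p[f == 8.0][0] == pytest.approx(peak / 4, rel=0.05)
        assert p[f == 16.0][0] == pytest.approx(peak / 4, rel=0.05)
        assert p[f == 24.0][0] < peak / 1e6

    @pytest.mark.parametrize("fs", [2500.0, 500.0])
    def test_three_second_segment_averages_23_windows(self, fs):
        nperseg, noverlap = _welch_segmenting(fs, 0.25, 0.5)
        n = int(3 * fs)
        n_windows = (n - noverlap) // (nperseg - noverlap)
        assert n_windows == 23

    def test_segment_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            welch_psd(np.zeros(50), FS)

    def test_white_noise_band_is_flat(self, rng):
        # PSD scaling sanity: >=100 averaged windows flatten the band
        x = rng.standard_normal(int(60 * FS))
        f, p = welch_psd(x, FS)
        assert np.abs(p / p.mean() - 1).max() < 0.10


def _labeled_epochs(rng, n_trials=8, channels=DEFAULT_EEG_CHANNELS):
    n = int(7 * FS)
    labels = [
        Condition("attempted", 2) if i < n_trials // 2 else Condition("none", 2)
        for i in range(n_trials)
    ]
    return EpochSet(
        data=rng.standard_normal((n_trials, len(channels), n)),
        times=-1.0 + np.arange(n) / FS,
        labels=labels,
        sample_rate_hz=FS,
        channel_labels=tuple(channels),
    )


class TestExtractFeatures:
    def test_feature_counts_per_channel_set(self, rng):
        epochs = _labeled_epochs(rng)
        assert extract_features(epochs, MOTOR_CHANNELS).values.shape == (8, 90)
        assert extract_features(epochs).values.shape == (8, 300)

    def test_column_order_is_channel_frequency_window(self, rng):
        fm = extract_features(_labeled_epochs(rng), channels=("C3", "C4"))
        meta = fm.meta
        assert meta.iloc[0].tolist() == ["C3", 8.0, "ERD"]
        assert meta.iloc[1].tolist() == ["C3", 8.0, "ERS"]
        assert meta.iloc[2].tolist() == ["C3", 12.0, "ERD"]
        assert meta.iloc[10].tolist() == ["C4", 8.0, "ERD"]

    def test_unknown_channel_named(self, rng):
        with pytest.raises(ValueError, match="Qz"):
            extract_features(_labeled_epochs(rng), channels=("C3", "Qz"))

    def test_trial_permutation_equivariance(self, rng):
        epochs = _labeled_epochs(rng)
        fm = extract_features(epochs, MOTOR_CHANNELS)
        perm = rng.permutation(epochs.n_trials)
        permuted = EpochSet(
            data=epochs.data[perm],
            times=epochs.times,
            labels=[epochs.labels[i] for i in perm],
            sample_rate_hz=FS,
            channel_labels=epochs.channel_labels,
        )
        fm_perm = extract_features(permuted, MOTOR_CHANNELS)
        assert np.allclose(fm.values[perm], fm_perm.values)

    def test_amplitude_doubling_quadruples_power(self, rng):
        epochs = _labeled_epochs(rng, n_trials=4)
        doubled = EpochSet(
            data=2.0 * epochs.data,
            times=epochs.times,
            labels=epochs.labels,
            sample_rate_hz=FS,
            channel_labels=epochs.channel_labels,
        )
        a = extract_features(epochs, ("C3",), log_power=False).values
        b = extract_features(doubled, ("C3",), log_power=False).values
        assert np.allclose(b, 4.0 * a, rtol=1e-10)
        # tf_map is in relative units: unchanged under rescaling
        ta = tf_map(epochs, "attempted").values
        tb = tf_map(doubled, "attempted").values
        assert np.allclose(ta, tb, rtol=1e-10)

    def test_tsv_export_has_column_names(self, rng, tmp_path):
        fm = extract_features(_labeled_epochs(rng, 4), ("C3",))
        fm.to_tsv(tmp_path / "features.tsv")
        header = (tmp_path / "features.tsv").read_text().splitlines()[0]
        assert "C3_8Hz_ERD" in header and "C3_24Hz_ERS" in header


class TestTfMap:
    def test_stationary_noise_maps_to_one(self, rng):
        epochs = _labeled_epochs(rng, n_trials=50, channels=("C3", "C4"))
        tm = tf_map(epochs, "attempted")
        # single cells fluctuate with sd ~ 1/sqrt(n_trials); the map must be
        # unstructured around 1, not each of the ~1100 cells individually
        dev = np.abs(tm.values - 1)
        assert dev.mean() < 0.2
        assert tm.values.mean() == pytest.approx(1.0, abs=0.02)

    def test_baseline_mean_is_exactly_one(self, rng):
        tm = tf_map(_labeled_epochs(rng, 6, channels=("C3",)), "none")
        assert np.abs(tm.values.mean(axis=-1) - 1).max() < 1e-9

    def test_missing_condition_raises(self, rng):
        epochs = _labeled_epochs(rng, 4)
        with pytest.raises(ValueError, match="imagined"):
            tf_map(epochs, "imagined")


class TestEmgSummary:
    def test_sinusoid_envelope_recovers_amplitude(self):
        # 50 Hz tone of amplitude A on the bipolar pair -> mean envelope ~ A
        fs = FS
        n = int(20 * fs)
        t = np.arange(n) / fs
        A = 3.0
        data = np.zeros((3, n))
        data[1] = A * np.sin(2 * np.pi * 50 * t)
        rec = RawRecording(data, fs, ("C3", "EMG1", "EMG2"), ("EEG", "EMG", "EMG"))
        from erdswitch.session_model import build_sequence, SessionPlan

        plan = SessionPlan(
            phase=1,
            events=build_sequence(Condition("actual", 1), 2, t0=2.0),
            sample_rate_hz=fs,
        )
        out = emg_power_summary(rec, plan, stat="magnitude")
        assert out["actual"] == pytest.approx(100.0, abs=1e-9)
        # inspect the raw per-trial envelope through a 1-trial reference
        from scipy.signal import butter, hilbert, sosfiltfilt

        sos = butter(4, 10, btype="highpass", fs=fs, output="sos")
        env = np.abs(hilbert(sosfiltfilt(sos, data[1] - data[2])))
        sl = slice(int(2.1 * fs), int(5.5 * fs))
        assert env[sl].mean() == pytest.approx(A, rel=0.01)

    def test_missing_reference_condition_errors(self, rng):
        fs = FS
        rec = RawRecording(
            rng.standard_normal((3, int(20 * fs))), fs,
            ("C3", "EMG1", "EMG2"), ("EEG", "EMG", "EMG"),
        )
        from erdswitch.session_model import build_sequence, SessionPlan

        plan = SessionPlan(
            phase=1,
            events=build_sequence(Condition("none", 1), 2, t0=2.0),
            sample_rate_hz=fs,
        )
        with pytest.raises(ValueError, match="actual"):
            emg_power_summary(rec, plan)

    def test_wrong_emg_channel_count_rejected(self, rng):
        rec = RawRecording(
            rng.standard_normal((2, 100)), FS, ("C3", "EMG1"), ("EEG", "EMG")
        )
        with pytest.raises(ValueError, match="EMG"):
            emg_power_summary(rec, [], conditions=[])
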