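"""Pulse segmentation, beat features, and surrogate resampling."""
import numpy as np
import pytest
from scipy.signal import periodogram

from respyre import (ArtifactSpec, ConfigError, InsufficientDataError,
                     SyntheticConfig, WaveformSignal, beat_feature_series,
                     extract_filter_based, generate_ppg, highpass_vlf,
                     inject_artifact, lowpass_ppg, resample_feature_series,
                     segment_pulses_ims)
from respyre.extract import FeatureSeries

from conftest import dominant_frequency


class TestSegmentPulses:
    def test_clean_beat_count(self):
        sig, _ = generate_ppg(SyntheticConfig(duration_s=60.0, heart_rate=60.0,
                                              resp_rate=15.0, bw_depth=0.0,
                                              am_depth=0.0, fm_depth=0.0, seed=1))
        beats = segment_pulses_ims(lowpass_ppg(sig))
        assert abs(beats.n_beats - 60) <= 1

    def test_flat_signal_empty(self):
        beats = segment_pulses_ims(WaveformSignal(np.zeros(2000), 125.0))
        assert beats.n_beats == 0

    def test_spike_beat_flagged(self, noisy_filtered_ppg):
        filtered, _ = noisy_filtered_ppg
        spiked = inject_artifact(filtered, ArtifactSpec("spike", 10.0, 0.5,
                                                        magnitude=10.0))
        beats = segment_pulses_ims(spiked)
        flagged_times = beats.peak_times[beats.artifact_flag.astype(bool)]
        assert any(9.0 <= t <= 11.5 for t in flagged_times)

    def test_noise_robust_beat_count(self):
        counts = []
        for noise in (0.0, 0.05):
            sig, _ = generate_ppg(SyntheticConfig(duration_s=60.0, heart_rate=75.0,
                                                  resp_rate=15.0, noise_sd=noise,
                                                  seed=9))
            counts.append(segment_pulses_ims(highpass_vlf(lowpass_ppg(sig))).n_beats)
        assert abs(counts[1] - counts[0]) <= 0.02 * counts[0] + 1

    def test_landmark_ordering(self, noisy_filtered_ppg):
        filtered, _ = noisy_filtered_ppg
        beats = segment_pulses_ims(filtered)
        assert np.all(np.diff(beats.peak_idx) > 0)
        assert np.all(beats.trough_idx <= beats.fiducial_idx)
        assert np.all(beats.fiducial_idx <= beats.peak_idx)


class TestBeatFeatures:
    def test_unmodulated_amplitude_constant(self):
        sig, _ = generate_ppg(SyntheticConfig(duration_s=60.0, heart_rate=60.0,
                                              resp_rate=15.0, bw_depth=0.0,
                                              am_depth=0.0, fm_depth=0.0, seed=2))
        beats = segment_pulses_ims(lowpass_ppg(sig))
        series = beat_feature_series(beats, "peak_amplitude")
        assert series.values.std() / series.values.mean() < 0.02

    @pytest.mark.parametrize("kind", ["am", "fm", "bw"])
    def test_modulation_dominant_frequency(self, kind, noisy_filtered_ppg):
        filtered, _ = noisy_filtered_ppg
        beats = segment_pulses_ims(filtered)
        surrogate = resample_feature_series(beat_feature_series(beats, kind),
                                            "linear")
        freq, df = dominant_frequency(surrogate.samples, surrogate.sampling_rate)
        assert abs(freq - 0.25) <= df

    def test_matching_modality_has_sharpest_peak(self):
        """With a single modulation active, the matching feature series
        concentrates the most spectral power at the respiratory frequency."""
        def concentration(series):
            surr = resample_feature_series(series, "linear")
            x = surr.samples - surr.samples.mean()
            freqs, power = periodogram(x, fs=surr.sampling_rate)
            df = freqs[1] - freqs[0]
            near = np.abs(freqs - 0.25) <= 1.5 * df
            return power[near].sum() / power.sum()

        for active in ("am", "fm", "bw"):
            kwargs = dict(bw_depth=0.0, am_depth=0.0, fm_depth=0.0, noise_sd=0.02)
            kwargs[f"{active}_depth"] = 0.1
            sig, _ = generate_ppg(SyntheticConfig(duration_s=120.0, heart_rate=75.0,
                                                  resp_rate=15.0, seed=7, **kwargs))
            beats = segment_pulses_ims(highpass_vlf(lowpass_ppg(sig)))
            scores = {k: concentration(beat_feature_series(beats, k))
                      for k in ("am", "fm", "bw")}
            assert max(scores, key=scores.get) == active, scores

    def test_too_few_beats_rejected(self):
        beats = segment_pulses_ims(WaveformSignal(np.zeros(2000), 125.0))
        with pytest.raises(InsufficientDataError):
            beat_feature_series(beats, "am")

    def test_unknown_kind_rejected(self, noisy_filtered_ppg):
        filtered, _ = noisy_filtered_ppg
        with pytest.raises(ConfigError):
            beat_feature_series(segment_pulses_ims(filtered), "wavelet")


class TestResampleFeatureSeries:
    def test_linear_two_points(self):
        series = FeatureSeries(np.array([0.0, 1.0]), np.array([0.0, 2.0]), "am")
        out = resample_feature_series(series, "linear", 4.0, bandpass=False)
        assert np.allclose(out.samples, [0.0, 0.5, 1.0, 1.5, 2.0])

    def test_spline_passes_through_knots(self):
        times = np.linspace(0.0, 10.0, 12)
        values = np.sin(times)
        series = FeatureSeries(times, values, "am")
        out = resample_feature_series(series, "cubic_spline", 1.1, bandpass=False)
        # output grid hits t=0 exactly; value must equal the knot
        assert out.samples[0] == pytest.approx(values[0], abs=1e-12)

    @pytest.mark.parametrize("method", ["linear", "cubic_spline", "berger"])
    def test_sinusoidal_series_dominant_frequency(self, method):
        # FM-modulated event train: intervals (and hence the Berger rate)
        # oscillate at 0.25 Hz
        times = [0.0]
        while times[-1] < 120.0:
            times.append(times[-1] + 0.8 * (1 + 0.1 * np.sin(2 * np.pi * 0.25 * times[-1])))
        times = np.array(times)
        series = FeatureSeries(0.5 * (times[1:] + times[:-1]), np.diff(times), "fm")
        out = resample_feature_series(series, method, 4.0)
        freq, df = dominant_frequency(out.samples, out.sampling_rate)
        assert abs(freq - 0.25) <= df

    def test_linear_and_spline_agree_on_smooth_series(self):
        rng = np.random.default_rng(3)
        times = np.cumsum(0.8 + 0.05 * rng.normal(size=150))  # beat-like spacing
        values = np.sin(2 * np.pi * 0.1 * times)
        series = FeatureSeries(times, values, "am")
        lin = resample_feature_series(series, "linear", 4.0, bandpass=False)
        spl = resample_feature_series(series, "cubic_spline", 4.0, bandpass=False)
        rms_diff = np.sqrt(np.mean((lin.samples - spl.samples) ** 2))
        rms = np.sqrt(np.mean(lin.samples ** 2))
        assert rms_diff / rms < 0.05

    def test_unknown_method_rejected(self):
        series = FeatureSeries(np.array([0.0, 1.0]), np.array([0.0, 1.0]), "am")
        with pytest.raises(ConfigError):
            resample_feature_series(series, "sinc", 4.0)

    def test_single_point_rejected(self):
        series = FeatureSeries(np.array([0.0]), np.array([1.0]), "am")
        with pytest.raises(InsufficientDataError):
            resample_feature_series(series, "linear", 4.0)


class TestFilterBased:
    def test_bw_modulated_dominant_frequency(self):
        sig, _ = generate_ppg(SyntheticConfig(duration_s=120.0, resp_rate=12.0,
                                              bw_depth=0.2, am_depth=0.0,
                                              fm_depth=0.0, seed=3))
        out = extract_filter_based(sig)
        freq, df = dominant_frequency(out.samples, out.sampling_rate)
        assert abs(freq - 0.2) <= df

    def test_zero_in_zero_out(self):
        out = extract_filter_based(WaveformSignal(np.zeros(60 * 125), 125.0))
        assert np.allclose(out.samples, 0.0)

    def test_unmodulated_has_little_respiratory_power(self):
        def band_power(sig):
            out = extract_filter_based(sig)
            freqs, power = periodogram(out.samples, fs=out.sampling_rate)
            df = freqs[1] - freqs[0]
            return power[np.abs(freqs - 0.2) <= 1.5 * df].sum()

        modulated, _ = generate_ppg(SyntheticConfig(duration_s=120.0, resp_rate=12.0,
                                                    bw_depth=0.2, am_depth=0.0,
                                                    fm_depth=0.0, seed=3))
        flat, _ = generate_ppg(SyntheticConfig(duration_s=120.0, resp_rate=12.0,
                                               bw_depth=0.0, am_depth=0.0,
                                               fm_depth=0.0, seed=3))
        assert band_power(flat) < 0.1 * band_power(modulated)
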