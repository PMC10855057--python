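"""Windowed RR estimators and the fusion rules."""
import numpy as np
import pytest

from respyre import (ConfigError, InsufficientDataError, RespiratorySignal,
                     RrEstimate, SpectrumEstimate, WaveformSignal, rr_spectral,
                     rr_trough_peak, rr_zero_crossing, smart_fusion,
                     spectral_peak_conditioned_average, temporal_fusion,
                     welch_spectrum)


def _sinusoid(freq, fs=4.0, duration=60.0, noise=0.0, seed=0, phase=-0.1):
    # phase -0.1: upward zero crossings fall just after each multiple of
    # the period, so all of them lie inside the sampled window
    t = np.arange(int(duration * fs)) / fs
    x = np.sin(2 * np.pi * freq * t + phase)
    if noise:
        x = x + noise * np.random.default_rng(seed).normal(size=t.size)
    return WaveformSignal(x, fs)


def _estimate(value, valid=True, window=(0.0, 60.0), method="spectral"):
    return RrEstimate(value=value if valid else None, window=window,
                      method=method, valid=valid)


class TestZeroCrossing:
    @pytest.mark.parametrize("freq,expected", [(0.25, 15.0), (8.0 / 60.0, 8.0)])
    def test_sinusoid_rate(self, freq, expected):
        est = rr_zero_crossing(_sinusoid(freq))
        assert est.valid and est.value == pytest.approx(expected, abs=1e-9)

    def test_zero_signal_invalid(self):
        est = rr_zero_crossing(WaveformSignal(np.zeros(240), 4.0))
        assert not est.valid and est.value is None

    def test_window_outside_signal(self):
        with pytest.raises(ConfigError):
            rr_zero_crossing(_sinusoid(0.25), (50.0, 120.0))


class TestTroughPeak:
    def test_sinusoid_rate(self):
        est = rr_trough_peak(_sinusoid(0.2))
        assert est.valid and est.value == pytest.approx(12.0)

    def test_noisy_sinusoid(self):
        est = rr_trough_peak(_sinusoid(0.25, noise=0.05, seed=4))
        assert est.valid and abs(est.value - 15.0) <= 1.0

    def test_monotone_ramp_invalid(self):
        est = rr_trough_peak(WaveformSignal(np.linspace(0, 1, 240), 4.0))
        assert not est.valid


class TestSpectral:
    def test_sinusoid_rate(self):
        est = rr_spectral(_sinusoid(0.3))
        assert est.valid and abs(est.value - 18.0) <= 0.5

    def test_larger_peak_wins(self):
        t = np.arange(240) / 4.0
        x = np.sin(2 * np.pi * 0.2 * t) + 0.3 * np.sin(2 * np.pi * 0.4 * t)
        est = rr_spectral(WaveformSignal(x, 4.0))
        assert est.valid and abs(est.value - 12.0) <= 0.5

    def test_noise_flagged_low_confidence(self):
        x = np.random.default_rng(0).normal(size=240)
        est = rr_spectral(WaveformSignal(x, 4.0))
        assert est.diagnostics["low_confidence"]
        # a clean sinusoid is not flagged
        assert not rr_spectral(_sinusoid(0.25)).diagnostics["low_confidence"]

    def test_short_window_flagged_low_resolution(self):
        est = rr_spectral(_sinusoid(0.25, duration=10.0))
        assert est.diagnostics["low_resolution"]


def test_estimators_agree_on_clean_sinusoids():
    for freq in (0.15, 0.25, 0.4):
        expected = freq * 60.0
        values = [rr_zero_crossing(_sinusoid(freq)).value,
                  rr_trough_peak(_sinusoid(freq)).value,
                  rr_spectral(_sinusoid(freq)).value]
        assert all(abs(v - expected) <= 1.0 for v in values), (freq, values)


class TestSmartFusion:
    def test_agreeing_inputs_fused(self):
        fused = smart_fusion([_estimate(10.0), _estimate(11.0), _estimate(12.0)])
        assert fused.valid and fused.value == pytest.approx(11.0)

    def test_disagreeing_inputs_abstain(self):
        fused = smart_fusion([_estimate(5.0), _estimate(15.0), _estimate(25.0)])
        assert not fused.valid and fused.value is None

    def test_identical_inputs(self):
        fused = smart_fusion([_estimate(14.0)] * 3)
        assert fused.valid and fused.value == pytest.approx(14.0)

    def test_invalid_input_propagates(self):
        fused = smart_fusion([_estimate(10.0), _estimate(None, valid=False),
                              _estimate(12.0)])
        assert not fused.valid

    def test_wrong_arity_rejected(self):
        with pytest.raises(ConfigError):
            smart_fusion([_estimate(10.0), _estimate(11.0)])

    def test_fused_value_within_input_range(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            vals = rng.uniform(4, 60, size=3)
            fused = smart_fusion([_estimate(v) for v in vals])
            if fused.valid:
                assert vals.min() - 1e-12 <= fused.value <= vals.max() + 1e-12


def _spectrum(peak_freq, width=0.01, flat=False):
    freqs = np.linspace(0.0, 2.0, 401)
    if flat:
        power = np.ones_like(freqs)
    else:
        power = np.exp(-0.5 * ((freqs - peak_freq) / width) ** 2) + 1e-6
    return SpectrumEstimate(frequencies=freqs, power=power)


class TestPeakConditionedAverage:
    def test_identical_peaks(self):
        est = spectral_peak_conditioned_average([_spectrum(0.25)] * 3)
        assert est.valid and est.value == pytest.approx(15.0, abs=0.5)

    def test_flat_spectrum_excluded(self):
        est = spectral_peak_conditioned_average(
            [_spectrum(0.25), _spectrum(0.25), _spectrum(0.0, flat=True)])
        assert est.valid and est.value == pytest.approx(15.0, abs=0.5)
        assert est.diagnostics["included"] == 2

    def test_all_flat_abstains(self):
        est = spectral_peak_conditioned_average([_spectrum(0.0, flat=True)] * 3)
        assert not est.valid

    def test_mismatched_grids_rejected(self):
        a = _spectrum(0.25)
        b = SpectrumEstimate(frequencies=a.frequencies * 1.001, power=a.power)
        with pytest.raises(ConfigError):
            spectral_peak_conditioned_average([a, b])


class TestTemporalFusion:
    def test_median_of_three(self):
        est = temporal_fusion([_estimate(15.0), _estimate(16.0), _estimate(14.0)])
        assert est.value == pytest.approx(15.0)

    def test_single_estimate(self):
        assert temporal_fusion([_estimate(15.0)]).value == pytest.approx(15.0)

    def test_invalid_entries_skipped(self):
        est = temporal_fusion([_estimate(15.0), _estimate(None, valid=False),
                               _estimate(17.0)])
        assert est.value == pytest.approx(16.0)

    def test_no_valid_history_abstains(self):
        est = temporal_fusion([_estimate(None, valid=False)])
        assert not est.valid

    def test_empty_history_rejected(self):
        with pytest.raises(InsufficientDataError):
            temporal_fusion([])


def test_welch_spectrum_properties():
    spec = welch_spectrum(_sinusoid(0.25))
    assert np.all(np.diff(spec.frequencies) > 0)
    assert np.all(spec.power >= 0)
    # grid at most 0.5 breaths/min
    assert spec.frequencies[1] - spec.frequencies[0] <= 0.5 / 60.0 + 1e-12
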