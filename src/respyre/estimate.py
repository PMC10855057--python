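"""Windowed respiratory-rate estimation and fusion.

Given a uniformly sampled respiratory surrogate, RR (breaths/min) is
estimated per window by time-domain breath detection (positive-gradient
zero crossings, or combined trough-and-peak detection) or by spectral
analysis (frequency of the largest Welch-periodogram peak between 4 and
60 breaths/min).  Estimates from the three modulation routes (BW, AM, FM)
can then be fused:

* **smart fusion** - mean of the three RR values if their standard
  deviation is below 4 breaths/min, otherwise no RR is produced;
* **spectral peak-conditioned averaging** - average of the Welch spectra
  whose power is concentrated around their own maximum, RR taken from the
  mean spectrum;
* **temporal fusion** - trailing median over a subject's recent valid
  estimates.

An estimate is *valid* only when it lies in the plausible 4-60
breaths/min band; fusion may abstain, which is reported as an invalid
estimate, never silently dropped.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .core import ConfigError, InsufficientDataError, WaveformSignal

__all__ = [
    "RrEstimate",
    "SpectrumEstimate",
    "rr_zero_crossing",
    "rr_trough_peak",
    "rr_spectral",
    "welch_spectrum",
    "smart_fusion",
    "spectral_peak_conditioned_average",
    "temporal_fusion",
    "RR_BAND_BPM",
]

RR_BAND_BPM = (4.0, 60.0)
SMART_FUSION_SD_BPM = 4.0
WELCH_MAX_SEGMENT_S = 32.0
WELCH_GRID_BPM = 0.5
FLATNESS_THRESHOLD = 0.4


@dataclass
class RrEstimate:
    """One windowed RR value in breaths/min.

    ``valid`` is False when the method abstained or the value fell outside
    the plausible band; ``value`` is then None.
    """

    value: float | None
    window: tuple[float, float]
    method: str
    valid: bool
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.valid and self.value is None:
            raise ConfigError("valid estimate requires a value")
        if not self.valid:
            self.value = None


@dataclass
class SpectrumEstimate:
    """A Welch power spectrum of one respiratory surrogate window."""

    frequencies: np.ndarray
    power: np.ndarray
    method: str = "welch"
    window: tuple[float, float] = (0.0, 0.0)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise ConfigError("frequencies and power must align")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ConfigError("frequencies must be increasing")
        if np.any(self.power < 0):
            raise ConfigError("power must be nonnegative")


def _window_samples(resp: WaveformSignal,
                    window: tuple[float, float] | None) -> tuple[np.ndarray, tuple[float, float]]:
    if window is None:
        return resp.samples, (resp.t0, resp.t0 + resp.duration)
    sub = resp.slice_seconds(*window)
    return sub.samples, (float(window[0]), float(window[1]))


def _bounded(value: float, window: tuple[float, float], method: str,
             diagnostics: dict | None = None) -> RrEstimate:
    valid = RR_BAND_BPM[0] <= value <= RR_BAND_BPM[1]
    return RrEstimate(value=value if valid else None, window=window,
                      method=method, valid=valid,
                      diagnostics=diagnostics or {})


def rr_zero_crossing(resp: WaveformSignal,
                     window: tuple[float, float] | None = None) -> RrEstimate:
    """RR from positive-gradient zero crossings.

    Counts samples where the (de-meaned) signal crosses from non-positive
    to positive; RR = 60 * crossings / window duration.
    """
    x, win = _window_samples(resp, window)
    if x.size < 2:
        raise InsufficientDataError("window too short for zero-crossing detection")
    x = x - x.mean()
    crossings = int(np.sum((x[:-1] <= 0) & (x[1:] > 0)))
    duration = win[1] - win[0]
    return _bounded(60.0 * crossings / duration, win, "zero_crossing",
                    {"crossings": crossings})


def rr_trough_peak(resp: WaveformSignal,
                   window: tuple[float, float] | None = None,
                   excursion_fraction: float = 0.2) -> RrEstimate:
    """RR from combined trough and peak detection.

    A breath is an alternating trough-to-peak pair whose excursion exceeds
    ``excursion_fraction`` times the window's interquartile amplitude
    range (peak prominence enforces both the excursion floor and the
    alternation); RR = 60 * breaths / window duration.
    """
    x, win = _window_samples(resp, window)
    if x.size < 3:
        raise InsufficientDataError("window too short for trough-peak detection")
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    floor = excursion_fraction * iqr
    if floor <= 0:
        return RrEstimate(value=None, window=win, method="trough_peak",
                          valid=False, diagnostics={"breaths": 0})
    peaks, _ = sps.find_peaks(x, prominence=floor)
    duration = win[1] - win[0]
    return _bounded(60.0 * len(peaks) / duration, win, "trough_peak",
                    {"breaths": int(len(peaks))})


def welch_spectrum(resp: WaveformSignal,
                   window: tuple[float, float] | None = None,
                   provenance: str | None = None) -> SpectrumEstimate:
    """Welch periodogram of one window: Hann taper, segments of at most
    32 s with 50% overlap, zero-padded to a grid of at most 0.5
    breaths/min."""
    x, win = _window_samples(resp, window)
    fs = resp.sampling_rate
    nperseg = int(min(x.size, round(WELCH_MAX_SEGMENT_S * fs)))
    if nperseg < 8:
        raise InsufficientDataError("window too short for a Welch spectrum")
    df_target = WELCH_GRID_BPM / 60.0
    nfft = int(2 ** np.ceil(np.log2(max(nperseg, fs / df_target))))
    freqs, power = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                             noverlap=nperseg // 2, nfft=nfft,
                             detrend="constant")
    return SpectrumEstimate(frequencies=freqs, power=power, window=win,
                            provenance=provenance or getattr(resp, "provenance", ""))


def _spectral_flatness(power: np.ndarray) -> float:
    p = power[power > 0]
    if p.size == 0:
        return 1.0
    return float(np.exp(np.mean(np.log(p))) / np.mean(p))


def rr_spectral(resp: WaveformSignal,
                window: tuple[float, float] | None = None) -> RrEstimate:
    """RR from the largest spectral peak between 4 and 60 breaths/min.

    Ties break to the lowest frequency.  The estimate always carries a
    spectral-flatness diagnostic; a near-flat in-band spectrum (no real
    peak) is marked ``low_confidence``.  Windows shorter than two cycles
    at 4 breaths/min are allowed but flagged ``low_resolution``.
    """
    spec = welch_spectrum(resp, window)
    band = (spec.frequencies >= RR_BAND_BPM[0] / 60.0) & \
           (spec.frequencies <= RR_BAND_BPM[1] / 60.0)
    freqs, power = spec.frequencies[band], spec.power[band]
    win = spec.window
    duration = win[1] - win[0]
    diagnostics = {
        "spectral_flatness": _spectral_flatness(power),
        "low_resolution": duration < 2.0 / (RR_BAND_BPM[0] / 60.0),
    }
    diagnostics["low_confidence"] = diagnostics["spectral_flatness"] > FLATNESS_THRESHOLD
    if freqs.size == 0 or not np.any(power > 0):
        return RrEstimate(value=None, window=win, method="spectral",
                          valid=False, diagnostics=diagnostics)
    rr = 60.0 * float(freqs[np.argmax(power)])
    return _bounded(rr, win, "spectral", diagnostics)


def smart_fusion(estimates: Sequence[RrEstimate]) -> RrEstimate:
    """Fuse the BW/AM/FM estimates of one window.

    If the sample standard deviation of the three values is below 4
    breaths/min the fused RR is their mean; otherwise (or if any input is
    invalid) no RR is produced.
    """
    if len(estimates) != 3:
        raise ConfigError(f"smart fusion takes exactly 3 estimates, got {len(estimates)}")
    window = estimates[0].window
    if any(not e.valid for e in estimates):
        return RrEstimate(value=None, window=window, method="smart_fusion",
                          valid=False, diagnostics={"reason": "invalid input"})
    values = np.array([e.value for e in estimates], dtype=float)
    sd = float(np.std(values, ddof=1))
    if sd >= SMART_FUSION_SD_BPM:
        return RrEstimate(value=None, window=window, method="smart_fusion",
                          valid=False, diagnostics={"sd": sd, "reason": "sd >= 4"})
    return RrEstimate(value=float(np.mean(values)), window=window,
                      method="smart_fusion", valid=True, diagnostics={"sd": sd})


def spectral_peak_conditioned_average(
        spectra: Sequence[SpectrumEstimate],
        inclusion_threshold: float = 0.33,
        band_halfwidth_hz: float = 0.1) -> RrEstimate:
    """Fuse modulation spectra by peak-conditioned averaging.

    Each spectrum is restricted to the respiratory band and normalised to
    unit total power there.  A spectrum is included only if the fraction
    of its power within ``band_halfwidth_hz`` of its own maximum reaches
    ``inclusion_threshold``; RR is the frequency of the maximum of the
    mean included spectrum.  If every spectrum is excluded, no RR is
    produced.
    """
    if not spectra:
        raise ConfigError("need at least one spectrum")
    freqs = spectra[0].frequencies
    for s in spectra[1:]:
        if s.frequencies.shape != freqs.shape or not np.allclose(s.frequencies, freqs):
            raise ConfigError("spectra must share a common frequency grid")
    band = (freqs >= RR_BAND_BPM[0] / 60.0) & (freqs <= RR_BAND_BPM[1] / 60.0)
    f_band = freqs[band]
    window = spectra[0].window
    included = []
    fractions = []
    for s in spectra:
        p = s.power[band]
        total = p.sum()
        if total <= 0:
            fractions.append(0.0)
            continue
        p = p / total
        peak_f = f_band[np.argmax(p)]
        near = np.abs(f_band - peak_f) <= band_halfwidth_hz
        frac = float(p[near].sum())
        fractions.append(frac)
        if frac >= inclusion_threshold:
            included.append(p)
    diagnostics = {"included": len(included), "fractions": fractions}
    if not included:
        return RrEstimate(value=None, window=window,
                          method="spectral_peak_conditioned_average",
                          valid=False, diagnostics=diagnostics)
    mean_spec = np.mean(included, axis=0)
    rr = 60.0 * float(f_band[np.argmax(mean_spec)])
    return _bounded(rr, window, "spectral_peak_conditioned_average", diagnostics)


def temporal_fusion(history: Sequence[RrEstimate], lookback: int = 3) -> RrEstimate:
    """Smooth a subject's consecutive estimates: median of the most recent
    ``lookback`` valid values (fewer at the start of the record); invalid
    if no valid estimate exists in the history."""
    if not history:
        raise InsufficientDataError("temporal fusion requires a non-empty history")
    window = history[-1].window
    values = [e.value for e in history if e.valid][-lookback:]
    if not values:
        return RrEstimate(value=None, window=window, method="temporal_fusion",
                          valid=False, diagnostics={"n_valid": 0})
    return _bounded(float(np.median(values)), window, "temporal_fusion",
                    {"n_valid": len(values)})
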