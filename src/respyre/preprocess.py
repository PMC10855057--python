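"""Filtering, resampling, scaling, and windowing.

These steps are shared by the classical and deep pipelines.  All filters
are order-4 Butterworth applied forward-backward (zero phase).  Because
forward-backward filtering squares the magnitude response, cutoffs are
numerically calibrated so that the *applied* response is -3 dB at the
stated band edges (4 breaths/min for the very-low-frequency high-pass,
4-60 breaths/min for the respiratory band-pass, 35 Hz for the PPG
low-pass).
"""
from __future__ import annotations

from dataclasses import replace
from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy import optimize, signal as sps

from .core import ConfigError, DegenerateSignalError, WaveformSignal, WindowSet

__all__ = [
    "highpass_vlf",
    "bandpass_resp",
    "lowpass_ppg",
    "resample_uniform",
    "zscore_clip",
    "segment_windows",
    "VLF_CUTOFF_HZ",
    "RESP_BAND_HZ",
    "PPG_LOWPASS_HZ",
]

VLF_CUTOFF_HZ = 4.0 / 60.0          # 4 breaths/min
RESP_BAND_HZ = (4.0 / 60.0, 1.0)    # 4-60 breaths/min
PPG_LOWPASS_HZ = 35.0
_ORDER = 4
_SQRT_HALF = 2.0 ** -0.5


def _filtfilt_gain(sos: np.ndarray, freq_hz: float, fs: float) -> float:
    _, h = sps.sosfreqz(sos, worN=[2.0 * np.pi * freq_hz / fs])
    return float(np.abs(h[0]) ** 2)


@lru_cache(maxsize=64)
def _design(btype: str, cutoffs: tuple[float, ...], fs: float) -> np.ndarray:
    """Butterworth SOS whose forward-backward response is -3 dB at the
    requested cutoffs.  Each design edge is solved numerically; the
    analytic single-edge shift ((sqrt(2)-1)^(1/(2N))) seeds the search."""
    shift = (2.0 ** 0.5 - 1.0) ** (1.0 / (2 * _ORDER))

    def build(edges: list[float]) -> np.ndarray:
        wn = [e / (fs / 2.0) for e in edges]
        arg = wn[0] if len(wn) == 1 else wn
        return sps.butter(_ORDER, arg, btype=btype, output="sos")

    if btype == "lowpass":
        edges = [cutoffs[0] / shift]
        directions = [+1]
    elif btype == "highpass":
        edges = [cutoffs[0] * shift]
        directions = [-1]
    else:  # bandpass
        edges = [cutoffs[0] * shift, cutoffs[1] / shift]
        directions = [-1, +1]

    # refine each edge so |H_filtfilt| = 1/sqrt(2) at its target cutoff
    for _ in range(3):
        for i, target in enumerate(cutoffs):
            def err(e: float, i: int = i) -> float:
                trial = list(edges)
                trial[i] = e
                return _filtfilt_gain(build(trial), target, fs) - _SQRT_HALF

            lo = edges[i] * 0.5
            hi = min(edges[i] * 2.0, fs / 2.0 * 0.999)
            try:
                edges[i] = optimize.brentq(err, lo, hi, xtol=1e-12)
            except ValueError:  # pragma: no cover - bracket failure, keep seed
                pass
    return build(edges)


def _apply_zero_phase(sig: WaveformSignal, sos: np.ndarray) -> WaveformSignal:
    n_sections = sos.shape[0]
    padlen = 3 * (2 * n_sections + 1)
    if len(sig) <= 3 * padlen:
        raise ConfigError(
            f"signal too short for stable zero-phase filtering "
            f"(need > {3 * padlen} samples, got {len(sig)})"
        )
    out = sps.sosfiltfilt(sos, sig.samples)
    return replace(sig, samples=out)


def highpass_vlf(sig: WaveformSignal, cutoff_hz: float = VLF_CUTOFF_HZ) -> WaveformSignal:
    """Remove DC and very-low-frequency drift below 4 breaths/min."""
    if sig.sampling_rate <= 2.0 * cutoff_hz:
        raise ConfigError("sampling rate must exceed twice the cutoff")
    return _apply_zero_phase(sig, _design("highpass", (cutoff_hz,), sig.sampling_rate))


def bandpass_resp(sig: WaveformSignal,
                  band_hz: tuple[float, float] = RESP_BAND_HZ) -> WaveformSignal:
    """Keep only the respiratory band, 4-60 breaths/min by default."""
    if sig.sampling_rate <= 2.0 * band_hz[1]:
        raise ConfigError("sampling rate must exceed twice the upper band edge")
    return _apply_zero_phase(sig, _design("bandpass", tuple(band_hz), sig.sampling_rate))


def lowpass_ppg(sig: WaveformSignal, cutoff_hz: float = PPG_LOWPASS_HZ) -> WaveformSignal:
    """Remove high-frequency noise above 35 Hz from the PPG."""
    if sig.sampling_rate <= 2.0 * cutoff_hz:
        raise ConfigError(
            f"sampling rate must exceed {2 * cutoff_hz} Hz for a {cutoff_hz} Hz low-pass"
        )
    return _apply_zero_phase(sig, _design("lowpass", (cutoff_hz,), sig.sampling_rate))


def resample_uniform(sig: WaveformSignal, target_rate: float) -> WaveformSignal:
    """Polyphase anti-aliased resampling to ``target_rate`` Hz.

    Output length is ``round(n * target_rate / source_rate)``; duration is
    preserved to within one sample.  Upsampling is permitted.
    """
    if not target_rate > 0:
        raise ConfigError("target_rate must be positive")
    if target_rate == sig.sampling_rate:
        return replace(sig, samples=sig.samples.copy())
    ratio = (Fraction(target_rate).limit_denominator(10 ** 6)
             / Fraction(sig.sampling_rate).limit_denominator(10 ** 6))
    up, down = ratio.numerator, ratio.denominator
    out = sps.resample_poly(sig.samples, up, down)
    n_target = int(round(len(sig) * target_rate / sig.sampling_rate))
    if len(out) > n_target:
        out = out[:n_target]
    elif len(out) < n_target:  # pragma: no cover - resample_poly returns ceil
        out = np.pad(out, (0, n_target - len(out)), mode="edge")
    return replace(sig, samples=out, sampling_rate=float(target_rate))


def zscore_clip(sig: WaveformSignal, clip: float = 2.0) -> WaveformSignal:
    """Z-score (population statistics) then hard-clip into ``[-clip, +clip]``.

    Removes per-subject baseline offset and scale so every respiratory
    signal lives on a common [-2, +2] range.
    """
    sd = float(np.std(sig.samples))
    if sd == 0.0:
        raise DegenerateSignalError("cannot z-score a constant signal")
    z = (sig.samples - float(np.mean(sig.samples))) / sd
    return replace(sig, samples=np.clip(z, -clip, clip))


def segment_windows(sig: WaveformSignal, window_length: int,
                    stride: int | None = None) -> WindowSet:
    """Cut a signal into equal-length windows, left to right.

    A trailing partial window is dropped.  ``window_length`` longer than
    the signal yields an empty WindowSet (not an error).
    """
    if window_length <= 0:
        raise ConfigError("window_length must be positive")
    stride = window_length if stride is None else stride
    if stride < 1:
        raise ConfigError("stride must be >= 1")
    n = len(sig)
    starts = list(range(0, n - window_length + 1, stride))
    windows = np.array([sig.samples[s:s + window_length] for s in starts])
    intervals = [
        (sig.t0 + s / sig.sampling_rate,
         sig.t0 + (s + window_length) / sig.sampling_rate)
        for s in starts
    ]
    return WindowSet(
        windows=windows if starts else np.empty((0, window_length)),
        window_length=window_length,
        stride=stride,
        source_intervals=intervals,
        sampling_rate=sig.sampling_rate,
    )
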