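"""Respiratory surrogate extraction from PPG.

Two routes produce a uniformly sampled respiratory signal from a PPG
trace:

* **feature-based** — segment the PPG into cardiac pulses with an
  incremental-merge line-segmentation (IMS) scheme, read one feature per
  beat (pulse amplitude for AM, beat interval for FM, pulse baseline for
  BW, and the peak-amplitude / consecutive-trough-mean variants), then
  resample the irregular beat series onto a uniform grid and band-pass it
  to the respiratory band;
* **filter-based** — band-pass the PPG itself to 4-60 breaths/min and
  downsample.

The surrogate rate for the classical estimators defaults to 4 Hz, ample
for respiration at or below 1 Hz; the deep pipeline uses 30 Hz.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from . import preprocess
from .core import (ConfigError, InsufficientDataError, RespiratorySignal,
                   WaveformSignal)

__all__ = [
    "BeatAnnotations",
    "FeatureSeries",
    "segment_pulses_ims",
    "beat_feature_series",
    "resample_feature_series",
    "extract_filter_based",
    "FEATURE_KINDS",
    "RESAMPLE_METHODS",
]

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("peak_amplitude", "trough_mean", "am", "fm", "bw")
RESAMPLE_METHODS = ("linear", "cubic_spline", "berger")
SURROGATE_RATE_HZ = 4.0


@dataclass
class BeatAnnotations:
    """Per-pulse landmarks and quality flags.

    One entry per detected cardiac pulse: the onset/trough index (start of
    the systolic up-slope), the systolic peak index, the amplitudes at
    both, the interval to the next peak (NaN for the last beat), and an
    artifact flag set when a beat's amplitude or duration deviates more
    than ``flag_ratio`` times from the running median.
    """

    onset_idx: np.ndarray
    peak_idx: np.ndarray
    trough_idx: np.ndarray
    peak_amp: np.ndarray
    trough_amp: np.ndarray
    beat_interval: np.ndarray
    artifact_flag: np.ndarray
    fiducial_idx: np.ndarray | None = None
    sampling_rate: float = 1.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.peak_idx)
        if self.fiducial_idx is None:
            self.fiducial_idx = self.peak_idx
        for name in ("onset_idx", "peak_idx", "trough_idx", "peak_amp",
                     "trough_amp", "beat_interval", "artifact_flag",
                     "fiducial_idx"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ConfigError(f"{name} must have one entry per beat")
            setattr(self, name, arr)
        if n and np.any(np.diff(self.peak_idx) <= 0):
            raise ConfigError("beat indices must be strictly increasing")
        if n and np.any(self.trough_idx > self.peak_idx):
            raise ConfigError("trough must precede peak within each pulse")

    @property
    def n_beats(self) -> int:
        return len(self.peak_idx)

    @property
    def peak_times(self) -> np.ndarray:
        return self.t0 + self.peak_idx / self.sampling_rate

    @property
    def trough_times(self) -> np.ndarray:
        return self.t0 + self.trough_idx / self.sampling_rate

    @property
    def fiducial_times(self) -> np.ndarray:
        """Per-beat timing fiducial: the mid-amplitude crossing of the
        systolic rise.  The rise is the steepest part of the pulse, so this
        point is far less sensitive to additive noise than the (locally
        flat) pulse peak; beat-interval series use it."""
        return self.t0 + self.fiducial_idx / self.sampling_rate

    def unflagged(self) -> "BeatAnnotations":
        keep = ~self.artifact_flag.astype(bool)
        return BeatAnnotations(
            onset_idx=self.onset_idx[keep], peak_idx=self.peak_idx[keep],
            trough_idx=self.trough_idx[keep], peak_amp=self.peak_amp[keep],
            trough_amp=self.trough_amp[keep],
            beat_interval=self.beat_interval[keep],
            artifact_flag=self.artifact_flag[keep],
            fiducial_idx=self.fiducial_idx[keep],
            sampling_rate=self.sampling_rate, t0=self.t0,
        )


@dataclass
class FeatureSeries:
    """Irregularly sampled beat-by-beat feature values."""

    times: np.ndarray
    values: np.ndarray
    feature_kind: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ConfigError("times and values must align")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ConfigError("feature times must be strictly increasing")
        if self.feature_kind not in FEATURE_KINDS:
            raise ConfigError(f"unknown feature kind {self.feature_kind!r}")


def _monotone_segments(x: np.ndarray) -> list[tuple[int, int, int]]:
    """Split ``x`` into maximal monotone runs; returns (start, end, sign)
    with sign +1 for rising, -1 for falling.  Flat stretches attach to the
    following run."""
    d = np.diff(x)
    sign = np.sign(d)
    nz = np.nonzero(sign)[0]
    if nz.size == 0:
        return []
    # flats take the sign of the next non-flat diff (trailing flats drop)
    pos = np.searchsorted(nz, np.arange(len(sign)), side="left")
    sign = np.where(pos < nz.size, sign[nz[np.minimum(pos, nz.size - 1)]], 0)
    segments = []
    start = 0
    for i in range(1, len(sign)):
        if sign[i] != sign[i - 1]:
            segments.append((start, i, int(sign[i - 1])))
            start = i
    segments.append((start, len(sign), int(sign[-1])))
    # merge consecutive same-sign runs (can appear after flat handling)
    merged: list[tuple[int, int, int]] = []
    for s in segments:
        if merged and merged[-1][2] == s[2]:
            merged[-1] = (merged[-1][0], s[1], s[2])
        else:
            merged.append(s)
    return [(a, b, s) for a, b, s in merged if s != 0]


def segment_pulses_ims(sig: WaveformSignal,
                       slope_fraction: float = 0.5,
                       merge_fraction: float = 0.25,
                       flag_ratio: float = 2.5,
                       flag_window: int = 11) -> BeatAnnotations:
    """Incremental-merge segmentation of a PPG into cardiac pulses.

    The waveform is scanned left to right with an amplitude hysteresis of
    ``merge_fraction`` times the running median pulse amplitude: local
    extrema whose excursion stays inside the hysteresis band - dicrotic
    notch bumps, noise ripples - are merged into the surrounding slope,
    larger reversals become trough/peak candidates.  A trough-to-peak rise
    is accepted as a pulse when its extent reaches ``slope_fraction`` of
    the running median extent of accepted rises; smaller rises are merged
    into the ongoing descent.  The running median is seeded from the
    largest monotone rises so ripples cannot drag the initial threshold
    down.  Beats whose amplitude or duration deviates more than
    ``flag_ratio``-fold from the running median (window ``flag_window``
    beats) are artifact-flagged.

    The input should be low-passed (see :func:`respyre.preprocess.lowpass_ppg`);
    a flat signal yields an empty annotation set with a logged warning.
    """
    x = sig.samples
    segments = _monotone_segments(x)
    empty = BeatAnnotations(*[np.array([], dtype=t) for t in
                              (int, int, int, float, float, float, bool)],
                            sampling_rate=sig.sampling_rate, t0=sig.t0)
    if not any(s > 0 for _, _, s in segments):
        logger.warning("no pulses found: signal has no rising segments")
        return empty

    up_extents = np.sort([x[b] - x[a] for a, b, s in segments if s > 0])[::-1]
    # seed: median of the top-K rises, K from a conservative 30 beats/min
    k = max(3, min(len(up_extents), int(round(sig.duration * 0.5))))
    seed = float(np.median(up_extents[:k]))
    recent: list[float] = [seed]

    troughs: list[int] = []
    peaks: list[int] = []
    state = "fall"
    cur_min_val, cur_min_idx = x[0], 0
    cur_max_val, cur_max_idx = x[0], 0
    pending: tuple[int, float] | None = None  # deepest trough since last pulse
    for i in range(1, len(x)):
        med = float(np.median(recent[-flag_window:]))
        delta = merge_fraction * med
        v = x[i]
        if state == "fall":
            if v < cur_min_val:
                cur_min_val, cur_min_idx = v, i
            elif v >= cur_min_val + delta:
                if pending is None or cur_min_val < pending[1]:
                    pending = (cur_min_idx, cur_min_val)
                state = "rise"
                cur_max_val, cur_max_idx = v, i
        else:
            if v > cur_max_val:
                cur_max_val, cur_max_idx = v, i
            elif v <= cur_max_val - delta:
                if (pending is not None
                        and cur_max_val - pending[1] >= slope_fraction * med):
                    troughs.append(pending[0])
                    peaks.append(cur_max_idx)
                    recent.append(cur_max_val - pending[1])
                    pending = None
                state = "fall"
                cur_min_val, cur_min_idx = v, i

    if not peaks:
        logger.warning("no pulses found: all rising segments below threshold")
        return empty
    troughs = np.array(troughs)
    peaks = np.array(peaks)

    peak_amp = x[peaks]
    trough_amp = x[troughs]
    fs = sig.sampling_rate
    # timing fiducial: mid-amplitude crossing of the systolic rise (the
    # steep part of the pulse, so additive noise barely moves it)
    fiducials = np.array([
        a + int(np.argmax(x[a:b + 1] >= 0.5 * (x[a] + x[b]))) if b > a else a
        for a, b in zip(troughs, peaks)
    ])
    interval = np.full(len(peaks), np.nan)
    if len(peaks) > 1:
        interval[:-1] = np.diff(fiducials) / fs

    amp = peak_amp - trough_amp
    flags = _deviation_flags(amp, flag_ratio, flag_window)
    dur = interval.copy()
    if len(peaks) > 1:
        dur[-1] = dur[-2]  # duration of the last beat is unknown; reuse
        flags |= _deviation_flags(dur, flag_ratio, flag_window)
    return BeatAnnotations(
        onset_idx=troughs, peak_idx=peaks, trough_idx=troughs,
        peak_amp=peak_amp, trough_amp=trough_amp, beat_interval=interval,
        artifact_flag=flags, fiducial_idx=fiducials,
        sampling_rate=fs, t0=sig.t0,
    )


def _deviation_flags(values: np.ndarray, ratio: float, window: int) -> np.ndarray:
    """Flag entries deviating more than ``ratio``-fold (either way) from a
    centred running median."""
    import pandas as pd

    s = pd.Series(values)
    med = s.rolling(window, center=True, min_periods=1).median().to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = values / med
    return (rel > ratio) | (rel < 1.0 / ratio)


def beat_feature_series(beats: BeatAnnotations, kind: str) -> FeatureSeries:
    """Beat-by-beat feature readings for one modulation route.

    * ``peak_amplitude`` / ``am`` - pulse amplitude (peak minus trough) at
      the peak time; carries amplitude modulation.
    * ``fm`` - beat-to-beat interval between consecutive beat fiducials
      (steepest systolic up-slope points), stamped at the midpoint of the
      pair; carries respiratory sinus arrhythmia.
    * ``bw`` - mean of peak and trough amplitude at the peak time; carries
      baseline wander.
    * ``trough_mean`` - mean of consecutive trough amplitudes at the
      midpoint of the pair.

    Artifact-flagged beats are excluded before the series is formed.
    """
    if kind not in FEATURE_KINDS:
        raise ConfigError(f"unknown feature kind {kind!r}")
    clean = beats.unflagged()
    if clean.n_beats < 2:
        raise InsufficientDataError(
            f"need at least 2 unflagged beats, got {clean.n_beats}"
        )
    t_peak = clean.peak_times
    if kind in ("peak_amplitude", "am"):
        return FeatureSeries(t_peak, clean.peak_amp - clean.trough_amp, kind)
    if kind == "bw":
        return FeatureSeries(t_peak, 0.5 * (clean.peak_amp + clean.trough_amp), kind)
    if kind == "fm":
        t_fid = clean.fiducial_times
        times = 0.5 * (t_fid[1:] + t_fid[:-1])
        return FeatureSeries(times, np.diff(t_fid), kind)
    # trough_mean
    t_trough = clean.trough_times
    times = 0.5 * (t_trough[1:] + t_trough[:-1])
    values = 0.5 * (clean.trough_amp[1:] + clean.trough_amp[:-1])
    return FeatureSeries(times, values, kind)


def _berger_rate(times: np.ndarray, grid: np.ndarray, target_rate: float) -> np.ndarray:
    """Local-window weighted count-rate resampling of event times
    (Berger-style): for each grid point, count events in a window of two
    output intervals, weighting the partial inter-event intervals at the
    window edges by the fraction inside it.  Returns a rate in events/s.
    """
    half = 1.0 / target_rate
    edges = times
    out = np.zeros_like(grid)
    for j, tc in enumerate(grid):
        lo, hi = tc - half, tc + half
        count = 0.0
        for k in range(len(edges) - 1):
            a, b = edges[k], edges[k + 1]
            overlap = max(0.0, min(b, hi) - max(a, lo))
            if overlap > 0:
                count += overlap / (b - a)
        out[j] = count / (2.0 * half)
    return out


def resample_feature_series(series: FeatureSeries, method: str,
                            target_rate: float = SURROGATE_RATE_HZ,
                            bandpass: bool = True) -> RespiratorySignal:
    """Resample an irregular beat series onto a uniform grid.

    The grid runs from the first to the last feature time at
    ``target_rate`` Hz.  ``linear`` and ``cubic_spline`` interpolate the
    feature values (the interpolant passes through the input points);
    ``berger`` applies the local-window weighted count-rate method to the
    feature's event times (approximate; values are ignored).  When
    ``bandpass`` is true the result is band-passed to 4-60 breaths/min.
    """
    if method not in RESAMPLE_METHODS:
        raise ConfigError(f"unknown resampling method {method!r}")
    if not target_rate > 0:
        raise ConfigError("target_rate must be positive")
    if series.times.size < 2:
        raise InsufficientDataError("need at least 2 feature points")
    t0, t1 = float(series.times[0]), float(series.times[-1])
    n = int(np.floor((t1 - t0) * target_rate + 1e-9)) + 1
    grid = t0 + np.arange(n) / target_rate
    if method == "linear":
        vals = np.interp(grid, series.times, series.values)
    elif method == "cubic_spline":
        vals = CubicSpline(series.times, series.values)(grid)
    else:
        vals = _berger_rate(series.times, grid, target_rate)
    out = RespiratorySignal(samples=vals, sampling_rate=target_rate, t0=t0,
                            provenance=series.feature_kind)
    if bandpass:
        filtered = preprocess.bandpass_resp(out)
        out = RespiratorySignal(samples=filtered.samples,
                                sampling_rate=target_rate, t0=t0,
                                provenance=series.feature_kind)
    return out


def extract_filter_based(sig: WaveformSignal,
                         target_rate: float = SURROGATE_RATE_HZ) -> RespiratorySignal:
    """Filter-based surrogate: band-pass the PPG itself to the respiratory
    band and downsample to the surrogate rate."""
    low = preprocess.resample_uniform(sig, target_rate)
    filtered = preprocess.bandpass_resp(low)
    return RespiratorySignal(samples=filtered.samples, sampling_rate=target_rate,
                             t0=sig.t0, provenance="filter_based")
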