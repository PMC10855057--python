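"""Core containers shared by every stage of the toolkit.

A :class:`WaveformSignal` is the carrier for every uniformly sampled 1-D
signal in the package: raw PPG, filtered PPG, and the respiratory
surrogates derived from it.  Time convention: sample index 0 corresponds
to ``t0`` seconds, and all window intervals are half-open ``[start, end)``
in seconds.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "RespyreError",
    "ConfigError",
    "FormatError",
    "DegenerateSignalError",
    "InsufficientDataError",
    "TrainingError",
    "WaveformSignal",
    "RespiratorySignal",
    "WindowSet",
]


class RespyreError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(RespyreError, ValueError):
    """Invalid configuration value."""


class FormatError(RespyreError, ValueError):
    """A file does not match the expected dataset layout."""


class DegenerateSignalError(RespyreError, ValueError):
    """Signal has no usable content (e.g. zero variance)."""


class InsufficientDataError(RespyreError, ValueError):
    """Not enough beats/samples/estimates for the requested operation."""


class TrainingError(RespyreError, RuntimeError):
    """Model training diverged or otherwise failed."""


@dataclass
class WaveformSignal:
    """Uniformly sampled 1-D signal.

    Parameters
    ----------
    samples:
        Amplitude values (arbitrary units); stored as a float64 array.
    sampling_rate:
        Sampling frequency in Hz; must be positive.
    t0:
        Time of sample 0 in seconds.
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ConfigError("samples must be one-dimensional")
        if not self.sampling_rate > 0:
            raise ConfigError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ConfigError("samples must be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds (n / fs)."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Time of each sample in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.sampling_rate

    def slice_seconds(self, start_s: float, end_s: float) -> "WaveformSignal":
        """Return the sub-signal on the half-open interval ``[start_s, end_s)``.

        Times are absolute (i.e. relative to the same origin as ``t0``).
        """
        if end_s <= start_s:
            raise ConfigError("end_s must exceed start_s")
        i0 = int(np.ceil((start_s - self.t0) * self.sampling_rate - 1e-9))
        i1 = int(np.ceil((end_s - self.t0) * self.sampling_rate - 1e-9))
        if i0 < 0 or i1 > self.samples.size:
            raise ConfigError(
                f"window [{start_s}, {end_s}) s outside signal extent "
                f"[{self.t0}, {self.t0 + self.duration}) s"
            )
        return replace(self, samples=self.samples[i0:i1].copy(),
                       t0=self.t0 + i0 / self.sampling_rate)


@dataclass
class RespiratorySignal(WaveformSignal):
    """A uniformly sampled respiratory surrogate with its provenance.

    ``provenance`` records how the surrogate was obtained: one of the
    beat-feature kinds (``am``, ``fm``, ``bw``, ``peak_amplitude``,
    ``trough_mean``) or ``filter_based``.
    """

    provenance: str = "filter_based"


@dataclass
class WindowSet:
    """Equal-length windows cut from one or more signals.

    ``windows`` is an ``(n_windows, window_length)`` array.  When windows
    come from several subjects, ``subject_ids`` records the source of each
    window (used by subject-level dataset splits and by the fluctuation
    flagger, whose statistics are per subject).
    """

    windows: np.ndarray
    window_length: int
    stride: int
    source_intervals: list[tuple[float, float]]
    sampling_rate: float = 1.0
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.size == 0:
            self.windows = self.windows.reshape(0, self.window_length)
        if self.windows.ndim != 2 or self.windows.shape[1] != self.window_length:
            raise ConfigError("every window must have exactly window_length samples")
        if len(self.source_intervals) != self.windows.shape[0]:
            raise ConfigError("one source interval per window required")
        if not self.subject_ids:
            self.subject_ids = [""] * self.windows.shape[0]
        if len(self.subject_ids) != self.windows.shape[0]:
            raise ConfigError("one subject id per window required")

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    def subset(self, indices: Sequence[int]) -> "WindowSet":
        idx = list(indices)
        return WindowSet(
            windows=self.windows[idx],
            window_length=self.window_length,
            stride=self.stride,
            source_intervals=[self.source_intervals[i] for i in idx],
            sampling_rate=self.sampling_rate,
            subject_ids=[self.subject_ids[i] for i in idx],
        )

    @staticmethod
    def concatenate(sets: Sequence["WindowSet"]) -> "WindowSet":
        sets = [s for s in sets if s.n_windows]
        if not sets:
            raise InsufficientDataError("no windows to concatenate")
        first = sets[0]
        for s in sets[1:]:
            if s.window_length != first.window_length:
                raise ConfigError("window lengths differ")
        return WindowSet(
            windows=np.concatenate([s.windows for s in sets], axis=0),
            window_length=first.window_length,
            stride=first.stride,
            source_intervals=sum((s.source_intervals for s in sets), []),
            sampling_rate=first.sampling_rate,
            subject_ids=sum((s.subject_ids for s in sets), []),
        )
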