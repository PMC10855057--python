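"""Performance metrics and signal-quality flagging.

Reference RR values x_i are compared with estimates x̂_i over N windows:

* MAE  = (1/N) Σ |x_i − x̂_i|                     (breaths/min)
* RMSE = sqrt((1/N) Σ (x_i − x̂_i)²)              (breaths/min)
* percentage error = (x̂ − x) / x × 100           (signed, per pair; the
  report aggregates the mean of absolute values)
* CP2  = percentage of windows with |x − x̂| ≤ 2 breaths/min (inclusive)

Pairs whose estimate is invalid (NaN) are excluded from the averages and
counted.  ``flag_fluctuation_segments`` is an automated stand-in for the
manual removal of severely fluctuating one-minute segments: a window is
flagged when its sample SD exceeds ``sd_ratio`` times the subject's
median window SD, or when more than ``rail_fraction`` of its samples sit
at the ±2 z-score clip rails.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .core import ConfigError, InsufficientDataError, WindowSet

__all__ = [
    "EvaluationReport",
    "mae",
    "rmse",
    "percentage_error",
    "mean_abs_percentage_error",
    "cp2",
    "evaluate_estimates",
    "flag_fluctuation_segments",
]

CP_THRESHOLD_BPM = 2.0


def _paired(ref, est) -> tuple[np.ndarray, np.ndarray, int]:
    ref = np.asarray(ref, dtype=float)
    est = np.asarray(est, dtype=float)
    if ref.shape != est.shape or ref.ndim != 1:
        raise ConfigError("ref and est must be 1-D and equal length")
    if ref.size == 0:
        raise InsufficientDataError("no pairs to evaluate")
    keep = np.isfinite(est)
    if not np.any(keep):
        raise InsufficientDataError("all estimates invalid")
    return ref[keep], est[keep], int(np.sum(~keep))


def mae(ref, est) -> float:
    """Mean absolute error in breaths/min; invalid (NaN) estimates are
    excluded from the mean."""
    r, e, _ = _paired(ref, est)
    return float(np.mean(np.abs(r - e)))


def rmse(ref, est) -> float:
    """Root mean square error in breaths/min."""
    r, e, _ = _paired(ref, est)
    return float(np.sqrt(np.mean((r - e) ** 2)))


def percentage_error(ref: float, est: float) -> float:
    """Signed per-pair percentage error, (est − ref) / ref × 100."""
    if ref == 0:
        raise ConfigError("reference RR of 0 has no percentage error")
    return (est - ref) / ref * 100.0


def mean_abs_percentage_error(ref, est) -> float:
    """Mean of absolute per-pair percentage errors."""
    r, e, _ = _paired(ref, est)
    if np.any(r == 0):
        raise ConfigError("reference RR of 0 has no percentage error")
    return float(np.mean(np.abs((e - r) / r)) * 100.0)


def cp2(ref, est, threshold: float = CP_THRESHOLD_BPM) -> float:
    """Percentage of pairs with absolute error ≤ 2 breaths/min (inclusive)."""
    r, e, _ = _paired(ref, est)
    return float(100.0 * np.mean(np.abs(r - e) <= threshold))


@dataclass
class EvaluationReport:
    """Aggregate metrics over the evaluated windows plus the exclusion
    audit trail (excluded windows are reported, never silently dropped)."""

    mae: float
    rmse: float
    mean_abs_percentage_error: float
    cp2: float
    n_windows: int
    n_invalid: int = 0
    excluded_windows: list = field(default_factory=list)
    per_window: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mae > self.rmse + 1e-12:
            raise ConfigError("mae cannot exceed rmse")
        if not 0.0 <= self.cp2 <= 100.0:
            raise ConfigError("cp2 must lie in [0, 100]")
        if self.n_windows < 0:
            raise ConfigError("n_windows must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        def tuplify(x):
            if isinstance(x, list):
                return tuple(tuplify(v) for v in x)
            return x

        d = dict(d)
        d["excluded_windows"] = [tuplify(x) for x in d.get("excluded_windows", [])]
        d["per_window"] = [tuplify(x) for x in d.get("per_window", [])]
        return cls(**d)


def evaluate_estimates(ref, est,
                       windows: list[tuple[float, float]] | None = None,
                       subjects: list[str] | None = None,
                       excluded: list | None = None) -> EvaluationReport:
    """Build an :class:`EvaluationReport` from paired reference/estimate
    arrays (NaN marks an invalid estimate)."""
    r, e, n_invalid = _paired(ref, est)
    ref_arr = np.asarray(ref, dtype=float)
    est_arr = np.asarray(est, dtype=float)
    per_window = []
    if windows is not None:
        subjects = subjects or [""] * len(windows)
        per_window = [
            (subj, tuple(win), float(x), None if not np.isfinite(y) else float(y))
            for subj, win, x, y in zip(subjects, windows, ref_arr, est_arr)
        ]
    return EvaluationReport(
        mae=mae(ref, est),
        rmse=rmse(ref, est),
        mean_abs_percentage_error=mean_abs_percentage_error(r, e),
        cp2=cp2(ref, est),
        n_windows=int(r.size),
        n_invalid=n_invalid,
        excluded_windows=list(excluded or []),
        per_window=per_window,
    )


def flag_fluctuation_segments(windows: WindowSet,
                              sd_ratio: float = 3.0,
                              rail_fraction: float = 0.10,
                              clip: float = 2.0) -> list[tuple[str, tuple[float, float], str]]:
    """Flag severely fluctuating windows of a respiratory surrogate.

    A window is flagged when (a) its sample SD exceeds ``sd_ratio`` times
    the subject's median window SD, or (b) more than ``rail_fraction`` of
    its samples sit at the ±``clip`` rails left by z-score clipping.
    Returns ``(subject, interval, reason)`` tuples; nothing is dropped.
    """
    flagged = []
    sds = windows.windows.std(axis=1)
    subjects = np.asarray(windows.subject_ids)
    medians = {s: float(np.median(sds[subjects == s])) for s in set(subjects)}
    for i in range(windows.n_windows):
        subj = windows.subject_ids[i]
        interval = windows.source_intervals[i]
        med = medians[subj]
        if med > 0 and sds[i] > sd_ratio * med:
            flagged.append((subj, interval, f"sd {sds[i]:.3g} > {sd_ratio} x median {med:.3g}"))
            continue
        at_rail = float(np.mean(np.abs(windows.windows[i]) >= clip - 1e-9))
        if at_rail > rail_fraction:
            flagged.append((subj, interval, f"{at_rail:.1%} of samples at ±{clip} clip rails"))
    return flagged
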