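"""Dataset readers and writers.

Supported layouts:

* **BIDMC CSV** (PhysioNet distribution): per subject,
  ``<prefix>_Signals.csv`` (``Time [s]``, ``PLETH``, ``RESP``, ... at
  125 Hz), ``<prefix>_Numerics.csv`` (``Time [s]``, ``HR``, ``RESP``,
  ``SpO2`` at 1 Hz), ``<prefix>_Breaths.csv`` (annotated breath sample
  indices).  Column names are matched case-insensitively and may be
  overridden.
* **CapnoBase** per-record MAT (v5 via scipy.io, v7.3 via h5py) with the
  benchmark's structure (``signal/pleth/y``, ``param/samplingrate/pleth``,
  ``labels/co2/startinsp/x``, ``reference/rr/co2``), or a plain CSV export
  (``<prefix>_ppg.csv``, ``<prefix>_breaths.csv``, ``<prefix>_rr.csv``).

Readers never resample: sampling rates are reported as found in the file.
Writers exist for every reader so synthetic fixtures round-trip.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FormatError, WaveformSignal
from .metrics import EvaluationReport
from .synthetic import BreathAnnotations

__all__ = [
    "SubjectRecord",
    "read_bidmc_record",
    "write_bidmc_record",
    "read_capnobase_record",
    "write_capnobase_record",
    "read_signal_csv",
    "write_signal_csv",
    "write_report",
    "read_report",
    "layout_description",
]

BIDMC_SAMPLING_HZ = 125.0


@dataclass
class SubjectRecord:
    """One subject's PPG plus whatever references the dataset provides."""

    ppg: WaveformSignal
    subject_id: str
    reference_resp: WaveformSignal | None = None
    reference_breaths: BreathAnnotations | None = None
    reference_rr_series: tuple[np.ndarray, np.ndarray] | None = None  # (time_s, bpm)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise FormatError("subject_id must be nonempty")


def _find_column(df: pd.DataFrame, name: str) -> str | None:
    for col in df.columns:
        if col.strip().lower() == name.strip().lower():
            return col
    return None


def _require_column(df: pd.DataFrame, name: str, path) -> str:
    col = _find_column(df, name)
    if col is None:
        raise FormatError(f"{path}: required column {name!r} not found "
                          f"(columns: {list(df.columns)})")
    return col


def read_bidmc_record(prefix, ppg_column: str = "PLETH",
                      resp_column: str = "RESP",
                      rr_numeric_column: str = "RESP") -> SubjectRecord:
    """Read one subject in the BIDMC CSV layout.

    ``prefix`` is the path up to the layout suffix, e.g. ``data/bidmc_01``
    for ``data/bidmc_01_Signals.csv`` etc.  The numerics and breaths files
    are optional; missing signal columns raise :class:`FormatError` naming
    the column.
    """
    prefix = Path(prefix)
    signals_path = prefix.parent / f"{prefix.name}_Signals.csv"
    if not signals_path.exists():
        raise FormatError(f"{signals_path} not found")
    df = pd.read_csv(signals_path)
    time_col = _require_column(df, "Time [s]", signals_path)
    ppg_col = _require_column(df, ppg_column, signals_path)
    t = df[time_col].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{signals_path}: need at least two samples")
    fs = (t.size - 1) / float(t[-1] - t[0])
    ppg_vals = df[ppg_col].to_numpy(dtype=float)
    if np.any(~np.isfinite(ppg_vals)):
        raise FormatError(f"{signals_path}: column {ppg_col!r} has "
                          "missing values (inconsistent lengths)")
    ppg = WaveformSignal(ppg_vals, sampling_rate=fs, t0=float(t[0]))

    resp = None
    resp_col = _find_column(df, resp_column)
    if resp_col is not None and resp_col != ppg_col:
        resp = WaveformSignal(df[resp_col].to_numpy(dtype=float),
                              sampling_rate=fs, t0=float(t[0]))

    rr_series = None
    metadata: dict = {}
    numerics_path = prefix.parent / f"{prefix.name}_Numerics.csv"
    if numerics_path.exists():
        num = pd.read_csv(numerics_path)
        ntime = _require_column(num, "Time [s]", numerics_path)
        rr_col = _find_column(num, rr_numeric_column)
        if rr_col is not None:
            rr_series = (num[ntime].to_numpy(dtype=float),
                         num[rr_col].to_numpy(dtype=float))
        for key in ("HR", "SpO2", "PULSE"):
            col = _find_column(num, key)
            if col is not None:
                metadata[key.lower()] = float(np.nanmean(num[col].to_numpy(dtype=float)))

    breaths = None
    breaths_path = prefix.parent / f"{prefix.name}_Breaths.csv"
    if breaths_path.exists():
        br = pd.read_csv(breaths_path)
        # first annotator column: sample indices of breaths
        idx = br[br.columns[0]].dropna().to_numpy(dtype=float)
        breaths = BreathAnnotations(breath_onset_times=np.sort(idx) / fs)

    return SubjectRecord(ppg=ppg, subject_id=prefix.name, reference_resp=resp,
                         reference_breaths=breaths,
                         reference_rr_series=rr_series, metadata=metadata)


def write_bidmc_record(record: SubjectRecord, directory) -> Path:
    """Write a record in the BIDMC CSV layout (for fixtures/round-trips).
    Returns the path prefix."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    prefix = directory / record.subject_id
    t = record.ppg.times
    data = {"Time [s]": t, "PLETH": record.ppg.samples}
    if record.reference_resp is not None:
        data["RESP"] = record.reference_resp.samples
    pd.DataFrame(data).to_csv(f"{prefix}_Signals.csv", index=False)
    if record.reference_rr_series is not None:
        nt, rr = record.reference_rr_series
        pd.DataFrame({"Time [s]": nt, "RESP": rr}).to_csv(
            f"{prefix}_Numerics.csv", index=False)
    if record.reference_breaths is not None:
        idx = np.round(record.reference_breaths.breath_onset_times
                       * record.ppg.sampling_rate).astype(int)
        pd.DataFrame({"breaths ann1 [signal sample no]": idx}).to_csv(
            f"{prefix}_Breaths.csv", index=False)
    return prefix


def _mat_v5(path) -> SubjectRecord:
    from scipy.io import loadmat
    try:
        mat = loadmat(path, squeeze_me=True, struct_as_record=False)
    except Exception as exc:
        raise FormatError(f"{path}: unreadable MAT container ({exc})") from exc

    def get(obj, *names):
        for n in names:
            if obj is None:
                return None
            obj = getattr(obj, n, None) if not isinstance(obj, dict) else obj.get(n)
        return obj

    signal = mat.get("signal")
    param = mat.get("param")
    pleth = get(signal, "pleth", "y")
    if pleth is None:
        raise FormatError(f"{path}: no signal/pleth/y entry")
    fs = get(param, "samplingrate", "pleth")
    if fs is None:
        raise FormatError(f"{path}: no param/samplingrate/pleth entry")
    ppg = WaveformSignal(np.asarray(pleth, dtype=float).ravel(), float(np.squeeze(fs)))
    labels = mat.get("labels")
    breaths = None
    start_insp = get(labels, "co2", "startinsp", "x")
    if start_insp is not None and np.asarray(start_insp).size:
        fs_co2 = get(param, "samplingrate", "co2") or fs
        breaths = BreathAnnotations(
            np.sort(np.asarray(start_insp, dtype=float).ravel()) / float(np.squeeze(fs_co2)))
    reference = mat.get("reference")
    rr_series = None
    rr_x = get(reference, "rr", "co2", "x")
    rr_y = get(reference, "rr", "co2", "y")
    if rr_x is not None and rr_y is not None:
        rr_series = (np.asarray(rr_x, dtype=float).ravel(),
                     np.asarray(rr_y, dtype=float).ravel())
    return SubjectRecord(ppg=ppg, subject_id=Path(path).stem,
                         reference_breaths=breaths, reference_rr_series=rr_series)


def _mat_v73(path) -> SubjectRecord:
    import h5py
    try:
        f = h5py.File(path, "r")
    except Exception as exc:
        raise FormatError(f"{path}: unreadable MAT container ({exc})") from exc
    with f:
        def get(*keys):
            node = f
            for k in keys:
                if k not in node:
                    return None
                node = node[k]
            return np.asarray(node)
        pleth = get("signal", "pleth", "y")
        fs = get("param", "samplingrate", "pleth")
        if pleth is None or fs is None:
            raise FormatError(f"{path}: missing signal/pleth/y or "
                              "param/samplingrate/pleth")
        ppg = WaveformSignal(pleth.ravel().astype(float), float(fs.ravel()[0]))
        breaths = None
        start_insp = get("labels", "co2", "startinsp", "x")
        if start_insp is not None and start_insp.size:
            fs_co2 = get("param", "samplingrate", "co2")
            fs_co2 = float(fs_co2.ravel()[0]) if fs_co2 is not None else ppg.sampling_rate
            breaths = BreathAnnotations(np.sort(start_insp.ravel().astype(float)) / fs_co2)
        rr_series = None
        rr_x, rr_y = get("reference", "rr", "co2", "x"), get("reference", "rr", "co2", "y")
        if rr_x is not None and rr_y is not None:
            rr_series = (rr_x.ravel().astype(float), rr_y.ravel().astype(float))
    return SubjectRecord(ppg=ppg, subject_id=Path(path).stem,
                         reference_breaths=breaths, reference_rr_series=rr_series)


def read_capnobase_record(path) -> SubjectRecord:
    """Read one CapnoBase benchmark record (MAT v5/v7.3, or the CSV
    export layout when ``path`` is a prefix of ``*_ppg.csv`` files)."""
    path = Path(path)
    if path.suffix.lower() == ".mat":
        if not path.exists():
            raise FormatError(f"{path} not found")
        import h5py
        if h5py.is_hdf5(path):
            return _mat_v73(path)
        return _mat_v5(path)
    ppg_path = path.parent / f"{path.name}_ppg.csv"
    if not ppg_path.exists():
        raise FormatError(f"{ppg_path} not found")
    ppg = read_signal_csv(ppg_path)
    breaths = None
    breaths_path = path.parent / f"{path.name}_breaths.csv"
    if breaths_path.exists():
        df = pd.read_csv(breaths_path)
        breaths = BreathAnnotations(np.sort(df[df.columns[0]].to_numpy(dtype=float)))
    rr_series = None
    rr_path = path.parent / f"{path.name}_rr.csv"
    if rr_path.exists():
        df = pd.read_csv(rr_path)
        rr_series = (df[df.columns[0]].to_numpy(dtype=float),
                     df[df.columns[1]].to_numpy(dtype=float))
    return SubjectRecord(ppg=ppg, subject_id=path.name,
                         reference_breaths=breaths, reference_rr_series=rr_series)


def write_capnobase_record(record: SubjectRecord, directory,
                           container: str = "csv") -> Path:
    """Write a record in the CapnoBase CSV export layout or as a MAT v5
    file mirroring the benchmark structure."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if container == "mat":
        from scipy.io import savemat
        path = directory / f"{record.subject_id}.mat"
        fs = record.ppg.sampling_rate
        mat = {
            "signal": {"pleth": {"y": record.ppg.samples}},
            "param": {"samplingrate": {"pleth": fs, "co2": fs}},
        }
        if record.reference_breaths is not None:
            mat["labels"] = {"co2": {"startinsp": {
                "x": record.reference_breaths.breath_onset_times * fs}}}
        if record.reference_rr_series is not None:
            mat["reference"] = {"rr": {"co2": {
                "x": record.reference_rr_series[0],
                "y": record.reference_rr_series[1]}}}
        savemat(path, mat)
        return path
    prefix = directory / record.subject_id
    write_signal_csv(record.ppg, f"{prefix}_ppg.csv")
    if record.reference_breaths is not None:
        pd.DataFrame({"onset_s": record.reference_breaths.breath_onset_times}
                     ).to_csv(f"{prefix}_breaths.csv", index=False)
    if record.reference_rr_series is not None:
        pd.DataFrame({"time_s": record.reference_rr_series[0],
                      "rr_bpm": record.reference_rr_series[1]}
                     ).to_csv(f"{prefix}_rr.csv", index=False)
    return prefix


def read_signal_csv(path) -> WaveformSignal:
    """Read a two-column (time_s, amplitude) CSV."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (time_s, amplitude)")
    t = df[df.columns[0]].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: need at least two samples")
    fs = (t.size - 1) / float(t[-1] - t[0])
    return WaveformSignal(df[df.columns[1]].to_numpy(dtype=float),
                          sampling_rate=fs, t0=float(t[0]))


def write_signal_csv(sig: WaveformSignal, path) -> None:
    pd.DataFrame({"time_s": sig.times, "amplitude": sig.samples}
                 ).to_csv(path, index=False)


def write_report(report: EvaluationReport, path) -> None:
    """Write an evaluation report as JSON (full, round-trippable) or CSV
    (per-window rows with a metrics header), by file extension."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(report.to_dict(), indent=2))
        return
    rows = [{"subject": s, "window_start_s": w[0], "window_end_s": w[1],
             "reference_rr": r, "estimated_rr": e}
            for s, w, r, e in report.per_window]
    with open(path, "w") as fh:
        fh.write(f"# mae={report.mae} rmse={report.rmse} "
                 f"mean_abs_percentage_error={report.mean_abs_percentage_error} "
                 f"cp2={report.cp2} n_windows={report.n_windows} "
                 f"n_invalid={report.n_invalid}\n")
        pd.DataFrame(rows, columns=["subject", "window_start_s", "window_end_s",
                                    "reference_rr", "estimated_rr"]
                     ).to_csv(fh, index=False)


def read_report(path) -> EvaluationReport:
    return EvaluationReport.from_dict(json.loads(Path(path).read_text()))


def layout_description(dataset: str) -> str:
    """Expected on-disk layout for a supported dataset."""
    layouts = {
        "bidmc": (
            "BIDMC CSV layout (PhysioNet 'bidmc' CSV distribution), one\n"
            "prefix per subject, e.g. bidmc_01:\n"
            "  <prefix>_Signals.csv   Time [s], RESP, PLETH, ... at 125 Hz\n"
            "  <prefix>_Numerics.csv  Time [s], HR, PULSE, RESP, SpO2 at 1 Hz\n"
            "  <prefix>_Breaths.csv   annotated breath sample indices\n"
        ),
        "capnobase": (
            "CapnoBase TBME-RR benchmark, one file or CSV prefix per record:\n"
            "  <record>.mat  with signal/pleth/y, param/samplingrate/pleth,\n"
            "                labels/co2/startinsp/x, reference/rr/co2/{x,y}\n"
            "or the CSV export layout:\n"
            "  <prefix>_ppg.csv      time_s, amplitude\n"
            "  <prefix>_breaths.csv  onset_s\n"
            "  <prefix>_rr.csv       time_s, rr_bpm\n"
        ),
    }
    if dataset not in layouts:
        raise FormatError(f"unknown dataset {dataset!r}; choose from {sorted(layouts)}")
    return layouts[dataset]
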