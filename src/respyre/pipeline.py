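"""End-to-end pipelines tying the modules together.

``run_classical_pipeline`` executes preprocess → pulse segmentation →
beat-feature surrogate extraction → windowed RR estimation → fusion →
evaluation.  ``run_deep_pipeline`` executes preprocess (30 Hz, z-score)
→ labelling → split → CNN-LSTM training → label prediction → RR from
inhalation counts → evaluation.  Both accept the same
:class:`PipelineConfig`, run fully deterministically under its seed, and
write per-window estimates, a report, and a run manifest when an output
directory is configured.

Inputs are either dataset directories (BIDMC / CapnoBase layouts) or the
synthetic generator; for synthetic runs the reference RR comes from the
generator's ground-truth annotations, for datasets from the annotated
breaths (preferred) or the recorded RR numerics.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__, io, preprocess
from .core import (ConfigError, InsufficientDataError, RespiratorySignal,
                   WaveformSignal, WindowSet)
from .estimate import (RrEstimate, rr_spectral, rr_trough_peak,
                       rr_zero_crossing, smart_fusion,
                       spectral_peak_conditioned_average, temporal_fusion,
                       welch_spectrum)
from .extract import (beat_feature_series, extract_filter_based,
                      resample_feature_series, segment_pulses_ims)
from .metrics import EvaluationReport, evaluate_estimates, flag_fluctuation_segments
from .nn import (LABEL_RATE_HZ, ModelConfig, build_model, label_breath_phase,
                 load_model, pool_labels, predict_labels, rr_from_labels,
                 save_model, split_dataset, train_model)
from .synthetic import BreathAnnotations, SyntheticConfig, generate_ppg

__all__ = [
    "SyntheticSpec",
    "ClassicalSpec",
    "PipelineConfig",
    "load_config",
    "run_classical_pipeline",
    "run_deep_pipeline",
    "make_synthetic_resp_dataset",
]

logger = logging.getLogger(__name__)

ESTIMATORS = {
    "zero_crossing": rr_zero_crossing,
    "trough_peak": rr_trough_peak,
    "spectral": rr_spectral,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for synthetic runs.

    ``resp_rates`` are cycled across subjects; when empty, each subject
    draws a rate uniformly from 8-30 breaths/min.
    """

    n_subjects: int = 5
    duration_s: float = 480.0
    sampling_rate: float = 125.0
    heart_rate: float = 75.0
    resp_rates: tuple[float, ...] = ()
    bw_depth: float = 0.1
    am_depth: float = 0.1
    fm_depth: float = 0.1
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be positive")


@dataclass(frozen=True)
class ClassicalSpec:
    """Choices for the classical estimation chain."""

    modalities: tuple[str, ...] = ("bw", "am", "fm")
    estimator: str = "spectral"
    fusion: str = "smart"          # none | smart | spectral_avg
    temporal: bool = True
    window_s: float = 60.0
    resample_method: str = "linear"
    surrogate_rate_hz: float = 4.0
    flag_fluctuations: bool = False

    def __post_init__(self) -> None:
        if self.estimator not in ESTIMATORS:
            raise ConfigError(f"estimator must be one of {sorted(ESTIMATORS)}")
        if self.fusion not in ("none", "smart", "spectral_avg"):
            raise ConfigError("fusion must be none, smart, or spectral_avg")
        if self.fusion != "none" and len(self.modalities) != 3:
            raise ConfigError("fusion needs the three bw/am/fm modalities")


@dataclass(frozen=True)
class PipelineConfig:
    synthetic: SyntheticSpec | None = field(default_factory=SyntheticSpec)
    data_dir: str | None = None
    dataset: str = "bidmc"
    classical: ClassicalSpec = field(default_factory=ClassicalSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    model_path: str | None = None
    output_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        """Build a config from a plain mapping, rejecting unknown keys."""
        def build(klass, d):
            if d is None:
                return None
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(d) - names
            if unknown:
                raise ConfigError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
            for key in ("resp_rates", "modalities"):
                if key in d and isinstance(d[key], list):
                    d = {**d, key: tuple(d[key])}
            return klass(**d)

        raw = dict(raw)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ConfigError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        if "synthetic" in raw:
            raw["synthetic"] = build(SyntheticSpec, raw["synthetic"])
        if "classical" in raw:
            raw["classical"] = build(ClassicalSpec, raw["classical"])
        if "model" in raw:
            raw["model"] = build(ModelConfig, raw["model"])
        return cls(**raw)


def load_config(path) -> PipelineConfig:
    """Load a YAML or JSON pipeline configuration."""
    import yaml

    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()) or {})


# ---------------------------------------------------------------------------
# input assembly

def _synthetic_records(spec: SyntheticSpec, seed: int):
    """Yield (SubjectRecord-like) tuples of (subject_id, ppg, annotations)."""
    rng = np.random.default_rng(seed)
    for i in range(spec.n_subjects):
        if spec.resp_rates:
            rr = spec.resp_rates[i % len(spec.resp_rates)]
        else:
            rr = float(rng.uniform(8.0, 30.0))
        cfg = SyntheticConfig(
            duration_s=spec.duration_s, sampling_rate=spec.sampling_rate,
            heart_rate=spec.heart_rate, resp_rate=rr, bw_depth=spec.bw_depth,
            am_depth=spec.am_depth, fm_depth=spec.fm_depth,
            noise_sd=spec.noise_sd, seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        ppg, ann = generate_ppg(cfg)
        yield f"synth{i:03d}", ppg, ann


def _dataset_records(config: PipelineConfig):
    directory = Path(config.data_dir)
    if config.dataset == "bidmc":
        prefixes = sorted({p.name[:-len("_Signals.csv")]
                           for p in directory.glob("*_Signals.csv")})
        if not prefixes:
            raise ConfigError(f"no *_Signals.csv records in {directory}")
        for prefix in prefixes:
            rec = io.read_bidmc_record(directory / prefix)
            yield rec.subject_id, rec.ppg, rec.reference_breaths or rec.reference_rr_series
    elif config.dataset == "capnobase":
        paths = sorted(directory.glob("*.mat")) or sorted(
            p.with_name(p.name[:-len("_ppg.csv")])
            for p in directory.glob("*_ppg.csv"))
        if not paths:
            raise ConfigError(f"no CapnoBase records in {directory}")
        for path in paths:
            rec = io.read_capnobase_record(path)
            yield rec.subject_id, rec.ppg, rec.reference_breaths or rec.reference_rr_series
    else:
        raise ConfigError(f"unknown dataset {config.dataset!r}")


def _reference_rr(reference, start: float, end: float) -> float | None:
    """Reference RR over one window from whatever reference is available."""
    if reference is None:
        return None
    if isinstance(reference, BreathAnnotations):
        return reference.reference_rr(start, end)
    times, values = reference
    mask = (times >= start) & (times < end)
    if not np.any(mask):
        return None
    return float(np.mean(values[mask]))


def _records(config: PipelineConfig):
    if config.data_dir is not None:
        yield from _dataset_records(config)
    elif config.synthetic is not None:
        yield from _synthetic_records(config.synthetic, config.seed)
    else:
        raise ConfigError("config needs either a data_dir or a synthetic spec")


def _write_outputs(config: PipelineConfig, report: EvaluationReport,
                   name: str) -> None:
    if config.output_dir is None:
        return
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_report(report, out / f"{name}_report.json")
    io.write_report(report, out / f"{name}_estimates.csv")
    manifest = {
        "pipeline": name,
        "seed": config.seed,
        "config": _config_dict(config),
        "versions": {"respyre": __version__, "numpy": np.__version__},
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / f"{name}_manifest.json").write_text(json.dumps(manifest, indent=2))


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d


# ---------------------------------------------------------------------------
# classical pipeline

def _surrogates(ppg: WaveformSignal, spec: ClassicalSpec) -> dict[str, RespiratorySignal]:
    filtered = preprocess.highpass_vlf(preprocess.lowpass_ppg(ppg))
    out: dict[str, RespiratorySignal] = {}
    feature_kinds = [m for m in spec.modalities if m != "filter_based"]
    if feature_kinds:
        beats = segment_pulses_ims(filtered)
        for kind in feature_kinds:
            series = beat_feature_series(beats, kind)
            out[kind] = resample_feature_series(
                series, spec.resample_method, spec.surrogate_rate_hz)
    if "filter_based" in spec.modalities:
        out["filter_based"] = extract_filter_based(ppg, spec.surrogate_rate_hz)
    return out


def _clip_window(sig: WaveformSignal, start: float, end: float) -> tuple[float, float] | None:
    a = max(start, sig.t0)
    b = min(end, sig.t0 + sig.duration)
    if b - a < 0.5 * (end - start):
        return None  # surrogate covers less than half the window
    return a, b


def run_classical_pipeline(config: PipelineConfig) -> EvaluationReport:
    """Classical chain over every subject and window; returns the report."""
    spec = config.classical
    estimator = ESTIMATORS[spec.estimator]
    refs, ests, windows, subjects = [], [], [], []
    excluded = []
    for subject_id, ppg, reference in _records(config):
        try:
            surrogates = _surrogates(ppg, spec)
        except InsufficientDataError as exc:
            logger.warning("%s: %s; subject skipped", subject_id, exc)
            excluded.append((subject_id, (ppg.t0, ppg.t0 + ppg.duration), str(exc)))
            continue
        if spec.flag_fluctuations:
            for name, surr in surrogates.items():
                zs = preprocess.zscore_clip(surr)
                ws = preprocess.segment_windows(
                    zs, int(spec.window_s * surr.sampling_rate))
                ws.subject_ids = [subject_id] * ws.n_windows
                excluded.extend(flag_fluctuation_segments(ws))
        excluded_intervals = [e[1] for e in excluded if e[0] == subject_id]

        def _is_excluded(start: float, end: float) -> bool:
            for a, b in excluded_intervals:
                overlap = min(end, b) - max(start, a)
                if overlap > 0.5 * (end - start):
                    return True
            return False
        history: list[RrEstimate] = []
        n_windows = int((ppg.duration + 1e-9) // spec.window_s)
        for w in range(n_windows):
            start = ppg.t0 + w * spec.window_s
            end = start + spec.window_s
            if _is_excluded(start, end):
                continue
            per_modality = []
            for name in spec.modalities:
                surr = surrogates[name]
                win = _clip_window(surr, start, end)
                if win is None:
                    per_modality.append(RrEstimate(None, (start, end), name, False))
                else:
                    per_modality.append(estimator(surr, win))
            if spec.fusion == "smart":
                fused = smart_fusion(per_modality)
            elif spec.fusion == "spectral_avg":
                spectra = []
                for name in spec.modalities:
                    surr = surrogates[name]
                    win = _clip_window(surr, start, end)
                    if win is not None:
                        spectra.append(welch_spectrum(surr, win))
                fused = (spectral_peak_conditioned_average(spectra)
                         if spectra else RrEstimate(None, (start, end),
                                                    "spectral_peak_conditioned_average", False))
            else:
                fused = per_modality[0]
            history.append(fused)
            final = temporal_fusion(history) if spec.temporal else fused
            ref = _reference_rr(reference, start, end)
            if ref is None:
                continue
            refs.append(ref)
            ests.append(final.value if final.valid else np.nan)
            windows.append((start, end))
            subjects.append(subject_id)
    report = evaluate_estimates(refs, ests, windows=windows, subjects=subjects,
                                excluded=excluded)
    _write_outputs(config, report, "classical")
    return report


# ---------------------------------------------------------------------------
# deep pipeline

def make_synthetic_resp_dataset(n_subjects: int, seed: int,
                                duration_s: float = 60.0,
                                noise_sd: float = 0.05,
                                rate_hz: float = LABEL_RATE_HZ,
                                window_samples: int = 210,
                                rr_range: tuple[float, float] = (8.0, 30.0),
                                ) -> tuple[WindowSet, dict[tuple[str, int], float]]:
    """Synthetic 30 Hz respiratory dataset for the deep pipeline.

    One sinusoidal respiratory signal per subject (RR uniform in
    ``rr_range``, random phase, additive white noise), z-scored and
    clipped to ±2, cut minute by minute into model windows.  Returns the
    windows plus the reference RR keyed by (subject, minute index).
    """
    rng = np.random.default_rng(seed)
    sets, ref = [], {}
    for s in range(n_subjects):
        subject = f"s{s:04d}"
        rr = float(rng.uniform(*rr_range))
        phase = float(rng.uniform(0.0, 2.0 * np.pi))
        t = np.arange(int(round(duration_s * rate_hz))) / rate_hz
        x = np.sin(2.0 * np.pi * rr / 60.0 * t + phase)
        if noise_sd > 0:
            x = x + noise_sd * rng.normal(size=t.size)
        sig = preprocess.zscore_clip(WaveformSignal(x, rate_hz))
        for minute in range(int(duration_s // 60.0)):
            chunk = sig.slice_seconds(minute * 60.0, (minute + 1) * 60.0)
            ws = preprocess.segment_windows(chunk, window_samples)
            ws.subject_ids = [subject] * ws.n_windows
            sets.append(ws)
            ref[(subject, minute)] = rr
    return WindowSet.concatenate(sets), ref


def _dataset_resp_windows(config: PipelineConfig
                          ) -> tuple[WindowSet, dict[tuple[str, int], float]]:
    """Respiratory surrogate windows from a dataset directory: filter-based
    extraction at 30 Hz, z-score, minute-by-minute windowing."""
    sets, ref = [], {}
    window_samples = config.model.window_samples
    for subject_id, ppg, reference in _records(config):
        surr = extract_filter_based(ppg, LABEL_RATE_HZ)
        sig = preprocess.zscore_clip(surr)
        n_minutes = int((sig.duration + 1e-9) // 60.0)
        for minute in range(n_minutes):
            start = sig.t0 + minute * 60.0
            rr = _reference_rr(reference, start, start + 60.0)
            if rr is None:
                continue
            chunk = sig.slice_seconds(start, start + 60.0)
            ws = preprocess.segment_windows(chunk, window_samples)
            ws.subject_ids = [subject_id] * ws.n_windows
            sets.append(ws)
            ref[(subject_id, minute)] = rr
    return WindowSet.concatenate(sets), ref


def _minute_key(subject: str, interval: tuple[float, float]) -> tuple[str, int]:
    return subject, int(interval[0] // 60.0)


def run_deep_pipeline(config: PipelineConfig) -> EvaluationReport:
    """Deep chain: label, split, train (or load), predict, count, evaluate.

    RR is evaluated per one-minute segment: each minute's predicted pooled
    labels are concatenated in time order and inhalation onsets are
    counted over the covered duration.
    """
    model_cfg = config.model
    if config.data_dir is not None:
        windows, ref = _dataset_resp_windows(config)
    else:
        spec = config.synthetic or SyntheticSpec()
        windows, ref = make_synthetic_resp_dataset(
            n_subjects=spec.n_subjects, seed=config.seed,
            duration_s=spec.duration_s if spec.duration_s else 60.0,
            noise_sd=spec.noise_sd, window_samples=model_cfg.window_samples)

    train, val, test = split_dataset(windows, model_cfg, by="subject")
    logger.info("split: %d train / %d val / %d test windows",
                train.n_windows, val.n_windows, test.n_windows)

    if config.model_path and Path(config.model_path).exists():
        trained = load_model(config.model_path)
        logger.info("loaded model from %s; training skipped", config.model_path)
    else:
        def as_xy(ws: WindowSet):
            return ws.windows, pool_labels(label_breath_phase(ws.windows), model_cfg)
        model = build_model(model_cfg)
        trained = train_model(model, as_xy(train), as_xy(val), model_cfg)
        logger.info("best validation loss %.4f at epoch %d",
                    trained.best_val_loss, trained.best_epoch)
        if config.output_dir is not None:
            out = Path(config.output_dir)
            out.mkdir(parents=True, exist_ok=True)
            save_model(trained, out / "model.npz")
            with open(out / "training_log.csv", "w") as fh:
                fh.write("epoch,train_loss,val_loss\n")
                for epoch, tr_loss, va_loss in trained.history:
                    fh.write(f"{epoch},{tr_loss},{va_loss}\n")

    labels = predict_labels(trained, test.windows)
    by_minute: dict[tuple[str, int], list[tuple[float, np.ndarray]]] = {}
    for i in range(test.n_windows):
        key = _minute_key(test.subject_ids[i], test.source_intervals[i])
        by_minute.setdefault(key, []).append(
            (test.source_intervals[i][0], labels[i]))
    refs, ests, intervals, subjects = [], [], [], []
    window_duration = model_cfg.window_samples / model_cfg.input_rate_hz
    for key, items in sorted(by_minute.items()):
        items.sort(key=lambda it: it[0])
        lab = np.concatenate([l for _, l in items])
        est = rr_from_labels(lab, len(items) * window_duration)
        refs.append(ref[key])
        ests.append(est.value if est.valid else np.nan)
        intervals.append((key[1] * 60.0, (key[1] + 1) * 60.0))
        subjects.append(key[0])
    report = evaluate_estimates(refs, ests, windows=intervals, subjects=subjects)
    _write_outputs(config, report, "deep")
    return report
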