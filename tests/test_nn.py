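"""CNN-LSTM classifier: configuration, splits, labelling, training, and
RR from predicted labels."""
import numpy as np
import pytest

from respyre import (ConfigError, ModelConfig, WaveformSignal, WindowSet,
                     build_model, label_breath_phase, pool_labels,
                     predict_labels, predict_proba, rr_from_labels,
                     load_model, save_model, segment_windows, split_dataset,
                     train_model, zscore_clip)
from respyre.nn import _loss_and_grads


def _dataset(n_subjects=40, seed=0, noise=0.0, duration=60.0, fs=30.0,
             window=210):
    """Sinusoidal respiratory windows with per-subject rates."""
    rng = np.random.default_rng(seed)
    sets = []
    for s in range(n_subjects):
        f = rng.uniform(8, 30) / 60.0
        t = np.arange(int(duration * fs)) / fs
        x = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        if noise:
            x = x + noise * rng.normal(size=t.size)
        sig = zscore_clip(WaveformSignal(x, fs))
        ws = segment_windows(sig, window)
        ws.subject_ids = [f"s{s:03d}"] * ws.n_windows
        sets.append(ws)
    return WindowSet.concatenate(sets)


def _xy(ws, cfg):
    return ws.windows, pool_labels(label_breath_phase(ws.windows), cfg)


class TestModelConfig:
    def test_pooled_length_truncates(self):
        assert ModelConfig(window_samples=210, pool_size=2).pooled_length == 105
        assert ModelConfig(window_samples=210, pool_size=3).pooled_length == 70
        assert ModelConfig(window_samples=240, pool_size=2,
                           conv_layers=2).pooled_length == 60

    @pytest.mark.parametrize("kwargs", [
        {"window_samples": 100},
        {"conv_layers": 4},
        {"filter_length": 6},
        {"pool_size": 1},
        {"split_ratio": "30:70"},
        {"learning_rate": 0.0},
        {"val_fraction": 1.0},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            ModelConfig(**kwargs)


class TestLabelling:
    def test_threshold_rule(self):
        assert list(label_breath_phase(np.array([0.5, -0.3, 1.2]))) == [1, 0, 1]

    def test_zero_is_exhalation(self):
        assert label_breath_phase(np.array([0.0]))[0] == 0

    def test_all_positive(self):
        assert label_breath_phase(np.ones(10)).sum() == 10

    def test_pooled_labels_any_inhale(self):
        cfg = ModelConfig(window_samples=210, pool_size=2)
        labels = np.zeros(210, dtype=int)
        labels[3] = 1  # one inhale sample inside pool group 1
        pooled = pool_labels(labels, cfg)
        assert pooled.shape == (105,)
        assert pooled[1] == 1 and pooled.sum() == 1


class TestSplit:
    def test_window_mode_floor_arithmetic(self):
        # 53 one-minute signals x 8 windows of 210 samples = 424 windows
        ws = _dataset(n_subjects=53, duration=60.0)
        assert ws.n_windows == 424
        cfg = ModelConfig(split_ratio="50:50", seed=1)
        train, val, test = split_dataset(ws, cfg, by="window")
        assert test.n_windows == 212
        assert train.n_windows == 169 and val.n_windows == 43

    def test_small_split(self):
        ws = _dataset(n_subjects=10, duration=7.0)
        cfg = ModelConfig(split_ratio="80:20", seed=0)
        _, _, test = split_dataset(ws, cfg, by="window")
        assert test.n_windows == 2

    def test_subject_mode_disjoint(self):
        ws = _dataset(n_subjects=20)
        cfg = ModelConfig(split_ratio="50:50", seed=2)
        train, val, test = split_dataset(ws, cfg, by="subject")
        train_subjects = set(train.subject_ids) | set(val.subject_ids)
        assert train_subjects.isdisjoint(set(test.subject_ids))

    def test_deterministic_under_seed(self):
        ws = _dataset(n_subjects=12)
        cfg = ModelConfig(seed=7)
        a = split_dataset(ws, cfg)
        b = split_dataset(ws, cfg)
        for x, y in zip(a, b):
            assert np.array_equal(x.windows, y.windows)


class TestBuildPredict:
    def test_same_seed_same_init(self):
        cfg = ModelConfig(seed=5)
        a, b = build_model(cfg), build_model(cfg)
        assert np.array_equal(a.params["lstm"]["Wx"], b.params["lstm"]["Wx"])
        assert np.array_equal(a.params["conv"][0]["W"], b.params["conv"][0]["W"])

    def test_probabilities_normalised(self):
        cfg = ModelConfig(seed=5)
        model = build_model(cfg)
        probs = predict_proba(model, np.random.default_rng(0).normal(size=(3, 210)))
        assert probs.shape == (3, 105, 2)
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_wrong_window_length_rejected(self):
        model = build_model(ModelConfig(seed=5))
        with pytest.raises(ConfigError):
            predict_labels(model, np.zeros(120))

    def test_argmax_tie_breaks_to_exhalation(self):
        probs = np.array([[[0.5, 0.5], [0.3, 0.7], [0.7, 0.3]]])
        labels = (probs[..., 1] > probs[..., 0]).astype(int)
        assert list(labels[0]) == [0, 1, 0]


def test_gradients_match_finite_differences():
    cfg = ModelConfig(window_samples=120, conv_layers=2, conv_filters=3,
                      filter_length=3, pool_size=2, lstm_units=5, seed=3)
    model = build_model(cfg)
    rng = np.random.default_rng(0)
    x = rng.normal(size=(4, 120))
    y = (rng.random((4, cfg.pooled_length)) > 0.5).astype(int)
    _, grads = _loss_and_grads(model.params, cfg, x, y)
    eps = 1e-6
    checks = [
        (model.params["conv"][0]["W"], grads["conv"][0]["W"], (0, 0, 0)),
        (model.params["lstm"]["Wx"], grads["lstm"]["Wx"], (1, 2)),
        (model.params["lstm"]["Wh"], grads["lstm"]["Wh"], (0, 3)),
        (model.params["dense"]["W"], grads["dense"]["W"], (2, 1)),
    ]
    for arr, grad, idx in checks:
        orig = arr[idx]
        arr[idx] = orig + eps
        lp, _ = _loss_and_grads(model.params, cfg, x, y)
        arr[idx] = orig - eps
        lm, _ = _loss_and_grads(model.params, cfg, x, y)
        arr[idx] = orig
        numeric = (lp - lm) / (2 * eps)
        assert grad[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-9)


class TestTraining:
    def test_loss_decreases_and_accuracy_high(self):
        cfg = ModelConfig(seed=7, epochs=30)
        ws = _dataset(n_subjects=100, seed=7)
        train, val, test = split_dataset(ws, cfg, by="subject")
        trained = train_model(build_model(cfg), _xy(train, cfg), _xy(val, cfg), cfg)
        first_val = trained.history[0][2]
        assert trained.best_val_loss < first_val
        labels = predict_labels(trained, test.windows)
        ref = pool_labels(label_breath_phase(test.windows), cfg)
        assert (labels == ref).mean() > 0.90

    def test_training_deterministic(self):
        cfg = ModelConfig(seed=9, epochs=2)
        ws = _dataset(n_subjects=12, seed=9)
        train, val, _ = split_dataset(ws, cfg, by="subject")
        a = train_model(build_model(cfg), _xy(train, cfg), _xy(val, cfg), cfg)
        b = train_model(build_model(cfg), _xy(train, cfg), _xy(val, cfg), cfg)
        assert a.history == b.history
        assert np.array_equal(a.params["lstm"]["Wx"], b.params["lstm"]["Wx"])

    def test_early_stopping_on_degenerate_labels(self):
        # constant but conflicting labels: fitting the training labels can
        # only worsen validation loss, so no epoch improves on the first
        cfg = ModelConfig(seed=1, epochs=100, patience=5)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(40, 210))
        y_tr = np.ones((32, cfg.pooled_length), dtype=int)
        y_va = np.zeros((8, cfg.pooled_length), dtype=int)
        trained = train_model(build_model(cfg), (x[:32], y_tr), (x[32:], y_va),
                              cfg)
        assert len(trained.history) < 100

    def test_best_val_loss_is_minimum(self):
        cfg = ModelConfig(seed=7, epochs=4)
        ws = _dataset(n_subjects=12, seed=3)
        train, val, _ = split_dataset(ws, cfg, by="subject")
        trained = train_model(build_model(cfg), _xy(train, cfg), _xy(val, cfg), cfg)
        assert trained.best_val_loss == min(h[2] for h in trained.history)


class TestRrFromLabels:
    def test_rising_edge_count(self):
        labels = np.zeros(1800, dtype=int)
        for k in range(15):  # 15 breaths over 60 s
            labels[k * 120: k * 120 + 60] = 1
        est = rr_from_labels(labels, 60.0)
        assert est.valid and est.value == pytest.approx(15.0)

    def test_seven_second_window_scaling(self):
        labels = np.zeros(210, dtype=int)
        labels[30:60] = 1
        labels[130:160] = 1
        est = rr_from_labels(labels, 7.0)
        assert est.value == pytest.approx(60.0 * 2 / 7)

    def test_leading_one_counts(self):
        assert rr_from_labels(np.array([1, 1, 0, 0] * 60), 24.0
                              ).diagnostics["breaths"] == 60

    def test_all_zero_invalid(self):
        est = rr_from_labels(np.zeros(210, dtype=int), 7.0)
        assert not est.valid and est.diagnostics["breaths"] == 0

    def test_ground_truth_labels_recover_exact_rate(self):
        # integer breaths per window: counting is exact
        fs, rr = 30.0, 12.0
        t = np.arange(int(60 * fs)) / fs
        labels = label_breath_phase(np.sin(2 * np.pi * rr / 60.0 * t + 1e-9))
        est = rr_from_labels(labels, 60.0)
        assert est.value == pytest.approx(rr)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ConfigError):
            rr_from_labels(np.array([1, 0, 1]), 0.0)


def test_save_load_roundtrip(tmp_path):
    cfg = ModelConfig(seed=2, epochs=1)
    ws = _dataset(n_subjects=10, seed=2)
    train, val, _ = split_dataset(ws, cfg, by="subject")
    trained = train_model(build_model(cfg), _xy(train, cfg), _xy(val, cfg), cfg)
    path = tmp_path / "model.npz"
    save_model(trained, path)
    loaded = load_model(path)
    assert loaded.config == trained.config
    assert loaded.best_epoch == trained.best_epoch
    x = np.random.default_rng(0).normal(size=(2, 210))
    assert np.array_equal(predict_labels(loaded, x), predict_labels(trained, x))
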