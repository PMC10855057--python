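"""CNN-LSTM breath-phase classifier.

The deep pipeline labels every timestep of a 30 Hz respiratory surrogate
as inhalation (1, signal above zero) or exhalation (0), and derives RR
from the number of inhalation onsets in the window.  The network is a
1-D convolution, max pooling, ReLU, an LSTM (tanh activation), and a
time-distributed softmax over the two classes, trained with plain SGD on
per-timestep cross-entropy.  Classification happens at the pooled
resolution, so reference labels are max-pooled (any-inhale) to the same
rate for the loss.

The network is small enough that it is implemented directly on numpy
arrays with hand-written backpropagation; a fixed seed makes
initialisation, batch shuffling, and therefore whole training runs
bit-reproducible.
"""
from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import (ConfigError, InsufficientDataError, TrainingError,
                   WaveformSignal, WindowSet)
from .estimate import RrEstimate, RR_BAND_BPM

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "label_breath_phase",
    "pool_labels",
    "split_dataset",
    "build_model",
    "train_model",
    "predict_labels",
    "predict_proba",
    "rr_from_labels",
    "save_model",
    "load_model",
]

WINDOW_CHOICES = (120, 150, 180, 210, 240)
SPLIT_CHOICES = ("20:80", "50:50", "80:20")
LABEL_RATE_HZ = 30.0


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults follow the tuned configuration: window of 210 samples (7 s at
    30 Hz), one convolution layer with filter length 1, pool size 2,
    batch size 20, 100 epochs of plain SGD with early stopping, and a
    50:50 train-test split (80/20 train/validation inside the train
    portion).
    """

    window_samples: int = 210
    conv_layers: int = 1
    conv_filters: int = 8
    filter_length: int = 1
    pool_size: int = 2
    lstm_units: int = 64
    batch_size: int = 20
    epochs: int = 100
    learning_rate: float = 0.01
    patience: int = 10
    split_ratio: str = "50:50"
    val_fraction: float = 0.2
    seed: int = 0
    input_rate_hz: float = LABEL_RATE_HZ

    def __post_init__(self) -> None:
        if self.window_samples not in WINDOW_CHOICES:
            raise ConfigError(f"window_samples must be one of {WINDOW_CHOICES}")
        if not 1 <= self.conv_layers <= 3:
            raise ConfigError("conv_layers must be 1-3")
        if not 1 <= self.filter_length <= 5:
            raise ConfigError("filter_length must be 1-5")
        if not 2 <= self.pool_size <= 5:
            raise ConfigError("pool_size must be 2-5")
        if self.split_ratio not in SPLIT_CHOICES:
            raise ConfigError(f"split_ratio must be one of {SPLIT_CHOICES}")
        for name in ("lstm_units", "batch_size", "epochs", "patience", "conv_filters"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        if not self.learning_rate > 0:
            raise ConfigError("learning_rate must be positive")
        if not 0.0 < self.val_fraction < 1.0:
            raise ConfigError("val_fraction must lie in (0, 1)")

    @property
    def pooled_length(self) -> int:
        """Output timesteps: window length floored by the pool size at each
        conv+pool stage (odd windows lose the tail timestep)."""
        n = self.window_samples
        for _ in range(self.conv_layers):
            n //= self.pool_size
        if n < 1:
            raise ConfigError("window too short for this pooling configuration")
        return n

    @property
    def test_fraction(self) -> float:
        return int(self.split_ratio.split(":")[1]) / 100.0


@dataclass
class TrainedModel:
    """Parameters plus the config and training record that produced them."""

    params: dict
    config: ModelConfig
    best_val_loss: float = float("inf")
    best_epoch: int = -1
    history: list = field(default_factory=list)  # (epoch, train_loss, val_loss)


def label_breath_phase(resp: WaveformSignal | np.ndarray) -> np.ndarray:
    """Label every sample: 1 (inhalation) where the signal is above zero,
    0 (exhalation) otherwise — a sample of exactly zero is exhalation."""
    x = resp.samples if isinstance(resp, WaveformSignal) else np.asarray(resp)
    return (x > 0).astype(np.int8)


def pool_labels(labels: np.ndarray, config: ModelConfig) -> np.ndarray:
    """Max-pool reference labels (any-inhale) to the model's pooled
    resolution, truncating the tail like the feature path does."""
    out = np.asarray(labels)
    for _ in range(config.conv_layers):
        t = out.shape[-1] // config.pool_size
        out = out[..., :t * config.pool_size]
        out = out.reshape(*out.shape[:-1], t, config.pool_size).max(axis=-1)
    return out


def split_dataset(windows: WindowSet, config: ModelConfig,
                  by: str = "subject") -> tuple[WindowSet, WindowSet, WindowSet]:
    """Partition windows into train / validation / test sets.

    ``by="subject"`` keeps each subject's windows on one side of the
    train-test divide (no leakage); ``by="window"`` splits windows
    directly, giving exact floor arithmetic on the counts.  The
    train/validation split inside the train portion is always by window.
    Deterministic under ``config.seed``.
    """
    if windows.n_windows < 10:
        raise InsufficientDataError("need at least 10 windows to split")
    if by not in ("subject", "window"):
        raise ConfigError("by must be 'subject' or 'window'")
    rng = np.random.default_rng(config.seed)
    n = windows.n_windows
    n_test = int(np.floor(n * config.test_fraction))
    if by == "window":
        order = rng.permutation(n)
        test_idx = sorted(order[:n_test])
        trainval_idx = sorted(order[n_test:])
    else:
        subjects = list(dict.fromkeys(windows.subject_ids))
        rng.shuffle(subjects)
        test_subjects: set[str] = set()
        count = 0
        for s in subjects:
            if count >= n_test:
                break
            test_subjects.add(s)
            count += sum(1 for t in windows.subject_ids if t == s)
        test_idx = [i for i, s in enumerate(windows.subject_ids) if s in test_subjects]
        trainval_idx = [i for i, s in enumerate(windows.subject_ids) if s not in test_subjects]
    trainval_idx = list(trainval_idx)
    perm = rng.permutation(len(trainval_idx))
    n_train = int(np.floor(len(trainval_idx) * (1.0 - config.val_fraction)))
    train_idx = sorted(trainval_idx[i] for i in perm[:n_train])
    val_idx = sorted(trainval_idx[i] for i in perm[n_train:])
    return windows.subset(train_idx), windows.subset(val_idx), windows.subset(test_idx)


# ---------------------------------------------------------------------------
# network internals

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[-2], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def build_model(config: ModelConfig) -> TrainedModel:
    """Initialise an untrained model (Glorot-uniform weights, forget-gate
    bias 1); identical seeds give identical initial parameters."""
    config.pooled_length  # validates pooling feasibility
    rng = np.random.default_rng(config.seed)
    params: dict = {"conv": [], "lstm": {}, "dense": {}}
    c_in = 1
    for _ in range(config.conv_layers):
        w = _glorot(rng, (config.filter_length, c_in, config.conv_filters))
        params["conv"].append({"W": w, "b": np.zeros(config.conv_filters)})
        c_in = config.conv_filters
    h = config.lstm_units
    params["lstm"] = {
        "Wx": _glorot(rng, (c_in, 4 * h)),
        "Wh": _glorot(rng, (h, 4 * h)),
        "b": np.zeros(4 * h),
    }
    params["lstm"]["b"][h:2 * h] = 1.0  # forget-gate bias
    params["dense"] = {"W": _glorot(rng, (h, 2)), "b": np.zeros(2)}
    return TrainedModel(params=params, config=config)


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    # x: (B, T, Cin); W: (L, Cin, Cout); 'same' padding
    L = W.shape[0]
    pad_l = (L - 1) // 2
    pad_r = L - 1 - pad_l
    xp = np.pad(x, ((0, 0), (pad_l, pad_r), (0, 0)))
    T = x.shape[1]
    y = np.zeros((x.shape[0], T, W.shape[2]))
    for l in range(L):
        y += xp[:, l:l + T, :] @ W[l]
    return y + b, xp


def _conv_backward(dy: np.ndarray, xp: np.ndarray, W: np.ndarray):
    L, _, _ = W.shape
    T = dy.shape[1]
    dW = np.zeros_like(W)
    for l in range(L):
        dW[l] = np.einsum("btc,bto->co", xp[:, l:l + T, :], dy)
    db = dy.sum(axis=(0, 1))
    dxp = np.zeros_like(xp)
    for l in range(L):
        dxp[:, l:l + T, :] += dy @ W[l].T
    pad_l = (L - 1) // 2
    dx = dxp[:, pad_l:pad_l + T, :]
    return dx, dW, db


def _pool_forward(x: np.ndarray, p: int):
    B, T, C = x.shape
    t = T // p
    xr = x[:, :t * p, :].reshape(B, t, p, C)
    arg = xr.argmax(axis=2)
    y = np.take_along_axis(xr, arg[:, :, None, :], axis=2)[:, :, 0, :]
    return y, (arg, x.shape, p)


def _pool_backward(dy: np.ndarray, cache) -> np.ndarray:
    arg, shape, p = cache
    B, T, C = shape
    t = dy.shape[1]
    dxr = np.zeros((B, t, p, C))
    np.put_along_axis(dxr, arg[:, :, None, :], dy[:, :, None, :], axis=2)
    dx = np.zeros(shape)
    dx[:, :t * p, :] = dxr.reshape(B, t * p, C)
    return dx


def _lstm_forward(x: np.ndarray, lstm: dict):
    B, T, _ = x.shape
    H = lstm["Wh"].shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    hs = np.zeros((B, T, H))
    cache = []
    for t in range(T):
        z = x[:, t, :] @ lstm["Wx"] + h @ lstm["Wh"] + lstm["b"]
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h = o * tc
        hs[:, t, :] = h
        cache.append((i, f, g, o, c, tc))
        c = c_new
    return hs, cache


def _lstm_backward(dhs: np.ndarray, x: np.ndarray, hs: np.ndarray,
                   cache, lstm: dict):
    B, T, H = dhs.shape
    dWx = np.zeros_like(lstm["Wx"])
    dWh = np.zeros_like(lstm["Wh"])
    db = np.zeros_like(lstm["b"])
    dx = np.zeros_like(x)
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        i, f, g, o, c_prev, tc = cache[t]
        dh = dhs[:, t, :] + dh_next
        do = dh * tc
        dc = dh * o * (1.0 - tc ** 2) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f
        dz = np.concatenate([
            di * i * (1.0 - i),
            df * f * (1.0 - f),
            dg * (1.0 - g ** 2),
            do * o * (1.0 - o),
        ], axis=1)
        h_prev = hs[:, t - 1, :] if t > 0 else np.zeros((B, H))
        dWx += x[:, t, :].T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dx[:, t, :] = dz @ lstm["Wx"].T
        dh_next = dz @ lstm["Wh"].T
    return dx, dWx, dWh, db


def _forward(params: dict, config: ModelConfig, x: np.ndarray):
    """Full forward pass; returns per-timestep class probabilities and the
    cache needed for backprop.  ``x`` is (B, window_samples)."""
    a = x[:, :, None]
    caches = []
    for layer in params["conv"]:
        y, xp = _conv_forward(a, layer["W"], layer["b"])
        pooled, pc = _pool_forward(y, config.pool_size)
        relu_mask = pooled > 0
        a = pooled * relu_mask
        caches.append((xp, pc, relu_mask))
    hs, lstm_cache = _lstm_forward(a, params["lstm"])
    logits = hs @ params["dense"]["W"] + params["dense"]["b"]
    m = logits.max(axis=-1, keepdims=True)
    ez = np.exp(logits - m)
    probs = ez / ez.sum(axis=-1, keepdims=True)
    return probs, (caches, a, hs, lstm_cache)


def _loss_and_grads(params: dict, config: ModelConfig,
                    x: np.ndarray, labels: np.ndarray):
    """Mean per-timestep cross-entropy and parameter gradients."""
    probs, (caches, a, hs, lstm_cache) = _forward(params, config, x)
    B, T, _ = probs.shape
    onehot = np.zeros_like(probs)
    onehot[..., 1] = labels
    onehot[..., 0] = 1 - labels
    eps = 1e-12
    loss = float(-np.sum(onehot * np.log(probs + eps)) / (B * T))
    dlogits = (probs - onehot) / (B * T)
    grads: dict = {"conv": [], "lstm": {}, "dense": {}}
    grads["dense"]["W"] = np.einsum("bth,btk->hk", hs, dlogits)
    grads["dense"]["b"] = dlogits.sum(axis=(0, 1))
    dhs = dlogits @ params["dense"]["W"].T
    dx, dWx, dWh, db = _lstm_backward(dhs, a, hs, lstm_cache, params["lstm"])
    grads["lstm"] = {"Wx": dWx, "Wh": dWh, "b": db}
    da = dx
    for layer, (xp, pc, relu_mask) in zip(reversed(params["conv"]),
                                          reversed(caches)):
        da = da * relu_mask
        dpooled = _pool_backward(da, pc)
        da, dW, dbc = _conv_backward(dpooled, xp, layer["W"])
        grads["conv"].insert(0, {"W": dW, "b": dbc})
    return loss, grads


def _eval_loss(params: dict, config: ModelConfig,
               x: np.ndarray, labels: np.ndarray, chunk: int = 256) -> float:
    total = 0.0
    n = 0
    for s in range(0, len(x), chunk):
        xb, yb = x[s:s + chunk], labels[s:s + chunk]
        probs, _ = _forward(params, config, xb)
        onehot = np.zeros_like(probs)
        onehot[..., 1] = yb
        onehot[..., 0] = 1 - yb
        total += float(-np.sum(onehot * np.log(probs + 1e-12)))
        n += probs.shape[0] * probs.shape[1]
    return total / n


def train_model(model: TrainedModel,
                train: tuple[np.ndarray, np.ndarray],
                validation: tuple[np.ndarray, np.ndarray],
                config: ModelConfig | None = None,
                log=None) -> TrainedModel:
    """Train with plain SGD on per-timestep cross-entropy.

    ``train`` and ``validation`` are (windows, labels) pairs; labels may
    be at the input rate (they are max-pooled automatically) or already
    pooled.  Validation loss is recorded each epoch; the parameter state
    of the epoch with the lowest validation loss is returned, and training
    stops early after ``patience`` epochs without improvement.  Raises
    :class:`TrainingError` if the loss becomes non-finite.
    """
    config = config or model.config
    x_tr, y_tr = train
    x_va, y_va = validation
    if len(x_tr) == 0 or len(x_va) == 0:
        raise InsufficientDataError("train and validation sets must be non-empty")
    if y_tr.shape[-1] == config.window_samples:
        y_tr = pool_labels(y_tr, config)
        y_va = pool_labels(y_va, config)
    if y_tr.shape[-1] != config.pooled_length:
        raise ConfigError("labels are not aligned to the pooled resolution")

    params = copy.deepcopy(model.params)
    rng = np.random.default_rng(config.seed + 1)
    best = copy.deepcopy(params)
    best_val = float("inf")
    best_epoch = -1
    history = []
    lr = config.learning_rate
    for epoch in range(config.epochs):
        order = rng.permutation(len(x_tr))
        epoch_loss = 0.0
        n_batches = 0
        for s in range(0, len(order), config.batch_size):
            idx = order[s:s + config.batch_size]
            loss, grads = _loss_and_grads(params, config, x_tr[idx], y_tr[idx])
            if not np.isfinite(loss):
                raise TrainingError(f"loss diverged at epoch {epoch}")
            epoch_loss += loss
            n_batches += 1
            for layer, g in zip(params["conv"], grads["conv"]):
                layer["W"] -= lr * g["W"]
                layer["b"] -= lr * g["b"]
            for k in params["lstm"]:
                params["lstm"][k] -= lr * grads["lstm"][k]
            for k in params["dense"]:
                params["dense"][k] -= lr * grads["dense"][k]
        val_loss = _eval_loss(params, config, x_va, y_va)
        if not np.isfinite(val_loss):
            raise TrainingError(f"validation loss diverged at epoch {epoch}")
        history.append((epoch, epoch_loss / max(n_batches, 1), val_loss))
        if log is not None:
            log(epoch, epoch_loss / max(n_batches, 1), val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best = copy.deepcopy(params)
        elif epoch - best_epoch >= config.patience:
            break
    return TrainedModel(params=best, config=config, best_val_loss=best_val,
                        best_epoch=best_epoch, history=history)


def predict_proba(model: TrainedModel, windows: np.ndarray) -> np.ndarray:
    """Per-pooled-timestep class probabilities, shape (B, T', 2)."""
    x = np.atleast_2d(np.asarray(windows, dtype=float))
    if x.shape[1] != model.config.window_samples:
        raise ConfigError(
            f"window length {x.shape[1]} != configured {model.config.window_samples}"
        )
    probs, _ = _forward(model.params, model.config, x)
    return probs


def predict_labels(model: TrainedModel, window: np.ndarray) -> np.ndarray:
    """Binary breath-phase labels at the pooled rate; the argmax tie
    (p0 == p1) breaks to exhalation (0)."""
    probs = predict_proba(model, window)
    labels = (probs[..., 1] > probs[..., 0]).astype(np.int8)
    return labels[0] if np.asarray(window).ndim == 1 else labels


def rr_from_labels(labels: np.ndarray, window_duration_s: float) -> RrEstimate:
    """RR from the number of inhalation onsets in a label sequence.

    An onset is a 0-to-1 transition; a leading 1 counts as one onset.
    RR = 60 * onsets / window duration; estimates outside 4-60
    breaths/min are invalid.
    """
    if window_duration_s <= 0:
        raise ConfigError("window duration must be positive")
    lab = np.asarray(labels).astype(int)
    if lab.size == 0:
        raise InsufficientDataError("empty label sequence")
    breaths = int(lab[0] == 1) + int(np.sum((lab[1:] == 1) & (lab[:-1] == 0)))
    rr = 60.0 * breaths / window_duration_s
    valid = RR_BAND_BPM[0] <= rr <= RR_BAND_BPM[1]
    return RrEstimate(value=rr if valid else None,
                      window=(0.0, window_duration_s), method="cnn_lstm",
                      valid=valid, diagnostics={"breaths": breaths})


def save_model(model: TrainedModel, path) -> None:
    """Serialise a model (parameters + config + training record) to .npz."""
    flat = {}
    for i, layer in enumerate(model.params["conv"]):
        flat[f"conv{i}_W"] = layer["W"]
        flat[f"conv{i}_b"] = layer["b"]
    for k, v in model.params["lstm"].items():
        flat[f"lstm_{k}"] = v
    for k, v in model.params["dense"].items():
        flat[f"dense_{k}"] = v
    meta = {
        "config": asdict(model.config),
        "best_val_loss": model.best_val_loss,
        "best_epoch": model.best_epoch,
        "history": model.history,
    }
    np.savez(path, __meta__=json.dumps(meta), **flat)


def load_model(path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        config = ModelConfig(**meta["config"])
        params: dict = {"conv": [], "lstm": {}, "dense": {}}
        for i in range(config.conv_layers):
            params["conv"].append({"W": data[f"conv{i}_W"], "b": data[f"conv{i}_b"]})
        for k in ("Wx", "Wh", "b"):
            params["lstm"][k] = data[f"lstm_{k}"]
        for k in ("W", "b"):
            params["dense"][k] = data[f"dense_{k}"]
    return TrainedModel(params=params, config=config,
                        best_val_loss=meta["best_val_loss"],
                        best_epoch=meta["best_epoch"],
                        history=[tuple(h) for h in meta["history"]])
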