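"""Compact deep classifiers for 30-s PPG windows and the confidence level.

Two architectures map a window to two-class softmax probabilities (AF vs
SR):

* ``cnn1d`` — exactly 6 stacked 1-D convolution blocks (convolution ->
  ReLU -> temporal downsampling via stride 2), a global average pool, and a
  2-unit softmax head. Learnable kernels convolved along the time axis
  compress the sequence layer by layer.
* ``rnn`` — the window is framed into 1-second tokens fed to a single-layer
  GRU; the final hidden state (the fully compressed features) feeds the
  2-unit softmax head.

Both are deliberately lightweight (well under 10^6 parameters) and train on
CPU. The confidence level (CL) of a diagnosis is 100 x the larger softmax
probability: 50% means the decision was a coin flip, 100% an unequivocal
call. CL is the two-class reliability metric reported alongside every
prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from . import _nn
from .core import AF, SR, Diagnosis, WindowSample
from .errors import InputError, ParameterError

MODEL_FS_HZ = 15.0  # classifier input rate; windows are resampled to this
WINDOW_S = 30.0

_LABEL_TO_INT = {AF: 0, SR: 1}
_INT_TO_LABEL = {0: AF, 1: SR}


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    The 1D-CNN has exactly ``n_conv_layers = 6`` convolution blocks; the RNN
    has a single recurrent layer plus the softmax head. All other values are
    package defaults, overridable per experiment.
    """

    arch: str = "cnn1d"
    n_conv_layers: int = 6
    channels: tuple[int, ...] = (4, 8, 8, 16, 16, 16)
    kernel: int = 7
    stride: int = 2
    rnn_layers: int = 1
    hidden: int = 32
    token_s: float = 1.0  # RNN token length in seconds
    lr: float = 3e-3
    batch_size: int = 128
    epochs: int = 12
    seed: int = 0
    max_train_windows: int | None = 4000  # stratified cap for CPU training
    input_fs: float = MODEL_FS_HZ
    window_s: float = WINDOW_S

    def __post_init__(self) -> None:
        if self.arch not in ("cnn1d", "rnn"):
            raise ParameterError(f"arch must be 'cnn1d' or 'rnn', got {self.arch!r}")
        if self.arch == "cnn1d":
            if self.n_conv_layers != 6:
                raise ParameterError("n_conv_layers: the 1D-CNN has exactly 6 layers")
            if len(self.channels) != self.n_conv_layers:
                raise ParameterError("channels must list one width per conv layer")
        if self.arch == "rnn" and self.rnn_layers != 1:
            raise ParameterError("rnn_layers: only a single recurrent layer is supported")

    @property
    def input_len(self) -> int:
        return int(round(self.window_s * self.input_fs))


class CnnModel:
    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
        self.convs = []
        c_in = 1
        for c_out in config.channels:
            self.convs.append(_nn.Conv1d(c_in, c_out, config.kernel, config.stride, rng))
            c_in = c_out
        self.head = _nn.Dense(c_in, 2, rng)

    @property
    def layers(self):
        return [*self.convs, self.head]

    @property
    def n_params(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (N, L) -> logits (N, 2)
        h = x[:, None, :].astype(_nn.F32)
        for conv in self.convs:
            h = np.maximum(conv.forward(h), 0)
            conv._relu = h
        self._pool_len = h.shape[2]
        pooled = h.mean(axis=2)  # global average pool
        return self.head.forward(pooled)

    def backward(self, dlogits: np.ndarray) -> None:
        dpooled = self.head.backward(dlogits)
        dh = np.repeat(dpooled[:, :, None], self._pool_len, axis=2) / self._pool_len
        for conv in reversed(self.convs):
            dh = conv.backward(dh * (conv._relu > 0))


class RnnModel:
    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 12]))
        self.token_len = int(round(config.token_s * config.input_fs))
        self.gru = _nn.GRU(self.token_len, config.hidden, rng)
        self.head = _nn.Dense(config.hidden, 2, rng)

    @property
    def layers(self):
        return [self.gru, self.head]

    @property
    def n_params(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, length = x.shape
        t_steps = length // self.token_len
        tokens = x[:, : t_steps * self.token_len].reshape(n, t_steps, self.token_len)
        h = self.gru.forward(tokens.astype(_nn.F32))
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.head.backward(dlogits)
        self.gru.backward(dh)


def build_model(config: ModelConfig):
    """Instantiate a classifier from its config (seeded initialization)."""
    model = CnnModel(config) if config.arch == "cnn1d" else RnnModel(config)
    if model.n_params >= 10**6:
        raise ParameterError("channels/hidden: parameter count must stay below 1e6")
    return model


def prepare_input(windows: list[WindowSample], config: ModelConfig | None = None) -> np.ndarray:
    """Resample normalized windows to the classifier input rate.

    Returns a float32 matrix of shape (n_windows, input_len).
    """
    cfg = config or ModelConfig()
    out = np.empty((len(windows), cfg.input_len), dtype=np.float32)
    for i, w in enumerate(windows):
        x = np.asarray(w.samples, dtype=float)
        if w.fs != cfg.input_fs:
            up, down = (np.array([cfg.input_fs, w.fs]) / np.gcd(int(cfg.input_fs), int(w.fs))).astype(int)
            x = sps.resample_poly(x, up, down)
        if len(x) < cfg.input_len:
            raise InputError("window shorter than the configured input length")
        out[i] = x[: cfg.input_len]
    return out


def encode_labels(labels: list[str]) -> np.ndarray:
    return np.array([_LABEL_TO_INT[l] for l in labels], dtype=np.int64)


def train(model, x: np.ndarray, y: np.ndarray, config: ModelConfig | None = None) -> dict:
    """Train by minibatch Adam on softmax cross-entropy.

    When ``max_train_windows`` is set and the training set is larger, a
    label-stratified random subsample (seeded) is used — a CPU-cost control
    that leaves the class balance intact. Returns a history dict with
    per-epoch mean loss.

    Raises on single-class training sets and aborts on non-finite loss.
    """
    cfg = config or model.config
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise InputError("training data must contain both classes")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 21]))
    if cfg.max_train_windows is not None and len(y) > cfg.max_train_windows:
        keep = []
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            n_cls = int(round(cfg.max_train_windows * len(idx) / len(y)))
            keep.append(rng.choice(idx, size=n_cls, replace=False))
        sel = np.sort(np.concatenate(keep))
        x, y = x[sel], y[sel]

    params = [p for layer in model.layers for p in layer.params]
    opt = _nn.Adam(params, lr=cfg.lr)
    history = {"loss": []}
    n = len(y)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for i0 in range(0, n, cfg.batch_size):
            idx = order[i0 : i0 + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward(xb)
            probs = _nn.softmax(logits)
            loss = _nn.cross_entropy(probs, yb)
            if not np.isfinite(loss):
                raise ArithmeticError(f"non-finite training loss ({loss}); aborting")
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits = (dlogits / len(yb)).astype(_nn.F32)
            model.backward(dlogits)
            opt.step([g for layer in model.layers for g in layer.grads])
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)))
    return history


def predict_proba(model, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
    """Softmax probabilities, column order (AF, SR)."""
    out = np.empty((len(x), 2), dtype=float)
    for i0 in range(0, len(x), batch_size):
        out[i0 : i0 + batch_size] = _nn.softmax(model.forward(x[i0 : i0 + batch_size]))
    return out


def confidence_level(p: tuple[float, float] | np.ndarray) -> float:
    """Confidence level of a two-class softmax output, in percent.

    CL = 100 x max(p); ranges from 50 (coin-flip diagnosis) to 100
    (unequivocal); symmetric under swapping the pair.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (2,):
        raise InputError("confidence_level expects a probability pair")
    if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
        raise InputError("probabilities must be non-negative and sum to 1")
    return float(100.0 * p.max())


def diagnose(p_af: float, p_sr: float) -> Diagnosis:
    """Wrap a softmax pair into a Diagnosis (argmax label + CL)."""
    cl = confidence_level((p_af, p_sr))
    return Diagnosis(
        p_af=p_af, p_sr=p_sr, predicted=AF if p_af >= p_sr else SR, cl=cl
    )


def save_model(model, path) -> None:
    """Save weights (.npz) plus a JSON sidecar with the full config."""
    import dataclasses
    import json
    from pathlib import Path

    path = Path(path)
    arrays = {
        f"p{i}": p
        for i, p in enumerate(p for layer in model.layers for p in layer.params)
    }
    np.savez(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(
        json.dumps(dataclasses.asdict(model.config))
    )


def load_model(path):
    """Rebuild a model from :func:`save_model` output."""
    import json
    from pathlib import Path

    path = Path(path)
    cfg_dict = json.loads(path.with_suffix(".json").read_text())
    for key in ("channels",):
        if key in cfg_dict and cfg_dict[key] is not None:
            cfg_dict[key] = tuple(cfg_dict[key])
    model = build_model(ModelConfig(**cfg_dict))
    data = np.load(path.with_suffix(".npz"))
    params = [p for layer in model.layers for p in layer.params]
    for i, p in enumerate(params):
        p[...] = data[f"p{i}"]
    return model


def predict(model, window: WindowSample) -> Diagnosis:
    """Classify one 30-s window."""
    x = prepare_input([window], model.config)
    if x.shape[1] != model.config.input_len:
        raise InputError("window length does not match the trained input length")
    p = predict_proba(model, x)[0]
    return diagnose(float(p[0]), float(p[1]))
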