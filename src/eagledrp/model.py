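"""Dual-branch Conv-LSTM classifier: layers, assembly, training, inference.

Architecture (the tuned preset mirrors the published optimal configuration):
a cell-line branch and an optional drug branch, each a stack of
convolution → activation → max-pool blocks with train-time Gaussian noise;
flattened branch outputs are concatenated, passed through dropout and a
fully-connected layer, reshaped so the flattened feature dimension becomes
the time axis, run through stacked LSTM layers with global max pooling over
time, and classified by a softmax head.

Everything is plain numpy with hand-written backpropagation; training is
mini-batch gradient descent on categorical cross-entropy, fully
deterministic under a seeded generator (which also drives the dropout and
Gaussian-noise layers).

Pooling uses stride = window with the window clamped to the spatial extent
and the remainder dropped (output size max(floor(n/p), 1)); this is the
sizing that reproduces the published shape chain 24→12→6→3→1→1 when a
spatial dimension collapses to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ModelConfig",
    "Model",
    "table_preset",
    "assemble_model",
    "conv_pool_block",
    "train_model",
    "predict_proba",
    "param_count",
]


class ArchitectureError(ValueError):
    """Inconsistent layer configuration; the message names the layer."""


class TrainingDivergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Config

TABLE_PRESET_BLOCKS: list[tuple[int, tuple[int, int], tuple[int, int], str]] = [
    (16, (3, 3), (2, 2), "sigmoid"),
    (32, (3, 3), (2, 2), "sigmoid"),
    (64, (3, 3), (2, 2), "sigmoid"),
    (128, (3, 3), (2, 2), "sigmoid"),
    (256, (3, 3), (2, 2), "sigmoid"),
]


@dataclass
class ModelConfig:
    """Classifier architecture and training hyperparameters."""

    input_shape: tuple[int, int, int] = (1, 256, 24)
    conv_blocks: list[tuple[int, tuple[int, int], tuple[int, int], str]] = field(
        default_factory=lambda: [tuple(b) for b in TABLE_PRESET_BLOCKS]
    )
    drug_input_shape: tuple[int, int, int] | None = None
    drug_conv_blocks: list[tuple[int, tuple[int, int], tuple[int, int], str]] | None = None
    fc_units: int = 278
    dropout_rate: float = 0.25
    lstm_units: int = 128
    lstm_layers: int = 2
    lstm_activation: str = "tanh"
    learning_rate: float = 0.1
    gaussian_noise_sd: float = 0.01
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fc_units < 1 or self.lstm_units < 1 or self.lstm_layers < 1:
            raise ArchitectureError("fc_units, lstm_units and lstm_layers must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ArchitectureError("dropout_rate must lie in [0, 1)")
        if self.n_classes < 2:
            raise ArchitectureError("n_classes must be >= 2")

    def key(self) -> tuple:
        """Hashable identity of the architecture (used for fitness caching)."""
        return (
            self.input_shape,
            tuple((f, tuple(k), tuple(p), a) for f, k, p, a in self.conv_blocks),
            self.drug_input_shape,
            None
            if self.drug_conv_blocks is None
            else tuple((f, tuple(k), tuple(p), a) for f, k, p, a in self.drug_conv_blocks),
            self.fc_units,
            self.dropout_rate,
            self.lstm_units,
            self.lstm_layers,
            self.lstm_activation,
            self.learning_rate,
            self.gaussian_noise_sd,
            self.n_classes,
        )


def table_preset() -> ModelConfig:
    """The published optimal configuration: 5 conv blocks 16→256 filters
    (3×3 kernels, 2×2 pools, sigmoid), fully-connected 278, two LSTM layers
    of 128 tanh units, learning rate 0.1."""
    return ModelConfig()


# ---------------------------------------------------------------------------
# Layers

_ACTIVATIONS = {"sigmoid", "relu", "tanh", "linear"}


def _act(name: str, x: np.ndarray) -> np.ndarray:
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
    if name == "relu":
        return np.maximum(x, 0.0)
    if name == "tanh":
        return np.tanh(x)
    if name == "linear":
        return x
    raise ArchitectureError(f"unknown activation {name!r}")


def _act_grad(name: str, y: np.ndarray) -> np.ndarray:
    """Derivative expressed through the activation output y."""
    if name == "sigmoid":
        return y * (1 - y)
    if name == "relu":
        return (y > 0).astype(float)
    if name == "tanh":
        return 1 - y * y
    return np.ones_like(y)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _same_pads(k: int) -> tuple[int, int]:
    return (k - 1) // 2, k // 2


class Conv2D(Layer):
    """Same-padding convolution, weights (filters, C_in, kh, kw)."""

    def __init__(self, in_channels: int, filters: int, kernel: tuple[int, int], rng):
        super().__init__()
        kh, kw = kernel
        fan_in = in_channels * kh * kw
        fan_out = filters * kh * kw
        r = np.sqrt(6.0 / (fan_in + fan_out))
        self.W = rng.uniform(-r, r, size=(filters, in_channels, kh, kw))
        self.b = np.zeros(filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        F, C, kh, kw = self.W.shape
        if x.shape[1] != C:
            raise ArchitectureError(
                f"Conv2D expects {C} input channels, got {x.shape[1]}"
            )
        ph, pw = _same_pads(kh), _same_pads(kw)
        padded = np.pad(x, ((0, 0), (0, 0), ph, pw))
        self._windows = np.lib.stride_tricks.sliding_window_view(
            padded, (kh, kw), axis=(2, 3)
        )
        self._in_shape = x.shape
        out = np.einsum("bchwij,fcij->bfhw", self._windows, self.W, optimize=True)
        return out + self.b[None, :, None, None]

    def backward(self, gout):
        F, C, kh, kw = self.W.shape
        self.grads[0][...] = np.einsum(
            "bfhw,bchwij->fcij", gout, self._windows, optimize=True
        )
        self.grads[1][...] = gout.sum(axis=(0, 2, 3))
        # input gradient: correlate gout (swapped padding) with flipped kernels
        (ph_lo, ph_hi), (pw_lo, pw_hi) = _same_pads(kh), _same_pads(kw)
        gpad = np.pad(gout, ((0, 0), (0, 0), (ph_hi, ph_lo), (pw_hi, pw_lo)))
        gwin = np.lib.stride_tricks.sliding_window_view(gpad, (kh, kw), axis=(2, 3))
        Wflip = self.W[:, :, ::-1, ::-1]
        return np.einsum("bfhwij,fcij->bchw", gwin, Wflip, optimize=True)


class Activation(Layer):
    def __init__(self, name: str):
        super().__init__()
        if name not in _ACTIVATIONS:
            raise ArchitectureError(f"unknown activation {name!r}")
        self.name = name

    def forward(self, x, train, rng):
        self._y = _act(self.name, x)
        return self._y

    def backward(self, gout):
        return gout * _act_grad(self.name, self._y)


class MaxPool2D(Layer):
    """Valid pooling, stride = window, window clamped to the spatial extent.

    Output size per dimension: max(floor(n / p), 1).
    """

    def __init__(self, pool: tuple[int, int]):
        super().__init__()
        self.pool = tuple(pool)
        if self.pool[0] < 1 or self.pool[1] < 1:
            raise ArchitectureError("pool window must be positive")

    def forward(self, x, train, rng):
        B, C, H, W = x.shape
        ph, pw = self.pool
        if ph > H and pw > W:
            raise ArchitectureError(
                f"pool window {self.pool} larger than both spatial dims {(H, W)}"
            )
        eh, ew = min(ph, H), min(pw, W)
        H2, W2 = H // eh, W // ew
        self._geom = (x.shape, eh, ew, H2, W2)
        crop = x[:, :, : H2 * eh, : W2 * ew]
        win = crop.reshape(B, C, H2, eh, W2, ew).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(B, C, H2, W2, eh * ew)
        self._arg = win.argmax(axis=-1)
        return win.max(axis=-1)

    def backward(self, gout):
        (B, C, H, W), eh, ew, H2, W2 = self._geom
        gwin = np.zeros((B, C, H2, W2, eh * ew))
        np.put_along_axis(gwin, self._arg[..., None], gout[..., None], axis=-1)
        gcrop = gwin.reshape(B, C, H2, W2, eh, ew).transpose(0, 1, 2, 4, 3, 5)
        gcrop = gcrop.reshape(B, C, H2 * eh, W2 * ew)
        gx = np.zeros((B, C, H, W))
        gx[:, :, : H2 * eh, : W2 * ew] = gcrop
        return gx


class GaussianNoise(Layer):
    """Additive Gaussian noise, active only during training."""

    def __init__(self, sd: float):
        super().__init__()
        self.sd = sd

    def forward(self, x, train, rng):
        if train and self.sd > 0:
            return x + self.sd * rng.standard_normal(x.shape)
        return x

    def backward(self, gout):
        return gout


class Dropout(Layer):
    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate

    def forward(self, x, train, rng):
        if train and self.rate > 0:
            self._mask = (rng.random(x.shape) >= self.rate) / (1 - self.rate)
            return x * self._mask
        self._mask = None
        return x

    def backward(self, gout):
        return gout if self._mask is None else gout * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng):
        super().__init__()
        r = np.sqrt(6.0 / (in_features + out_features))
        self.W = rng.uniform(-r, r, size=(out_features, in_features))
        self.b = np.zeros(out_features)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        if x.shape[1] != self.W.shape[1]:
            raise ArchitectureError(
                f"Dense expects {self.W.shape[1]} inputs, got {x.shape[1]}"
            )
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, gout):
        self.grads[0][...] = gout.T @ self._x
        self.grads[1][...] = gout.sum(axis=0)
        return gout @ self.W


class ToSequence(Layer):
    """Treat the flattened feature dimension as the time axis: (B, F) → (B, F, 1)."""

    def forward(self, x, train, rng):
        return x[:, :, None]

    def backward(self, gout):
        return gout[:, :, 0]


class LSTM(Layer):
    """Standard LSTM over (B, T, D) sequences, returning the full (B, T, H)
    hidden sequence.  Gates use sigmoid; candidate/output use tanh."""

    def __init__(self, input_size: int, hidden: int, rng):
        super().__init__()
        r = np.sqrt(6.0 / (input_size + hidden))
        self.Wx = rng.uniform(-r, r, size=(4 * hidden, input_size))
        self.Wh = rng.uniform(-r, r, size=(4 * hidden, hidden))
        self.b = np.zeros(4 * hidden)
        self.hidden = hidden
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(self.Wx), np.zeros_like(self.Wh), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        B, T, D = x.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._cache = []
        self._x = x
        out = np.empty((B, T, H))
        for t in range(T):
            a = x[:, t] @ self.Wx.T + h @ self.Wh.T + self.b
            i = _act("sigmoid", a[:, :H])
            f = _act("sigmoid", a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _act("sigmoid", a[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            self._cache.append((h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
            out[:, t] = h
        return out

    def backward(self, gout):
        B, T, D = self._x.shape
        H = self.hidden
        gWx = np.zeros_like(self.Wx)
        gWh = np.zeros_like(self.Wh)
        gb = np.zeros_like(self.b)
        gx = np.zeros_like(self._x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tanh_c = self._cache[t]
            dh = gout[:, t] + dh_next
            do = dh * tanh_c
            dc = dc_next + dh * o * (1 - tanh_c * tanh_c)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            gWx += da.T @ self._x[:, t]
            gWh += da.T @ h_prev
            gb += da.sum(axis=0)
            gx[:, t] = da @ self.Wx
            dh_next = da @ self.Wh
        self.grads[0][...] = gWx
        self.grads[1][...] = gWh
        self.grads[2][...] = gb
        return gx


class SequenceNoise(GaussianNoise):
    pass


class GlobalMaxPoolTime(Layer):
    """Global max pooling over the time axis: (B, T, H) → (B, H)."""

    def forward(self, x, train, rng):
        self._shape = x.shape
        self._arg = x.argmax(axis=1)
        return x.max(axis=1)

    def backward(self, gout):
        gx = np.zeros(self._shape)
        np.put_along_axis(gx, self._arg[:, None, :], gout[:, None, :], axis=1)
        return gx


# ---------------------------------------------------------------------------
# Functional conv block (used standalone and by the assembler shape logic)


def conv_pool_output_shape(
    in_shape: tuple[int, int, int],
    filters: int,
    kernel: tuple[int, int],
    pool: tuple[int, int],
) -> tuple[int, int, int]:
    _, H, W = in_shape
    eh, ew = min(pool[0], H), min(pool[1], W)
    return (filters, max(H // eh, 1), max(W // ew, 1))


def conv_pool_block(
    X: np.ndarray,
    filters: int,
    kernel: tuple[int, int],
    pool: tuple[int, int],
    activation: str,
    weights: np.ndarray | None = None,
    bias: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """One convolution → activation → max-pool block on a single (C, H, W)
    tensor.  Weights default to a seeded Glorot draw; pass explicit
    ``weights``/``bias`` for reproducible kernels (e.g. an identity)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ArchitectureError("input must be (channels, H, W)")
    C, H, W = X.shape
    kh, kw = kernel
    rng = np.random.default_rng(seed)
    conv = Conv2D(C, filters, kernel, rng)
    if weights is not None:
        conv.W[...] = weights
    if bias is not None:
        conv.b[...] = bias
    out = conv.forward(X[None], train=False, rng=rng)
    out = _act(activation, out)
    pool_layer = MaxPool2D(pool)
    return pool_layer.forward(out, train=False, rng=rng)[0]


# ---------------------------------------------------------------------------
# Model


class Model:
    """Branch stacks + trunk with explicit forward/backward passes."""

    def __init__(
        self,
        cfg: ModelConfig,
        branches: list[list[Layer]],
        branch_flat_sizes: list[int],
        trunk: list[Layer],
        conv_shapes: list[list[tuple[int, int, int]]],
    ):
        self.cfg = cfg
        self.branches = branches
        self.branch_flat_sizes = branch_flat_sizes
        self.trunk = trunk
        self.conv_shapes = conv_shapes  # per branch, shape after each conv block

    def layers(self):
        for stack in self.branches:
            yield from stack
        yield from self.trunk

    def forward(
        self,
        inputs: Sequence[np.ndarray],
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        rng = np.random.default_rng() if rng is None else rng
        if len(inputs) != len(self.branches):
            raise ArchitectureError(
                f"model has {len(self.branches)} branches, got {len(inputs)} inputs"
            )
        outs = []
        for x, stack in zip(inputs, self.branches):
            h = np.asarray(x, dtype=float)
            for layer in stack:
                h = layer.forward(h, train, rng)
            outs.append(h)
        self._split = [o.shape[1] for o in outs]
        h = np.concatenate(outs, axis=1) if len(outs) > 1 else outs[0]
        for layer in self.trunk:
            h = layer.forward(h, train, rng)
        return h  # logits

    def backward(self, glogits: np.ndarray) -> None:
        g = glogits
        for layer in reversed(self.trunk):
            g = layer.backward(g)
        pieces = np.split(g, np.cumsum(self._split)[:-1], axis=1)
        for piece, stack in zip(pieces, self.branches):
            gb = piece
            for layer in reversed(stack):
                gb = layer.backward(gb)

    def sgd_step(self, lr: float) -> None:
        for layer in self.layers():
            for p, g in zip(layer.params, layer.grads):
                p -= lr * g


def param_count(model: Model) -> int:
    return sum(p.size for layer in model.layers() for p in layer.params)


def _build_branch(
    input_shape: tuple[int, int, int],
    blocks: list[tuple[int, tuple[int, int], tuple[int, int], str]],
    noise_sd: float,
    rng,
) -> tuple[list[Layer], int, list[tuple[int, int, int]]]:
    layers: list[Layer] = []
    shape = tuple(input_shape)
    shapes = []
    for bi, (filters, kernel, pool, activation) in enumerate(blocks):
        # same padding keeps convolution well-defined even when a spatial
        # dim has collapsed below the kernel size (e.g. width 1 under 3×3)
        if pool[0] > shape[1] and pool[1] > shape[2]:
            raise ArchitectureError(
                f"conv block {bi + 1}: pool {pool} larger than both spatial dims {shape[1:]}"
            )
        layers.append(Conv2D(shape[0], filters, tuple(kernel), rng))
        layers.append(Activation(activation))
        layers.append(MaxPool2D(tuple(pool)))
        layers.append(GaussianNoise(noise_sd))
        shape = conv_pool_output_shape(shape, filters, tuple(kernel), tuple(pool))
        shapes.append(shape)
    layers.append(Flatten())
    return layers, int(np.prod(shape)), shapes


def assemble_model(cfg: ModelConfig) -> Model:
    """Build the classifier from its configuration.

    The flatten size is computed from the actual conv-block output shapes
    (the published table prints 1536 where the preceding shape flattens to
    2048; the computed value is used).  Weight initialization is a seeded
    Glorot draw, so identical configs give identical models.
    """
    rng = np.random.default_rng(cfg.seed)
    branches = []
    flat_sizes = []
    conv_shapes = []
    stack, flat, shapes = _build_branch(
        cfg.input_shape, cfg.conv_blocks, cfg.gaussian_noise_sd, rng
    )
    branches.append(stack)
    flat_sizes.append(flat)
    conv_shapes.append(shapes)
    if cfg.drug_input_shape is not None:
        blocks = cfg.drug_conv_blocks if cfg.drug_conv_blocks is not None else cfg.conv_blocks
        stack, flat, shapes = _build_branch(
            cfg.drug_input_shape, blocks, cfg.gaussian_noise_sd, rng
        )
        branches.append(stack)
        flat_sizes.append(flat)
        conv_shapes.append(shapes)

    trunk: list[Layer] = [
        Dropout(cfg.dropout_rate),
        Dense(sum(flat_sizes), cfg.fc_units, rng),
        ToSequence(),
    ]
    in_size = 1
    for _ in range(cfg.lstm_layers):
        trunk.append(LSTM(in_size, cfg.lstm_units, rng))
        trunk.append(SequenceNoise(cfg.gaussian_noise_sd))
        in_size = cfg.lstm_units
    trunk.append(GlobalMaxPoolTime())
    trunk.append(Dense(cfg.lstm_units, cfg.n_classes, rng))
    return Model(cfg, branches, flat_sizes, trunk, conv_shapes)


# ---------------------------------------------------------------------------
# Training and inference


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def _as_inputs(features) -> tuple[np.ndarray, ...]:
    if isinstance(features, (tuple, list)):
        return tuple(np.asarray(f, dtype=float) for f in features)
    return (np.asarray(features, dtype=float),)


def cross_entropy(model: Model, features, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy in inference mode (noise/dropout off)."""
    probs = predict_proba(model, features)
    p = np.clip(probs[np.arange(len(labels)), labels], 1e-12, 1.0)
    return float(-np.log(p).mean())


def train_model(
    model: Model,
    features,
    labels: np.ndarray,
    epochs: int,
    learning_rate: float | None = None,
    rng: np.random.Generator | None = None,
    batch_size: int = 32,
) -> tuple[Model, list[float]]:
    """Mini-batch gradient descent on categorical cross-entropy.

    The per-epoch history records the full-data loss in inference mode
    (noise and dropout disabled), so a zero learning rate yields a constant
    history.  Deterministic given the seeded generator, which also drives
    the Gaussian-noise and dropout layers.
    """
    rng = np.random.default_rng() if rng is None else rng
    lr = model.cfg.learning_rate if learning_rate is None else learning_rate
    inputs = _as_inputs(features)
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    n_classes = model.cfg.n_classes
    onehot = np.eye(n_classes)[labels]
    history = [cross_entropy(model, features, labels)]
    for epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            batch = [x[idx] for x in inputs]
            logits = model.forward(batch, train=True, rng=rng)
            probs = _softmax(logits)
            model.backward((probs - onehot[idx]) / len(idx))
            model.sgd_step(lr)
        loss = cross_entropy(model, features, labels)
        if not np.isfinite(loss):
            raise TrainingDivergenceError(f"non-finite loss at epoch {epoch}")
        history.append(loss)
    return model, history


def predict_proba(model: Model, features) -> np.ndarray:
    """Class probabilities; rows sum to 1.  Inference is deterministic
    (Gaussian noise and dropout disabled)."""
    logits = model.forward(_as_inputs(features), train=False)
    return _softmax(logits)
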