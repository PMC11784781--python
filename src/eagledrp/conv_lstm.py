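"""The ConvLSTM cell: convolutional gate pre-activations with peephole terms.

Gate equations for input gate J, forget gate K and output gate L at step t
(state tensors Z = cell state, C = memory output, input Y):

    J_t = σ[(δ_J^Y ∗ Y_t) + (δ_J^C ∗ C_{t−1}) + (δ_J^Z ∘ Z_{t−1}) + η^J]
    K_t, L_t analogously with their own kernels/biases
    Z̃_t = tanh[(δ_F^Y ∗ Y_t) + (δ_F^C ∗ C_{t−1}) + η^F]
    Z_t = K_t ∘ Z_{t−1} + J_t ∘ Z̃_t
    C_t = L_t ∘ tanh(Z_t)

∗ is a same-padding 2-D convolution, ∘ the Hadamard (elementwise) product;
the Hadamard δ^Z terms are peephole connections on the cell state.  The
output layer maps the flattened memory output through a dense weight and a
softmax, G = softmax(δ · C + η).

Tensors are laid out channels-first, (channels, height, width).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConvLSTMParams",
    "ConvLSTMState",
    "conv2d_same",
    "zero_state",
    "random_params",
    "cell_step",
    "sequence_forward",
    "output_layer",
]


def conv2d_same(x: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Same-padding 2-D cross-correlation.

    ``x``: (C_in, H, W); ``kernels``: (C_out, C_in, kh, kw) → (C_out, H, W).
    Even kernel sizes pad one less on the leading side.
    """
    c_in, H, W = x.shape
    c_out, c_in2, kh, kw = kernels.shape
    if c_in != c_in2:
        raise ValueError(f"input has {c_in} channels, kernels expect {c_in2}")
    ph_lo, ph_hi = (kh - 1) // 2, kh // 2
    pw_lo, pw_hi = (kw - 1) // 2, kw // 2
    padded = np.pad(x, ((0, 0), (ph_lo, ph_hi), (pw_lo, pw_hi)))
    windows = np.lib.stride_tricks.sliding_window_view(padded, (kh, kw), axis=(1, 2))
    # windows: (C_in, H, W, kh, kw)
    return np.einsum("chwij,ocij->ohw", windows, kernels, optimize=True)


@dataclass
class ConvLSTMState:
    """Cell state Z and memory output C; identical shapes (C, H, W)."""

    Z: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        if self.Z.shape != self.C.shape:
            raise ValueError("Z and C must share a shape")


@dataclass
class ConvLSTMParams:
    """All gate kernels, peephole tensors and biases of one ConvLSTM cell.

    Per gate G ∈ {J, K, L}: input kernel ``w_y[G]`` (C_state, C_in, kh, kw),
    memory kernel ``w_c[G]`` (C_state, C_state, kh, kw), peephole tensor
    ``w_z[G]`` shaped like the state, bias ``bias[G]`` per state channel.
    The candidate node F has kernels ``w_y['F']``, ``w_c['F']`` and bias
    ``bias['F']`` but no peephole.  ``w_out``/``b_out`` form the dense
    softmax output layer over the flattened memory output.
    """

    w_y: dict[str, np.ndarray]
    w_c: dict[str, np.ndarray]
    w_z: dict[str, np.ndarray]
    bias: dict[str, np.ndarray]
    w_out: np.ndarray | None = None
    b_out: np.ndarray | None = None

    def __post_init__(self) -> None:
        for g in ("J", "K", "L", "F"):
            if g not in self.w_y or g not in self.w_c or g not in self.bias:
                raise ValueError(f"missing parameters for gate {g}")
        for g in ("J", "K", "L"):
            if g not in self.w_z:
                raise ValueError(f"missing peephole tensor for gate {g}")

    @property
    def state_shape(self) -> tuple[int, int, int]:
        return self.w_z["J"].shape


def zero_state(shape: tuple[int, int, int]) -> ConvLSTMState:
    return ConvLSTMState(Z=np.zeros(shape), C=np.zeros(shape))


def random_params(
    input_channels: int,
    state_shape: tuple[int, int, int],
    kernel: tuple[int, int] = (3, 3),
    n_classes: int | None = None,
    rng: np.random.Generator | None = None,
    scale: float = 0.1,
) -> ConvLSTMParams:
    """Small random cell parameters for a given input/state geometry."""
    rng = np.random.default_rng() if rng is None else rng
    cs = state_shape[0]
    kh, kw = kernel

    def k_in() -> np.ndarray:
        return scale * rng.standard_normal((cs, input_channels, kh, kw))

    def k_state() -> np.ndarray:
        return scale * rng.standard_normal((cs, cs, kh, kw))

    params = ConvLSTMParams(
        w_y={g: k_in() for g in ("J", "K", "L", "F")},
        w_c={g: k_state() for g in ("J", "K", "L", "F")},
        w_z={g: scale * rng.standard_normal(state_shape) for g in ("J", "K", "L")},
        bias={g: np.zeros(cs) for g in ("J", "K", "L", "F")},
    )
    if n_classes is not None:
        flat = int(np.prod(state_shape))
        params.w_out = scale * rng.standard_normal((n_classes, flat))
        params.b_out = np.zeros(n_classes)
    return params


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def cell_step(
    Y: np.ndarray, prev: ConvLSTMState, params: ConvLSTMParams
) -> tuple[ConvLSTMState, dict[str, np.ndarray]]:
    """One ConvLSTM step; returns the new state and the gate tensors J, K, L.

    Gate outputs lie in (0, 1); the memory output C lies in (−1, 1).
    """
    if Y.ndim != 3:
        raise ValueError("input must be a (channels, H, W) tensor")
    gates: dict[str, np.ndarray] = {}
    for g in ("J", "K", "L"):
        pre = (
            conv2d_same(Y, params.w_y[g])
            + conv2d_same(prev.C, params.w_c[g])
            + params.w_z[g] * prev.Z
            + params.bias[g][:, None, None]
        )
        gates[g] = _sigmoid(pre)
    candidate = np.tanh(
        conv2d_same(Y, params.w_y["F"])
        + conv2d_same(prev.C, params.w_c["F"])
        + params.bias["F"][:, None, None]
    )
    Z = gates["K"] * prev.Z + gates["J"] * candidate
    C = gates["L"] * np.tanh(Z)
    return ConvLSTMState(Z=Z, C=C), gates


def sequence_forward(
    inputs: list[np.ndarray] | np.ndarray,
    init: ConvLSTMState,
    params: ConvLSTMParams,
) -> list[np.ndarray]:
    """Iterate :func:`cell_step` over a sequence; returns all memory outputs C_t."""
    if len(inputs) == 0:
        raise ValueError("sequence must contain at least one step")
    state = init
    outputs = []
    for Y in inputs:
        state, _ = cell_step(Y, state, params)
        outputs.append(state.C)
    return outputs


def output_layer(C: np.ndarray, params: ConvLSTMParams) -> np.ndarray:
    """Class probabilities softmax(δ·vec(C) + η); sums to 1."""
    if params.w_out is None or params.b_out is None:
        raise ValueError("params carry no output layer")
    flat = np.asarray(C, dtype=float).ravel()
    if flat.size != params.w_out.shape[1]:
        raise ValueError(
            f"flattened state has {flat.size} entries, output layer expects "
            f"{params.w_out.shape[1]}"
        )
    logits = params.w_out @ flat + params.b_out
    logits -= logits.max()
    ex = np.exp(logits)
    return ex / ex.sum()
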