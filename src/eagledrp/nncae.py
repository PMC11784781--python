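"""L1/L2 non-negativity-constrained sparse autoencoder (NNCAE).

A single-hidden-layer autoencoder whose cost is

    J(W, b) = J_AE + β · Σ_j KL(p ‖ ρ̂_j) + Σ_l Σ_ij f_{L1/L2}(w_ij^l)

where J_AE is the mean squared reconstruction error over the batch,
KL(p ‖ ρ̂_j) the Bernoulli Kullback–Leibler sparsity penalty between the
target activation rate p and the batch-mean activation ρ̂_j of hidden unit
j, and f_{L1/L2} a composite weight-decay term applied only to *negative*
weights:

    f(w) = α1 · ⌈(w, k) + (α2 / 2) · w²    if w < 0,    0 if w ≥ 0

with ⌈(·, k) the smoothed L1 norm (quadratic inside a ball of radius k,
restoring differentiability at the origin).  Penalizing negative weights in
both layers pushes the weight distribution toward nonnegativity, giving
part-based, additive representations in the spirit of non-negative matrix
factorization.  Training is plain mini-batch gradient descent with learning
rate ε on the exact analytic gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NNCAEConfig",
    "NNCAEParams",
    "smoothed_l1",
    "smoothed_l1_grad",
    "nonneg_penalty",
    "nonneg_penalty_grad",
    "encode",
    "decode",
    "reconstruction_cost",
    "sparsity_divergence",
    "total_cost",
    "cost_gradients",
    "train_nncae",
    "extract_features",
]

_ACT_CLIP = 1e-12  # keeps mean activations strictly inside (0, 1) for the KL term


class TrainingDivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class NNCAEConfig:
    """Hyperparameters of the NNCAE.

    ``sparsity_target`` (p), ``sparsity_weight`` (β), ``alpha1``/``alpha2``
    (negative-weight penalty factors), ``smoothing_k`` (smoothed-L1 radius)
    and ``learning_rate`` (ε) have no values prescribed by theory — they are
    set experimentally; the defaults here are the package's working set for
    unit-interval inputs.
    """

    n_hidden: int = 16
    sparsity_target: float = 0.05
    sparsity_weight: float = 3.0
    alpha1: float = 3e-4
    alpha2: float = 3e-3
    learning_rate: float = 0.1
    smoothing_k: float = 0.1
    epochs: int = 200
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.smoothing_k <= 0:
            raise ValueError("smoothing_k must be > 0")
        if not 0 < self.sparsity_target < 1:
            raise ValueError("sparsity_target must lie in (0, 1)")
        for name in ("sparsity_weight", "alpha1", "alpha2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_hidden < 1 or self.epochs < 0 or self.batch_size < 1:
            raise ValueError("n_hidden/epochs/batch_size out of range")


@dataclass
class NNCAEParams:
    """Encoder/decoder weights and biases.

    ``W1``: (n_hidden, n_features) encoder weights; ``W2``: (n_features,
    n_hidden) decoder weights; ``b_x``: encoder bias; ``b_h``: decoder bias.
    Weights are untied; the composite penalty applies to both layers.
    """

    W1: np.ndarray
    W2: np.ndarray
    b_x: np.ndarray
    b_h: np.ndarray

    def __post_init__(self) -> None:
        h, n = self.W1.shape
        if self.W2.shape != (n, h):
            raise ValueError("W2 must have shape (n_features, n_hidden)")
        if self.b_x.shape != (h,) or self.b_h.shape != (n,):
            raise ValueError("bias shapes inconsistent with weights")
        for arr in (self.W1, self.W2, self.b_x, self.b_h):
            if not np.isfinite(arr).all():
                raise ValueError("parameters must be finite")

    def copy(self) -> "NNCAEParams":
        return NNCAEParams(self.W1.copy(), self.W2.copy(), self.b_x.copy(), self.b_h.copy())


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# Smoothed L1 norm and the composite negative-weight penalty


def smoothed_l1(z: np.ndarray | float, k: float) -> float:
    """Smoothed L1 norm ⌈(z, k) of a finite-dimensional vector (or scalar).

    Returns ‖z‖ when ‖z‖ > k, else ‖z‖²/(2k) + k/2; the two branches agree
    at ‖z‖ = k, so the function is continuous and differentiable everywhere.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    norm = float(np.linalg.norm(np.atleast_1d(np.asarray(z, dtype=float))))
    if norm > k:
        return norm
    return norm * norm / (2.0 * k) + k / 2.0


def smoothed_l1_grad(z: np.ndarray | float, k: float) -> np.ndarray | float:
    """Gradient of the smoothed L1 norm: z/‖z‖ outside the ball, z/k inside."""
    if k <= 0:
        raise ValueError("k must be > 0")
    scalar = np.isscalar(z)
    arr = np.atleast_1d(np.asarray(z, dtype=float))
    norm = float(np.linalg.norm(arr))
    grad = arr / norm if norm > k else arr / k
    return float(grad[0]) if scalar and arr.size == 1 else grad


def _penalty_elementwise(W: np.ndarray, cfg: NNCAEConfig) -> np.ndarray:
    """f_{L1/L2} applied per scalar weight: zero on w >= 0."""
    absw = np.abs(W)
    k = cfg.smoothing_k
    sl1 = np.where(absw > k, absw, absw * absw / (2.0 * k) + k / 2.0)
    pen = cfg.alpha1 * sl1 + 0.5 * cfg.alpha2 * W * W
    return np.where(W < 0, pen, 0.0)


def _penalty_grad_elementwise(W: np.ndarray, cfg: NNCAEConfig) -> np.ndarray:
    absw = np.abs(W)
    k = cfg.smoothing_k
    sl1g = np.where(absw > k, np.sign(W), W / k)
    grad = cfg.alpha1 * sl1g + cfg.alpha2 * W
    return np.where(W < 0, grad, 0.0)


def nonneg_penalty(w: float | np.ndarray, cfg: NNCAEConfig) -> float | np.ndarray:
    """Composite L1/L2 decay of a weight: 0 for w ≥ 0, else α1·⌈(w,k) + (α2/2)·w²."""
    arr = np.asarray(w, dtype=float)
    out = _penalty_elementwise(arr, cfg)
    return float(out) if np.isscalar(w) or arr.ndim == 0 else out


def nonneg_penalty_grad(w: float | np.ndarray, cfg: NNCAEConfig) -> float | np.ndarray:
    """Derivative g(w) of the composite decay: 0 for w ≥ 0, else α1·∇⌈ + α2·w."""
    arr = np.asarray(w, dtype=float)
    out = _penalty_grad_elementwise(arr, cfg)
    return float(out) if np.isscalar(w) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# Forward maps and cost


def encode(X: np.ndarray, params: NNCAEParams) -> np.ndarray:
    """Hidden activations σ(W1·x + b_x) per sample; values in (0, 1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.W1.shape[1]:
        raise ValueError(f"expected {params.W1.shape[1]} features, got {X.shape[1]}")
    return _sigmoid(X @ params.W1.T + params.b_x)


def decode(H: np.ndarray, params: NNCAEParams) -> np.ndarray:
    """Reconstruction σ(W2·h + b_h) per hidden code."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    if H.shape[1] != params.W2.shape[1]:
        raise ValueError(f"expected {params.W2.shape[1]} hidden units, got {H.shape[1]}")
    return _sigmoid(H @ params.W2.T + params.b_h)


def reconstruction_cost(X: np.ndarray, params: NNCAEParams) -> float:
    """Mean squared reconstruction error (1/m)·Σ_k ‖x̂_k − x_k‖²."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 1 or X.size == 0:
        raise ValueError("batch must contain at least one sample")
    Xhat = decode(encode(X, params), params)
    return float(np.sum((Xhat - X) ** 2) / X.shape[0])


def sparsity_divergence(mean_activations: np.ndarray, p: float) -> float:
    """Bernoulli KL divergence Σ_j KL(p ‖ ρ̂_j); zero iff every ρ̂_j = p."""
    rho = np.asarray(mean_activations, dtype=float)
    if np.any(rho <= 0) or np.any(rho >= 1):
        raise ValueError("mean activations must lie strictly in (0, 1)")
    return float(np.sum(p * np.log(p / rho) + (1 - p) * np.log((1 - p) / (1 - rho))))


def total_cost(X: np.ndarray, params: NNCAEParams, cfg: NNCAEConfig) -> float:
    """Full NNCAE objective: reconstruction + β·KL sparsity + weight penalties."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 1:
        raise ValueError("batch must contain at least one sample")
    H = encode(X, params)
    Xhat = decode(H, params)
    recon = float(np.sum((Xhat - X) ** 2) / X.shape[0])
    rho = np.clip(H.mean(axis=0), _ACT_CLIP, 1 - _ACT_CLIP)
    kl = sparsity_divergence(rho, cfg.sparsity_target)
    pen = float(
        _penalty_elementwise(params.W1, cfg).sum() + _penalty_elementwise(params.W2, cfg).sum()
    )
    return recon + cfg.sparsity_weight * kl + pen


def cost_gradients(X: np.ndarray, params: NNCAEParams, cfg: NNCAEConfig) -> NNCAEParams:
    """Exact analytic gradient of :func:`total_cost` w.r.t. every parameter.

    Backpropagation through the sigmoid encoder/decoder, the β-weighted KL
    term (which couples samples through the batch-mean activation), and the
    composite penalty g(w) on both weight layers.  Biases carry no penalty
    term.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m = X.shape[0]
    if m < 1:
        raise ValueError("batch must contain at least one sample")
    H = encode(X, params)  # (m, h)
    Xhat = decode(H, params)  # (m, n)

    delta_out = (2.0 / m) * (Xhat - X) * Xhat * (1 - Xhat)  # (m, n)
    gW2 = delta_out.T @ H + _penalty_grad_elementwise(params.W2, cfg)
    gb_h = delta_out.sum(axis=0)

    dH = delta_out @ params.W2  # (m, h)
    rho = H.mean(axis=0)
    rho_c = np.clip(rho, _ACT_CLIP, 1 - _ACT_CLIP)
    p = cfg.sparsity_target
    dkl_drho = np.where(
        (rho > _ACT_CLIP) & (rho < 1 - _ACT_CLIP),
        -p / rho_c + (1 - p) / (1 - rho_c),
        0.0,  # clipped activations are flat w.r.t. parameters
    )
    dH += cfg.sparsity_weight * dkl_drho / m  # broadcast over samples

    delta_hidden = dH * H * (1 - H)  # (m, h)
    gW1 = delta_hidden.T @ X + _penalty_grad_elementwise(params.W1, cfg)
    gb_x = delta_hidden.sum(axis=0)
    return NNCAEParams(W1=gW1, W2=gW2, b_x=gb_x, b_h=gb_h)


# ---------------------------------------------------------------------------
# Training


def init_params(n_features: int, cfg: NNCAEConfig, rng: np.random.Generator) -> NNCAEParams:
    """Glorot-uniform initialization; biases start at zero."""
    h = cfg.n_hidden
    r1 = np.sqrt(6.0 / (n_features + h))
    return NNCAEParams(
        W1=rng.uniform(-r1, r1, size=(h, n_features)),
        W2=rng.uniform(-r1, r1, size=(n_features, h)),
        b_x=np.zeros(h),
        b_h=np.zeros(n_features),
    )


def train_nncae(X: np.ndarray, cfg: NNCAEConfig) -> tuple[NNCAEParams, list[float]]:
    """Mini-batch gradient descent on the NNCAE cost.

    Returns the trained parameters and the per-epoch full-data total cost
    (entry 0 is the cost before any update).  Deterministic given
    ``cfg.seed``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.isfinite(X).all():
        raise ValueError("training data must be finite (impute first)")
    rng = np.random.default_rng(cfg.seed)
    params = init_params(X.shape[1], cfg, rng)
    m = X.shape[0]
    history = [total_cost(X, params, cfg)]
    for epoch in range(cfg.epochs):
        order = rng.permutation(m)
        for start in range(0, m, cfg.batch_size):
            batch = X[order[start : start + cfg.batch_size]]
            grads = cost_gradients(batch, params, cfg)
            params.W1 -= cfg.learning_rate * grads.W1
            params.W2 -= cfg.learning_rate * grads.W2
            params.b_x -= cfg.learning_rate * grads.b_x
            params.b_h -= cfg.learning_rate * grads.b_h
        loss = total_cost(X, params, cfg)
        if not np.isfinite(loss):
            raise TrainingDivergenceError(f"non-finite loss at epoch {epoch}")
        history.append(loss)
    return params, history


def extract_features(X: np.ndarray, params: NNCAEParams) -> np.ndarray:
    """Encoded representation fed to the downstream classifier (= encode)."""
    return encode(X, params)
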