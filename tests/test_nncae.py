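import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eagledrp.nncae import (
    NNCAEConfig,
    NNCAEParams,
    cost_gradients,
    encode,
    extract_features,
    init_params,
    nonneg_penalty,
    nonneg_penalty_grad,
    reconstruction_cost,
    smoothed_l1,
    smoothed_l1_grad,
    sparsity_divergence,
    total_cost,
    train_nncae,
)
from eagledrp.synthetic import SyntheticSpec, generate_dataset
from eagledrp.preprocess import UnitScaler


def _rand_params(n_features, n_hidden, rng, scale=0.5):
    return NNCAEParams(
        W1=scale * rng.standard_normal((n_hidden, n_features)),
        W2=scale * rng.standard_normal((n_features, n_hidden)),
        b_x=scale * rng.standard_normal(n_hidden),
        b_h=scale * rng.standard_normal(n_features),
    )


# ---------------------------------------------------------------------------
# Smoothed L1


def test_smoothed_l1_branches():
    assert smoothed_l1(np.array([3.0, 0.0]), 0.1) == pytest.approx(3.0)
    assert smoothed_l1(0.0, 0.1) == pytest.approx(0.05)  # k/2 at the origin
    assert smoothed_l1(np.array([0.1]), 0.1) == pytest.approx(0.1)  # seam


def test_smoothed_l1_continuous_at_seam():
    k = 0.1
    for eps in (1e-9, -1e-9):
        z = np.array([k + eps])
        assert abs(smoothed_l1(z, k) - k) < 1e-8
    # branch values agree exactly at the seam
    norm = k
    upper = norm
    lower = norm**2 / (2 * k) + k / 2
    assert abs(upper - lower) < 1e-15


def test_smoothed_l1_grad_branches():
    g = smoothed_l1_grad(np.array([3.0, 4.0]), 0.1)
    assert np.linalg.norm(g) == pytest.approx(1.0)  # z/||z|| has unit norm
    assert smoothed_l1_grad(0.0, 0.1) == pytest.approx(0.0)  # z/k at origin


def test_smoothed_l1_grad_matches_finite_difference():
    rng = np.random.default_rng(0)
    for _ in range(10):
        z = rng.standard_normal(4) * rng.choice([0.01, 1.0])
        k = 0.1
        g = smoothed_l1_grad(z, k)
        eps = 1e-7
        for i in range(4):
            zp, zm = z.copy(), z.copy()
            zp[i] += eps
            zm[i] -= eps
            num = (smoothed_l1(zp, k) - smoothed_l1(zm, k)) / (2 * eps)
            assert num == pytest.approx(g[i], rel=1e-5, abs=1e-8)


@pytest.mark.parametrize("bad_k", [0.0, -1.0])
def test_nonpositive_k_rejected(bad_k):
    with pytest.raises(ValueError):
        smoothed_l1(1.0, bad_k)
    with pytest.raises(ValueError):
        smoothed_l1_grad(1.0, bad_k)


# ---------------------------------------------------------------------------
# Composite penalty


def test_penalty_values():
    cfg = NNCAEConfig(alpha1=1.0, alpha2=2.0, smoothing_k=0.1)
    assert nonneg_penalty(0.7, cfg) == 0.0
    assert nonneg_penalty(0.0, cfg) == 0.0  # w = 0 on the zero branch
    assert nonneg_penalty(-1.0, cfg) == pytest.approx(2.0)  # 1·1 + (2/2)·1


def test_penalty_grad_values():
    cfg = NNCAEConfig(alpha1=1.0, alpha2=2.0, smoothing_k=0.1)
    assert nonneg_penalty_grad(0.7, cfg) == 0.0
    assert nonneg_penalty_grad(-1.0, cfg) == pytest.approx(-3.0)


def test_penalty_grad_finite_difference_in_smoothing_zone():
    cfg = NNCAEConfig(alpha1=0.3, alpha2=0.7, smoothing_k=0.1)
    w = -0.05
    eps = 1e-7
    num = (nonneg_penalty(w + eps, cfg) - nonneg_penalty(w - eps, cfg)) / (2 * eps)
    assert num == pytest.approx(nonneg_penalty_grad(w, cfg), rel=1e-5)


@given(st.floats(min_value=-5, max_value=-1e-6))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_penalty_monotone_on_negative_axis(w):
    """The penalty decreases toward 0 as w rises through the negative axis."""
    cfg = NNCAEConfig(alpha1=0.5, alpha2=0.5)
    closer = w / 2
    assert nonneg_penalty(closer, cfg) < nonneg_penalty(w, cfg)
    assert nonneg_penalty(w, cfg) > 0


# ---------------------------------------------------------------------------
# Forward maps and cost terms


def test_encode_zero_params_gives_half():
    params = NNCAEParams(np.zeros((3, 4)), np.zeros((4, 3)), np.zeros(3), np.zeros(4))
    H = encode(np.ones((2, 4)), params)
    np.testing.assert_allclose(H, 0.5)


def test_encode_saturation_and_scalar_value():
    params = NNCAEParams(
        np.array([[1.0]]), np.zeros((1, 1)), np.zeros(1), np.zeros(1)
    )
    assert encode(np.array([[0.5]]), params)[0, 0] == pytest.approx(0.6224593, abs=1e-6)
    big = NNCAEParams(np.array([[100.0]]), np.zeros((1, 1)), np.zeros(1), np.zeros(1))
    assert encode(np.array([[1.0]]), big)[0, 0] > 1 - 1e-9


def test_reconstruction_cost_zero_at_fixed_point():
    # zero weights: reconstruction of 0.5-valued input is sigmoid(0) = 0.5
    params = NNCAEParams(np.zeros((3, 4)), np.zeros((4, 3)), np.zeros(3), np.zeros(4))
    X = 0.5 * np.ones((1, 4))
    assert reconstruction_cost(X, params) == pytest.approx(0.0, abs=1e-15)


def test_reconstruction_cost_mean_invariant_under_duplication():
    rng = np.random.default_rng(1)
    params = _rand_params(4, 3, rng)
    X = rng.random((5, 4))
    doubled = np.vstack([X, X])
    assert reconstruction_cost(doubled, params) == pytest.approx(
        reconstruction_cost(X, params)
    )


def test_sparsity_divergence_identity_and_positivity():
    assert sparsity_divergence(np.full(4, 0.05), 0.05) == pytest.approx(0.0)
    assert sparsity_divergence(np.array([0.2]), 0.05) == pytest.approx(
        0.05 * np.log(0.25) + 0.95 * np.log(0.95 / 0.8)
    )
    assert sparsity_divergence(np.array([0.04]), 0.05) > 0
    with pytest.raises(ValueError):
        sparsity_divergence(np.array([0.0]), 0.05)


def test_total_cost_degenerates_to_reconstruction():
    rng = np.random.default_rng(2)
    params = _rand_params(5, 3, rng)
    cfg = NNCAEConfig(n_hidden=3, sparsity_weight=0.0, alpha1=0.0, alpha2=0.0)
    X = rng.random((6, 5))
    assert total_cost(X, params, cfg) == pytest.approx(reconstruction_cost(X, params))


def test_total_cost_dominates_reconstruction_and_nonneg_weights_free():
    rng = np.random.default_rng(3)
    cfg = NNCAEConfig(n_hidden=3)
    params = _rand_params(5, 3, rng)
    X = rng.random((6, 5))
    assert total_cost(X, params, cfg) >= reconstruction_cost(X, params)
    # all-nonnegative weights contribute zero penalty
    pos = NNCAEParams(np.abs(params.W1), np.abs(params.W2), params.b_x, params.b_h)
    cfg_nokl = NNCAEConfig(n_hidden=3, sparsity_weight=0.0)
    assert total_cost(X, pos, cfg_nokl) == pytest.approx(reconstruction_cost(X, pos))


# ---------------------------------------------------------------------------
# Gradients


def _max_rel_grad_error(X, params, cfg, rng, n_coords=20):
    grads = cost_gradients(X, params, cfg)
    worst = 0.0
    eps = 1e-6
    names = ["W1", "W2", "b_x", "b_h"]
    for _ in range(n_coords):
        name = names[rng.integers(len(names))]
        arr = getattr(params, name)
        i = int(rng.integers(arr.size))
        plus, minus = params.copy(), params.copy()
        getattr(plus, name).flat[i] += eps
        getattr(minus, name).flat[i] -= eps
        num = (total_cost(X, plus, cfg) - total_cost(X, minus, cfg)) / (2 * eps)
        ana = getattr(grads, name).flat[i]
        worst = max(worst, abs(num - ana) / max(abs(num), 1e-8))
    return worst


def test_gradients_match_finite_differences_random_hyperparams():
    rng = np.random.default_rng(0)
    X = rng.random((8, 6))
    for draw in range(5):
        cfg = NNCAEConfig(
            n_hidden=4,
            sparsity_target=float(rng.uniform(0.02, 0.3)),
            sparsity_weight=float(rng.uniform(0, 3)),
            alpha1=float(rng.uniform(0, 0.01)),
            alpha2=float(rng.uniform(0, 0.01)),
        )
        params = _rand_params(6, 4, rng)
        assert _max_rel_grad_error(X, params, cfg, rng) <= 1e-5


def test_gradient_reduces_to_plain_autoencoder():
    rng = np.random.default_rng(4)
    X = rng.random((8, 6))
    cfg = NNCAEConfig(n_hidden=4, sparsity_weight=0.0, alpha1=0.0, alpha2=0.0)
    params = _rand_params(6, 4, rng)
    assert _max_rel_grad_error(X, params, cfg, rng) <= 1e-5


def test_bias_gradients_carry_no_penalty():
    """The composite decay applies to weights only; bias gradients must be
    unchanged by the alpha settings."""
    rng = np.random.default_rng(5)
    X = rng.random((8, 6))
    params = _rand_params(6, 4, rng)
    g_pen = cost_gradients(X, params, NNCAEConfig(n_hidden=4, alpha1=0.1, alpha2=0.1))
    g_off = cost_gradients(X, params, NNCAEConfig(n_hidden=4, alpha1=0.0, alpha2=0.0))
    np.testing.assert_array_equal(g_pen.b_x, g_off.b_x)
    np.testing.assert_array_equal(g_pen.b_h, g_off.b_h)


# ---------------------------------------------------------------------------
# Training


def test_training_reduces_cost_and_is_deterministic():
    table = generate_dataset(SyntheticSpec(n_samples=100, noise_sd=0.05, seed=0))
    X = UnitScaler.fit(table.values).transform(table.values)
    cfg = NNCAEConfig(n_hidden=8, epochs=200, learning_rate=0.1, seed=0)
    params, history = train_nncae(X, cfg)
    assert history[-1] < history[0]
    _, history2 = train_nncae(X, cfg)
    assert history == history2


def test_negative_weight_mass_decreases_with_penalty_strength():
    """Negative-weight mass shrinks monotonically as alpha1 = alpha2 grows."""
    table = generate_dataset(SyntheticSpec(n_samples=120, noise_sd=0.05, seed=1))
    X = UnitScaler.fit(table.values).transform(table.values)
    masses = []
    for a in (0.0, 1e-4, 1e-3, 1e-2):
        cfg = NNCAEConfig(n_hidden=8, alpha1=a, alpha2=a, epochs=150, seed=1)
        params, _ = train_nncae(X, cfg)
        masses.append(
            np.abs(np.minimum(params.W1, 0)).mean()
            + np.abs(np.minimum(params.W2, 0)).mean()
        )
    assert all(b < a for a, b in zip(masses, masses[1:]))


def test_extract_features_is_encode(trained_nncae, scaled_table):
    params, _ = trained_nncae
    X = scaled_table.values[:10]
    F = extract_features(X, params)
    assert F.shape == (10, params.W1.shape[0])
    assert np.all((F > 0) & (F < 1))
    np.testing.assert_array_equal(F, encode(X, params))


def test_config_validation():
    with pytest.raises(ValueError):
        NNCAEConfig(learning_rate=0.0)
    with pytest.raises(ValueError):
        NNCAEConfig(smoothing_k=-0.1)
    with pytest.raises(ValueError):
        NNCAEConfig(sparsity_target=1.0)
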