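import numpy as np
import pytest

from eagledrp.nncae import NNCAEConfig, train_nncae
from eagledrp.preprocess import UnitScaler, knn_impute
from eagledrp.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def scaled_table():
    """A clean, well-separated 200×22 synthetic table scaled to [0, 1]."""
    table = generate_dataset(
        SyntheticSpec(n_samples=200, n_features=22, noise_sd=0.05,
                      class_separation=5.0, seed=11)
    )
    imputed, _ = knn_impute(table, k=5)
    scaler = UnitScaler.fit(imputed.values)
    imputed.values = scaler.transform(imputed.values)
    return imputed


@pytest.fixture(scope="session")
def trained_nncae(scaled_table):
    """NNCAE trained on the shared table (moderate sparsity, converged)."""
    cfg = NNCAEConfig(n_hidden=16, sparsity_weight=0.5, sparsity_target=0.2,
                      learning_rate=0.3, epochs=300, seed=11)
    params, history = train_nncae(scaled_table.values, cfg)
    return params, history
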