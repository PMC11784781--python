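"""GDSC-shaped synthetic data with controllable noise, missingness and imbalance.

The generator emulates the *statistical* shape of GDSC ANOVA feature tables
(22 real-valued feature columns, binary response, sporadic missing cells,
heavily-missing columns, outlying rows, minority/majority imbalance) through
a low-rank latent-factor model:

    values = L · F + noise,   L ~ N(0, 1),   F = |N(0, 1)|

with the first latent factor shifted by ``class_separation`` for
positive-label samples, so the Bayes error of the classification task is
directly controlled.  Loadings are nonnegative so that a
non-negativity-constrained encoder is a well-posed feature learner for the
data it sees.  No pharmacological realism (dose-response curves, IC50s) is
attempted; only the shape the pipeline consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from eagledrp.data_io import FeatureTable

#: multiplicative factor applied to outlier rows — large enough to be
#: detectable by autoencoder reconstruction error
OUTLIER_SCALE = 10.0


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic GDSC-like dataset draw."""

    n_samples: int = 400
    n_features: int = 22
    latent_rank: int = 4
    noise_sd: float = 0.05
    minority_fraction: float = 0.35
    missing_column_fraction: float = 0.0
    missing_cell_fraction: float = 0.0
    outlier_fraction: float = 0.0
    class_separation: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_rank > self.n_features:
            raise ValueError("latent_rank must be <= n_features")
        if not 0 < self.minority_fraction <= 0.5:
            raise ValueError("minority_fraction must lie in (0, 0.5]")
        for name in ("missing_column_fraction", "missing_cell_fraction", "outlier_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.noise_sd < 0 or self.class_separation < 0:
            raise ValueError("noise_sd and class_separation must be nonnegative")


def _latent_and_labels(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    labels = (rng.random(spec.n_samples) < spec.minority_fraction).astype(int)
    latent = rng.standard_normal((spec.n_samples, spec.latent_rank))
    latent[:, 0] += spec.class_separation * labels
    return latent, labels


def _loadings(rank: int, n_features: int, rng: np.random.Generator) -> np.ndarray:
    # nonnegative loadings: the part-based structure an NNCAE can recover
    return np.abs(rng.standard_normal((rank, n_features)))


def generate_dataset(spec: SyntheticSpec) -> FeatureTable:
    """Draw one labelled feature table from the latent-factor model.

    Construction order: clean low-rank signal + Gaussian noise → outlier
    rows scaled by ``OUTLIER_SCALE`` → a ``missing_column_fraction`` share of
    columns masked above the 1/3 imputation-trigger level → uniform cell
    masking elsewhere at ``missing_cell_fraction`` (capped per column so only
    the designated columns exceed 1/3 missingness).  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    latent, labels = _latent_and_labels(spec, rng)
    loadings = _loadings(spec.latent_rank, spec.n_features, rng)
    values = latent @ loadings + spec.noise_sd * rng.standard_normal(
        (spec.n_samples, spec.n_features)
    )

    n_outliers = int(round(spec.outlier_fraction * spec.n_samples))
    outlier_rows = rng.choice(spec.n_samples, size=n_outliers, replace=False)
    values[outlier_rows] *= OUTLIER_SCALE

    mask = np.zeros(values.shape, dtype=bool)
    n, p = values.shape
    n_high = int(round(spec.missing_column_fraction * p))
    high_cols = rng.choice(p, size=n_high, replace=False)
    # strictly more than 1/3 of cells masked in the designated columns
    n_masked_high = int(np.floor(n / 3.0)) + 1
    for col in high_cols:
        rows = rng.choice(n, size=n_masked_high, replace=False)
        mask[rows, col] = True

    if spec.missing_cell_fraction > 0:
        cap = int(np.floor(n / 3.0))  # other columns must stay at <= 1/3
        other_cols = np.setdiff1d(np.arange(p), high_cols)
        for col in other_cols:
            n_cells = min(rng.binomial(n, spec.missing_cell_fraction), cap)
            if n_cells:
                rows = rng.choice(n, size=n_cells, replace=False)
                mask[rows, col] = True

    values = values.copy()
    values[mask] = np.nan
    return FeatureTable(
        sample_ids=[f"S{i:06d}" for i in range(n)],
        feature_names=[f"feat_{j:02d}" for j in range(p)],
        values=values,
        missing_mask=mask,
        labels=labels,
    )


def generate_paired_branch_data(
    spec: SyntheticSpec, drug_dim: int
) -> tuple[FeatureTable, FeatureTable]:
    """Cell-line table and drug table sharing sample ids, labels and latents.

    Both tables are driven by the same latent factors, so the drug features
    carry label information exactly when ``class_separation > 0``.  The drug
    table is clean (no masking/outliers); missingness and outliers are
    cell-line-table phenomena in the data this emulates.
    """
    if drug_dim < 1:
        raise ValueError("drug_dim must be >= 1")
    rng = np.random.default_rng(spec.seed)
    latent, labels = _latent_and_labels(spec, rng)
    cell_loadings = _loadings(spec.latent_rank, spec.n_features, rng)
    drug_loadings = _loadings(spec.latent_rank, drug_dim, rng)
    noise = spec.noise_sd
    cell_values = latent @ cell_loadings + noise * rng.standard_normal(
        (spec.n_samples, spec.n_features)
    )
    drug_values = latent @ drug_loadings + noise * rng.standard_normal(
        (spec.n_samples, drug_dim)
    )
    ids = [f"S{i:06d}" for i in range(spec.n_samples)]
    cell = FeatureTable(
        sample_ids=ids,
        feature_names=[f"feat_{j:02d}" for j in range(spec.n_features)],
        values=cell_values,
        missing_mask=np.zeros(cell_values.shape, dtype=bool),
        labels=labels,
    )
    drug = FeatureTable(
        sample_ids=list(ids),
        feature_names=[f"drug_{j:02d}" for j in range(drug_dim)],
        values=drug_values,
        missing_mask=np.zeros(drug_values.shape, dtype=bool),
        labels=labels.copy(),
    )
    return cell, drug
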