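"""Missing-data handling, outlier flagging and class balancing.

Fixed stage order ahead of classifier training:

1. detect columns with more than 1/3 missing cells (flagged for reporting —
   no feature or sample is ever dropped);
2. KNN imputation of every missing cell (neighbour mean over the k nearest
   rows under nan-aware Euclidean distance);
3. min–max scaling to the unit interval (the autoencoder reconstructs
   through a sigmoid, so its inputs live in [0, 1]);
4. NNCAE training on the scaled table;
5. outlier flagging by reconstruction-error z-score (flagged rows are
   excluded from classifier training, never removed from the table);
6. minority-class oversampling by interpolation in the NNCAE latent space
   (encode two random minority rows, mix their codes with a uniform weight,
   decode).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.impute import KNNImputer

from eagledrp.data_io import FeatureTable
from eagledrp.nncae import NNCAEConfig, NNCAEParams, decode, encode, train_nncae

logger = logging.getLogger("eagledrp")

HIGH_MISSING_THRESHOLD = 1.0 / 3.0


@dataclass
class ImputationReport:
    high_missing_columns: list[str]
    imputed_cell_count: int
    knn_k: int


@dataclass
class BalanceReport:
    class_counts_before: dict[int, int]
    class_counts_after: dict[int, int]
    synthetic_sample_count: int


def detect_high_missing_columns(
    table: FeatureTable, threshold: float = HIGH_MISSING_THRESHOLD
) -> list[str]:
    """Names of columns whose missing fraction is *strictly* above threshold.

    A column at exactly the threshold (e.g. 2 of 6 cells at the default 1/3)
    is not flagged.  Detection only — nothing is dropped.
    """
    frac = table.missing_fraction_per_column()
    return [name for name, f in zip(table.feature_names, frac) if f > threshold]


def knn_impute(table: FeatureTable, k: int = 5) -> tuple[FeatureTable, ImputationReport]:
    """Replace every masked cell by the mean of the feature over the k
    nearest rows (nan-aware Euclidean distance on mutually observed
    features).

    Degenerate cases: an all-missing column is imputed with 0 (warned); a
    row sharing no observed feature with any other row falls back to the
    column mean.  Observed cells are never altered.
    """
    if table.n_samples < k + 1:
        raise ValueError(f"need at least k+1={k + 1} rows for k={k} imputation")
    values = table.values.copy()
    values[table.missing_mask] = np.nan
    n_missing = int(table.missing_mask.sum())

    empty_cols = [
        name for name, m in zip(table.feature_names, table.missing_mask.all(axis=0)) if m
    ]
    if empty_cols:
        logger.warning("all-missing columns imputed with 0: %s", empty_cols)
    if n_missing:
        imputer = KNNImputer(n_neighbors=k, weights="uniform", keep_empty_features=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sklearn warns on no-overlap rows; we log instead
            imputed = imputer.fit_transform(values)
    else:
        imputed = values

    out = FeatureTable(
        sample_ids=list(table.sample_ids),
        feature_names=list(table.feature_names),
        values=imputed,
        missing_mask=np.zeros(imputed.shape, dtype=bool),
        labels=None if table.labels is None else table.labels.copy(),
    )
    report = ImputationReport(
        high_missing_columns=detect_high_missing_columns(table),
        imputed_cell_count=n_missing,
        knn_k=k,
    )
    return out, report


@dataclass
class UnitScaler:
    """Quantile map of each feature onto [0, 1], clipping the tails.

    Fitting on the 1st–99th percentile range keeps a handful of extreme
    rows (e.g. the ×10 outliers the generator injects) from compressing the
    bulk of the data into a sliver of the unit interval, which would starve
    the sigmoid autoencoder of dynamic range.  Constant features map to 0.
    """

    minimum: np.ndarray
    scale: np.ndarray  # quantile range, zeros replaced by 1

    @classmethod
    def fit(cls, X: np.ndarray, q: float = 0.01) -> "UnitScaler":
        mn = np.quantile(X, q, axis=0)
        rng = np.quantile(X, 1 - q, axis=0) - mn
        rng = np.where(rng == 0, 1.0, rng)
        return cls(minimum=mn, scale=rng)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.clip((X - self.minimum) / self.scale, 0.0, 1.0)


def reconstruction_errors(X: np.ndarray, params: NNCAEParams) -> np.ndarray:
    """Per-row squared reconstruction error through the trained NNCAE."""
    Xhat = decode(encode(X, params), params)
    return ((Xhat - X) ** 2).sum(axis=1)


def flag_outliers(
    table: FeatureTable, params: NNCAEParams, z_cut: float = 3.0
) -> np.ndarray:
    """Boolean flag per sample: reconstruction-error z-score above ``z_cut``.

    Centre and spread are the median and the scaled median absolute
    deviation (MAD·1.4826) of the errors — the plain mean/sd are inflated
    by the very outliers being hunted and mask all but the most extreme
    rows.  Flagged rows are meant to be excluded from classifier training;
    the table itself is untouched.  Requires a fully imputed table and at
    least 3 samples (a spread estimate is meaningless below that).
    """
    if table.missing_mask.any():
        raise ValueError("table must be fully imputed before outlier flagging")
    if table.n_samples < 3:
        raise ValueError("need at least 3 samples to estimate the error spread")
    errors = reconstruction_errors(table.values, params)
    centre = float(np.median(errors))
    spread = 1.4826 * float(np.median(np.abs(errors - centre)))
    if spread == 0:
        spread = float(errors.std())
    if np.isinf(z_cut) or spread == 0:
        return np.zeros(table.n_samples, dtype=bool)
    return errors > centre + z_cut * spread


def balance_classes(
    features: np.ndarray,
    labels: np.ndarray,
    params: NNCAEParams,
    target_ratio: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, BalanceReport]:
    """Oversample the minority class by NNCAE latent-space interpolation.

    Two random minority samples are encoded, their codes mixed with a
    uniform weight λ ~ U(0, 1), and the mix decoded back to feature space
    (hence synthetic values lie in (0, 1), the sigmoid range).  Appending
    continues until minority/majority reaches ``target_ratio``; majority
    samples are untouched and no sample is ever removed.
    """
    rng = np.random.default_rng() if rng is None else rng
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("balancing requires two classes")
    before = {int(c): int(n) for c, n in zip(classes, counts)}
    minority = int(classes[np.argmin(counts)])
    majority = int(classes[np.argmax(counts)])
    n_needed = int(np.floor(target_ratio * before[majority])) - before[minority]
    n_needed = max(n_needed, 0)

    if n_needed:
        pool = features[labels == minority]
        codes = encode(pool, params)
        i = rng.integers(len(pool), size=n_needed)
        j = rng.integers(len(pool), size=n_needed)
        lam = rng.random((n_needed, 1))
        synthetic = decode(lam * codes[i] + (1 - lam) * codes[j], params)
        features = np.vstack([features, synthetic])
        labels = np.concatenate([labels, np.full(n_needed, minority)])

    after = {int(c): int((labels == c).sum()) for c in classes}
    report = BalanceReport(
        class_counts_before=before,
        class_counts_after=after,
        synthetic_sample_count=n_needed,
    )
    return features, labels, report


@dataclass
class PreprocessResult:
    """Output of the full preprocessing pipeline."""

    features: np.ndarray  # balanced, scaled feature matrix (input space)
    labels: np.ndarray
    nncae_params: NNCAEParams
    scaler: UnitScaler
    outlier_flags: np.ndarray  # over the original (unbalanced) rows
    imputation: ImputationReport
    balance: BalanceReport
    loss_history: list[float] = field(default_factory=list)


def preprocess_pipeline(
    table: FeatureTable,
    nncae_cfg: NNCAEConfig,
    *,
    missing_threshold: float = HIGH_MISSING_THRESHOLD,
    knn_k: int = 5,
    z_cut: float = 3.0,
    target_ratio: float = 1.0,
    seed: int = 0,
) -> PreprocessResult:
    """Run detect → impute → scale → train NNCAE → flag outliers → balance."""
    if table.labels is None:
        raise ValueError("pipeline requires a labelled table")
    high = detect_high_missing_columns(table, missing_threshold)
    imputed, imp_report = knn_impute(table, k=knn_k)
    imp_report.high_missing_columns = high
    scaler = UnitScaler.fit(imputed.values)
    X = scaler.transform(imputed.values)
    params, history = train_nncae(X, nncae_cfg)
    scaled_table = FeatureTable(
        sample_ids=list(imputed.sample_ids),
        feature_names=list(imputed.feature_names),
        values=X,
        missing_mask=np.zeros(X.shape, dtype=bool),
        labels=imputed.labels,
    )
    flags = flag_outliers(scaled_table, params, z_cut=z_cut)
    keep = ~flags
    rng = np.random.default_rng(seed)
    feats, labs, bal_report = balance_classes(
        X[keep], table.labels[keep], params, target_ratio=target_ratio, rng=rng
    )
    return PreprocessResult(
        features=feats,
        labels=labs,
        nncae_params=params,
        scaler=scaler,
        outlier_flags=flags,
        imputation=imp_report,
        balance=bal_report,
        loss_history=history,
    )
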