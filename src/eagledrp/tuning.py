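"""Hyperparameter tuning of the Conv-LSTM via MOGEO, and model evaluation.

Eagle positions live in the unit box [0, 1]^D and are decoded to model
configurations dimension by dimension: continuous dimensions are rescaled
affinely to their bounds, integer dimensions additionally rounded half-up,
categorical dimensions indexed by floor(position · n_options).  The tuner
minimizes the pair (validation error, log10 parameter count) — accuracy is
the quantity the method optimizes; model size keeps the Pareto front
meaningful and breaks ties toward smaller networks.
"""

from __future__ import annotations

import hashlib
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import train_test_split

from eagledrp.geo import ArchiveMember, GEOConfig, mogeo_minimize
from eagledrp.model import (
    Model,
    ModelConfig,
    assemble_model,
    param_count,
    predict_proba,
    train_model,
)

logger = logging.getLogger("eagledrp")

#: worst-case fitness assigned when a candidate diverges during training
DIVERGENCE_SENTINEL = (1.0, 12.0)


@dataclass
class Dimension:
    """One tunable dimension of the search space."""

    name: str
    kind: str  # "continuous" | "integer" | "categorical"
    bounds: tuple[float, float] | None = None
    options: Sequence[Any] | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"continuous", "integer", "categorical"}:
            raise ValueError(f"unknown dimension kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.options:
                raise ValueError(f"categorical dimension {self.name!r} needs options")
        else:
            if self.bounds is None or not all(np.isfinite(self.bounds)):
                raise ValueError(f"dimension {self.name!r} needs finite bounds")

    def decode(self, u: float) -> Any:
        u = float(np.clip(u, 0.0, 1.0))
        if self.kind == "categorical":
            idx = min(int(np.floor(u * len(self.options))), len(self.options) - 1)
            return self.options[idx]
        lo, hi = self.bounds
        value = lo + u * (hi - lo)
        if self.kind == "integer":
            return int(np.floor(value + 0.5))
        return value


@dataclass
class HyperparamSpace:
    """Ordered list of dimensions; names map onto ModelConfig fields."""

    dimensions: list[Dimension] = field(default_factory=list)

    @property
    def dim(self) -> int:
        return len(self.dimensions)

    def decode(self, position: np.ndarray) -> dict[str, Any]:
        position = np.asarray(position, dtype=float)
        if position.size != self.dim:
            raise ValueError(f"position has {position.size} entries, space has {self.dim}")
        return {d.name: d.decode(u) for d, u in zip(self.dimensions, position)}


def decode_position(
    position: np.ndarray, space: HyperparamSpace, base: ModelConfig | None = None
) -> ModelConfig:
    """Map a unit-box position to a full model configuration.

    Decoded values override the corresponding fields of ``base`` (a default
    configuration when omitted).  Total and deterministic: every position
    decodes to a valid config.
    """
    base = ModelConfig() if base is None else base
    return replace(base, **space.decode(position))


def fitness_evaluate(
    position: np.ndarray,
    space: HyperparamSpace,
    train_data: tuple,
    val_data: tuple,
    budget_epochs: int,
    seed: int = 0,
    base: ModelConfig | None = None,
    cache: dict | None = None,
) -> np.ndarray:
    """Train the decoded model briefly and return the minimization pair
    (1 − validation accuracy, log10 parameter count).

    Evaluations are cached by decoded-config identity, and the training
    seed is derived from that identity, so two positions decoding to the
    same architecture get bit-identical fitness.  A training divergence is
    mapped to a worst-case sentinel.
    """
    cfg = decode_position(position, space, base)
    key = cfg.key()
    if cache is not None and key in cache:
        return cache[key]
    # stable across processes (unlike hash()), so runs are replayable
    digest = int.from_bytes(hashlib.sha256(repr(key).encode()).digest()[:4], "big")
    train_seed = (seed + digest) % (2**31)
    rng = np.random.default_rng(train_seed)
    cfg = replace(cfg, seed=train_seed)
    try:
        model = assemble_model(cfg)
        model, _ = train_model(model, train_data[0], train_data[1], budget_epochs, rng=rng)
        probs = predict_proba(model, val_data[0])
        acc = float((probs.argmax(axis=1) == val_data[1]).mean())
        fitness = np.array([1.0 - acc, math.log10(param_count(model))])
    except (RuntimeError, FloatingPointError) as exc:
        logger.warning("candidate diverged (%s); assigning worst-case fitness", exc)
        fitness = np.array(DIVERGENCE_SENTINEL)
    if cache is not None:
        cache[key] = fitness
    return fitness


def tune(
    data: tuple,
    space: HyperparamSpace,
    mogeo_cfg: GEOConfig,
    budget_epochs: int = 5,
    base: ModelConfig | None = None,
    capacity: int = 25,
    val_fraction: float = 0.2,
) -> tuple[ModelConfig, list[ArchiveMember]]:
    """Run MOGEO over the hyperparameter space.

    ``data`` = (features, labels); an internal stratified split provides
    the validation set.  The best configuration is the archive member with
    the lowest validation error, ties broken by fewer parameters.
    """
    X, y = data
    idx = np.arange(len(y))
    tr, va = train_test_split(
        idx, test_size=val_fraction, stratify=y, random_state=mogeo_cfg.seed
    )
    if isinstance(X, (tuple, list)):
        train_data = (tuple(x[tr] for x in X), y[tr])
        val_data = (tuple(x[va] for x in X), y[va])
    else:
        train_data = (X[tr], y[tr])
        val_data = (X[va], y[va])
    cache: dict = {}

    def objectives(position: np.ndarray) -> np.ndarray:
        return fitness_evaluate(
            position,
            space,
            train_data,
            val_data,
            budget_epochs,
            seed=mogeo_cfg.seed,
            base=base,
            cache=cache,
        )

    archive = mogeo_minimize(objectives, mogeo_cfg, capacity=capacity)
    best = min(archive, key=lambda m: (m.objectives[0], m.objectives[1]))
    best_cfg = decode_position(best.position, space, base)
    return best_cfg, archive


# ---------------------------------------------------------------------------
# Evaluation metrics


@dataclass
class EvaluationReport:
    """The eight-metric panel used for drug-response classifiers."""

    accuracy: float
    precision: float
    recall: float
    f_measure: float
    specificity: float
    rmse: float
    scc: float
    pcc: float


def metrics_from_scores(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> EvaluationReport:
    """Compute the metric panel from positive-class probabilities.

    Confusion counts use the given threshold; RMSE and the Pearson/Spearman
    correlations compare the continuous probability against the 0/1 label.
    Undefined ratios on a single-class test set are reported as 0 with a
    warning.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting 0")
            return 0.0
        return num / den

    accuracy = (tp + tn) / len(y)
    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    if precision + recall == 0:
        warnings.warn("f-measure undefined; reporting 0")
        f_measure = 0.0
    else:
        f_measure = 2 * precision * recall / (precision + recall)
    specificity = ratio(tn, tn + fp, "specificity")
    rmse = float(np.sqrt(np.mean((p - y) ** 2)))

    def corr(fn_corr, name: str) -> float:
        if np.unique(y).size < 2 or np.unique(p).size < 2:
            warnings.warn(f"{name} undefined on constant input; reporting 0")
            return 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = fn_corr(p, y).statistic
        return float(r) if np.isfinite(r) else 0.0

    pcc = corr(stats.pearsonr, "pcc")
    scc = corr(stats.spearmanr, "scc")
    return EvaluationReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f_measure=f_measure,
        specificity=specificity,
        rmse=rmse,
        scc=scc,
        pcc=pcc,
    )


def evaluate_model(model: Model, test_features, test_labels: np.ndarray) -> EvaluationReport:
    """Metric panel of a trained classifier on held-out data."""
    probs = predict_proba(model, test_features)
    return metrics_from_scores(probs[:, 1], test_labels)
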