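"""Reading and writing GDSC-style feature tables, run configuration, reports.

A feature table is a flat CSV (RFC-4180, header row) of real-valued cells:
one row per sample (a cell line × drug record in GDSC exports), one column
per feature, optionally a binary response column and a ``sample_id`` column.
Missing cells are blank or one of the sentinels ``NA`` / ``NaN``
(case-insensitive), matching how GDSC ANOVA exports encode absent values.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("eagledrp")

#: cell contents treated as missing (compared lower-cased and stripped)
MISSING_SENTINELS = frozenset({"", "na", "nan"})

SAMPLE_ID_COLUMN = "sample_id"


class ConfigError(ValueError):
    """Configuration file is malformed or references unknown keys."""


@dataclass
class FeatureTable:
    """Samples × features matrix with an explicit missing-value mask.

    Parameters
    ----------
    sample_ids : list of str
        One identifier per row.
    feature_names : list of str
        Unique column names, order preserved from file.
    values : ndarray, shape (n_samples, n_features)
        Cell values; entries under a true mask are meaningless and must not
        be read by any statistic.
    missing_mask : ndarray of bool, same shape as ``values``
        True marks a missing cell.
    labels : ndarray of int in {0, 1}, optional
        Binary drug-response label per sample.
    """

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    missing_mask: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != self.missing_mask.shape:
            raise ValueError(
                f"values shape {self.values.shape} != mask shape {self.missing_mask.shape}"
            )
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError("values shape inconsistent with sample_ids/feature_names")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.sample_ids),):
                raise ValueError("labels length must equal n_samples")
            if not np.isin(self.labels, [0, 1]).all():
                raise ValueError("labels must be binary (0/1)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def missing_fraction_per_column(self) -> np.ndarray:
        return self.missing_mask.mean(axis=0)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            sample_ids=list(self.sample_ids),
            feature_names=list(self.feature_names),
            values=self.values.copy(),
            missing_mask=self.missing_mask.copy(),
            labels=None if self.labels is None else self.labels.copy(),
        )


def read_feature_table(path: str | Path, label_column: str | None = None) -> FeatureTable:
    """Read a CSV feature table; blank/NA/NaN cells set the missing mask.

    Raises
    ------
    ValueError
        On a malformed CSV (message names the offending line) or a
        non-numeric cell.
    ConfigError
        If ``label_column`` is named but absent.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # pandas messages carry the line number
        raise ValueError(f"malformed CSV {path}: {exc}") from exc

    columns = list(df.columns)
    sample_ids: list[str]
    if SAMPLE_ID_COLUMN in columns:
        sample_ids = [str(v) for v in df[SAMPLE_ID_COLUMN]]
        columns.remove(SAMPLE_ID_COLUMN)
    else:
        sample_ids = [f"S{i:06d}" for i in range(len(df))]

    labels = None
    if label_column is not None:
        if label_column not in columns:
            raise ConfigError(f"label column {label_column!r} not found in {path}")
        raw = df[label_column].str.strip()
        try:
            labels = raw.astype(int).to_numpy()
        except ValueError as exc:
            raise ValueError(f"label column {label_column!r} must be integer 0/1: {exc}") from exc
        columns.remove(label_column)

    raw = df[columns].to_numpy(dtype=str) if columns else np.empty((len(df), 0), dtype=str)
    stripped = np.char.strip(raw)
    mask = np.isin(np.char.lower(stripped), sorted(MISSING_SENTINELS))
    values = np.zeros(stripped.shape, dtype=float)
    filled = np.where(mask, "0", stripped)
    try:
        values = filled.astype(float)
    except ValueError:
        bad = next(
            (i, j)
            for i in range(filled.shape[0])
            for j in range(filled.shape[1])
            if not _is_float(filled[i, j])
        )
        raise ValueError(
            f"non-numeric cell at data line {bad[0] + 2}, column {columns[bad[1]]!r}: "
            f"{raw[bad]!r}"
        ) from None
    values[mask] = np.nan

    return FeatureTable(
        sample_ids=sample_ids,
        feature_names=columns,
        values=values,
        missing_mask=mask,
        labels=labels,
    )


def _is_float(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_feature_table(
    table: FeatureTable, path: str | Path, label_column: str = "response"
) -> None:
    """Write a feature table as CSV; missing cells become empty strings.

    Floats are written at 17 significant digits so read∘write round-trips
    exactly.
    """
    path = Path(path)
    cells: dict[str, Any] = {SAMPLE_ID_COLUMN: table.sample_ids}
    for j, name in enumerate(table.feature_names):
        col = [
            "" if table.missing_mask[i, j] else format(table.values[i, j], ".17g")
            for i in range(table.n_samples)
        ]
        cells[name] = col
    if table.labels is not None:
        cells[label_column] = [str(int(v)) for v in table.labels]
    pd.DataFrame(cells).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class PreprocessingConfig:
    missing_threshold: float = 1.0 / 3.0
    knn_k: int = 5
    outlier_z_cut: float = 3.0
    balance_target_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_threshold < 1:
            raise ConfigError("missing_threshold must lie in [0, 1)")
        if self.knn_k < 1:
            raise ConfigError("knn_k must be >= 1")


@dataclass
class RunConfig:
    """Top-level run configuration: one seed, one block per pipeline stage."""

    seed: int = 0
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    nncae: dict[str, Any] = field(default_factory=dict)
    model: dict[str, Any] = field(default_factory=dict)
    tuner: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ConfigError("seed must be >= 0")


def _build_block(cls: type, mapping: Mapping[str, Any], block: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(mapping) - known)
    if unknown:
        raise ConfigError(f"unknown keys in {block!r} block: {unknown}")
    return cls(**mapping)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run configuration; absent fields take defaults.

    Unknown keys raise :class:`ConfigError` listing the offending names.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    known = {"seed", "preprocessing", "nncae", "model", "tuner"}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown top-level keys: {unknown}")
    pre = _build_block(PreprocessingConfig, data.get("preprocessing", {}) or {}, "preprocessing")
    return RunConfig(
        seed=int(data.get("seed", 0)),
        preprocessing=pre,
        nncae=dict(data.get("nncae", {}) or {}),
        model=dict(data.get("model", {}) or {}),
        tuner=dict(data.get("tuner", {}) or {}),
    )


def write_report(report: Any, path: str | Path) -> None:
    """Serialize a report (dataclass or mapping) as machine-readable JSON."""
    if dataclasses.is_dataclass(report) and not isinstance(report, type):
        report = dataclasses.asdict(report)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def log_stage(stage: str, shape: Sequence[int] | None, elapsed: float) -> None:
    """One structured log line per pipeline stage."""
    logger.info("stage=%s shape=%s elapsed=%.3fs", stage, tuple(shape or ()), elapsed)
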