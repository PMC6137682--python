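"""Data containers, file I/O and run configuration.

Datasets are exchanged as comma-separated text: a header row of item ids,
one row per person, first column the person id.  Accuracy and time matrices
live in separate files with identical layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Dataset",
    "AnalysisConfig",
    "DataValidationError",
    "ConfigError",
    "read_dataset",
    "write_dataset",
    "parse_config",
    "MODEL_KINDS",
]

MODEL_KINDS = ("ci", "linear", "quadratic", "multicat")


class DataValidationError(ValueError):
    """Raised when an input matrix violates a Dataset invariant."""


class ConfigError(ValueError):
    """Raised when a run configuration is inconsistent."""


@dataclass
class Dataset:
    """Paired accuracy and response-time matrices for N persons x K items.

    Invariants: ``X`` and ``T`` share a shape, ``X`` is strictly 0/1,
    every entry of ``T`` is strictly positive and no cell is missing.
    """

    X: np.ndarray
    T: np.ndarray
    person_ids: Sequence[str] = field(default=None)  # type: ignore[assignment]
    item_ids: Sequence[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.T = np.asarray(self.T, dtype=float)
        if self.X.ndim != 2 or self.T.ndim != 2:
            raise DataValidationError("X and T must be 2-dimensional matrices")
        if self.X.shape != self.T.shape:
            raise DataValidationError(
                f"shape mismatch: X is {self.X.shape}, T is {self.T.shape}")
        if np.isnan(self.T).any() or pd.isna(self.X).any():
            p, i = np.argwhere(pd.isna(self.X) | np.isnan(self.T))[0]
            raise DataValidationError(f"missing value at (person={p}, item={i}); "
                                      "missing responses are not supported")
        bad = ~np.isin(self.X, (0, 1))
        if bad.any():
            p, i = np.argwhere(bad)[0]
            raise DataValidationError(
                f"non-binary accuracy {self.X[p, i]!r} at (person={p}, item={i})")
        self.X = self.X.astype(np.int8)
        bad = ~(self.T > 0) | ~np.isfinite(self.T)
        if bad.any():
            p, i = np.argwhere(bad)[0]
            raise DataValidationError(
                f"non-positive response time {self.T[p, i]!r} at (person={p}, item={i})")
        if self.person_ids is None:
            self.person_ids = [f"p{j}" for j in range(self.X.shape[0])]
        if self.item_ids is None:
            self.item_ids = [f"item{j}" for j in range(self.X.shape[1])]
        if len(self.person_ids) != self.X.shape[0]:
            raise DataValidationError("person_ids length does not match matrix")
        if len(self.item_ids) != self.X.shape[1]:
            raise DataValidationError("item_ids length does not match matrix")

    @property
    def n_persons(self) -> int:
        return self.X.shape[0]

    @property
    def n_items(self) -> int:
        return self.X.shape[1]

    @property
    def log_T(self) -> np.ndarray:
        return np.log(self.T)


def read_dataset(x_path: str | Path, t_path: str | Path) -> Dataset:
    """Read paired accuracy/time CSV files into a validated Dataset."""
    xf = pd.read_csv(x_path, index_col=0)
    tf = pd.read_csv(t_path, index_col=0)
    if xf.shape != tf.shape:
        raise DataValidationError(
            f"shape mismatch between {x_path} {xf.shape} and {t_path} {tf.shape}")
    return Dataset(X=xf.to_numpy(), T=tf.to_numpy(dtype=float),
                   person_ids=[str(p) for p in xf.index],
                   item_ids=[str(i) for i in xf.columns])


def write_dataset(ds: Dataset, x_path: str | Path, t_path: str | Path) -> None:
    """Write a Dataset as the pair of CSVs accepted by :func:`read_dataset`."""
    pd.DataFrame(ds.X, index=list(ds.person_ids),
                 columns=list(ds.item_ids)).to_csv(x_path, index_label="person")
    pd.DataFrame(ds.T, index=list(ds.person_ids),
                 columns=list(ds.item_ids)).to_csv(t_path, index_label="person")


_DEFAULT_THRESHOLDS = (-1.5, -0.5, 0.5, 1.5)
_DEFAULT_FOCAL = tuple(np.arange(-2.0, 2.0 + 1e-9, 0.5))


@dataclass
class AnalysisConfig:
    """Run settings; unspecified fields take the published defaults."""

    model: str = "ci"
    n_iter: int = 10_000
    burn_in: int = 5_000
    thin: int = 1
    seed: int = 0
    multicat_thresholds: tuple = _DEFAULT_THRESHOLDS
    multicat_baseline: int | None = None  # None -> middle category
    focal_points: tuple = _DEFAULT_FOCAL
    bandwidth_h: float = 1.1
    n_permutations: int = 500
    n_ppc_replicates: int = 500

    def __post_init__(self) -> None:
        if self.model not in MODEL_KINDS:
            raise ConfigError(f"unknown model {self.model!r}; expected one of {MODEL_KINDS}")
        if self.n_iter <= 0 or self.thin <= 0:
            raise ConfigError("n_iter and thin must be positive")
        if not (0 <= self.burn_in < self.n_iter):
            raise ConfigError(
                f"burn_in ({self.burn_in}) must be non-negative and < n_iter ({self.n_iter})")
        thr = np.asarray(self.multicat_thresholds, dtype=float)
        if thr.ndim != 1 or len(thr) < 1 or np.any(np.diff(thr) <= 0):
            raise ConfigError("multicat_thresholds must be strictly ascending")
        self.multicat_thresholds = tuple(thr)
        if self.multicat_baseline is None:
            # middle of the M = len(thr)+1 categories
            self.multicat_baseline = len(thr) // 2
        m = int(self.multicat_baseline)
        if not (0 <= m <= len(thr)):
            raise ConfigError("multicat_baseline outside the category range")
        self.multicat_baseline = m
        fp = np.asarray(self.focal_points, dtype=float)
        if fp.ndim != 1 or len(fp) < 2 or np.any(np.diff(fp) <= 0):
            raise ConfigError("focal_points must be strictly ascending with >= 2 points")
        self.focal_points = tuple(fp)
        if self.bandwidth_h <= 0:
            raise ConfigError("bandwidth_h must be positive")
        if self.n_permutations < 1 or self.n_ppc_replicates < 1:
            raise ConfigError("n_permutations and n_ppc_replicates must be >= 1")

    @property
    def n_categories(self) -> int:
        return len(self.multicat_thresholds) + 1


def parse_config(path: str | Path | None = None, text: str | None = None) -> AnalysisConfig:
    """Parse a JSON or YAML configuration document.

    Fields not present in the document take the defaults of
    :class:`AnalysisConfig`.  An empty document yields pure defaults.
    """
    if text is None:
        text = Path(path).read_text() if path is not None else ""
    try:
        doc = json.loads(text) if text.lstrip().startswith("{") else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"could not parse configuration: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError("configuration document must be a mapping")
    known = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    for key in ("multicat_thresholds", "focal_points"):
        if key in doc:
            doc[key] = tuple(doc[key])
    return AnalysisConfig(**doc)
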