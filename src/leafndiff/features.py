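"""Reduced design matrices with provenance, shared by every reduction."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .differencing import DifferenceSet

__all__ = ["FeatureSet"]


@dataclass(frozen=True)
class FeatureSet:
    """A reduced design matrix aligned with a difference set.

    ``X`` has one row per sample of the parent :class:`DifferenceSet`
    (same order); ``method`` names the reduction ("dwmd", "spa", "pca",
    "iriv"); ``meta`` records how the features were produced (selected
    bands, wavelet spec, loadings source, ...).
    """

    X: np.ndarray
    sample_ids: tuple[str, ...]
    method: str
    split: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if len(self.sample_ids) != X.shape[0]:
            raise ValueError("sample_ids must align with rows")
        object.__setattr__(self, "X", X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def _mask(self, label: str) -> np.ndarray:
        if self.split is None:
            raise ValueError("feature set carries no split labels")
        return np.asarray(self.split) == label

    @property
    def X_train(self) -> np.ndarray:
        return self.X[self._mask("train")]

    @property
    def X_val(self) -> np.ndarray:
        return self.X[self._mask("val")]


def targets_for(feats: FeatureSet, diffs: DifferenceSet) -> tuple[np.ndarray, np.ndarray]:
    """ΔN targets aligned with a feature set's train/val rows."""
    if feats.sample_ids != diffs.sample_ids:
        raise ValueError("feature set and difference set are misaligned")
    return diffs.delta_n[feats._mask("train")], diffs.delta_n[feats._mask("val")]
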