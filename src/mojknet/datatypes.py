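"""Shared data containers for the multi-omics subtype-classification pipeline.

All containers are thin dataclasses around numpy arrays / pandas objects with
validated invariants: matching row order between sample ids and values,
symmetry of affinity graphs, finiteness of learned embeddings.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Modality",
    "OmicsMatrix",
    "MultiOmicsDataset",
    "SplitPlan",
    "AffinityGraph",
    "LatentEmbedding",
]


class Modality(str, Enum):
    """The four molecular layers the pipeline integrates."""

    CNA = "CNA"      # copy-number alteration
    MET = "MET"      # DNA methylation
    MRNA = "mRNA"    # mRNA expression
    RPPA = "RPPA"    # reverse-phase protein array (proteomics)

    @classmethod
    def ordered(cls) -> tuple["Modality", ...]:
        """Canonical modality order (CNA, MET, mRNA, RPPA).

        This order fixes the mapping of the autoencoder loss weights
        (alpha, beta, gamma, delta) onto modalities.
        """
        return (cls.CNA, cls.MET, cls.MRNA, cls.RPPA)


@dataclass
class OmicsMatrix:
    """One modality's samples x features table.

    ``values`` may contain NaN at cells flagged in ``missing_mask`` before
    imputation; after :func:`mojknet.omics_io.filter_and_impute` the matrix is
    guaranteed finite.
    """

    modality: Modality
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (samples x features)")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.feature_ids) != p:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {p} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_ids)) != p:
            raise ValueError("duplicate feature ids")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape must match values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, ids: Sequence[str]) -> "OmicsMatrix":
        """Return a copy restricted to ``ids``, in the given order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return OmicsMatrix(
            modality=self.modality,
            sample_ids=list(ids),
            feature_ids=list(self.feature_ids),
            values=self.values[rows].copy(),
            missing_mask=self.missing_mask[rows].copy(),
        )


@dataclass
class MultiOmicsDataset:
    """Aligned multi-omics cohort: four modalities + labels (+ survival)."""

    omics: dict[Modality, OmicsMatrix]
    labels: pd.Series                 # index = sample_ids, values = class codes
    sample_ids: list[str]
    survival: Optional[pd.DataFrame] = None   # columns: time, event; index = sample_ids
    class_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        for mod, mat in self.omics.items():
            if list(mat.sample_ids) != list(self.sample_ids):
                raise ValueError(f"{mod.value} sample order differs from dataset order")
        if list(self.labels.index) != list(self.sample_ids):
            raise ValueError("labels index must equal sample_ids in order")
        if self.labels.isna().any():
            raise ValueError("every sample must carry a subtype label")
        if self.survival is not None:
            if list(self.survival.index) != list(self.sample_ids):
                raise ValueError("survival index must equal sample_ids in order")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_classes(self) -> int:
        return int(self.labels.nunique())

    @property
    def y(self) -> np.ndarray:
        """Integer class codes aligned with ``sample_ids``."""
        return self.labels.to_numpy(dtype=np.int64)


@dataclass
class SplitPlan:
    """Assignment of each sample to an evaluation fold.

    ``kind`` is ``"cv"`` for k-fold cross-validation (test set of round *i* is
    fold *i*) or ``"holdout"`` for a single stratified split (fold 1 = test).
    """

    n_folds: int
    fold_of: np.ndarray
    stratified: bool
    seed: int
    kind: str = "cv"

    def __post_init__(self) -> None:
        self.fold_of = np.asarray(self.fold_of, dtype=np.int64)
        if self.fold_of.min() < 0 or self.fold_of.max() >= self.n_folds:
            raise ValueError("fold indices out of range")
        counts = np.bincount(self.fold_of, minlength=self.n_folds)
        if (counts == 0).any():
            raise ValueError("every fold must be non-empty")

    @property
    def test_folds(self) -> range:
        return range(self.n_folds) if self.kind == "cv" else range(1, 2)

    def test_mask(self, fold: int) -> np.ndarray:
        return self.fold_of == fold

    def train_mask(self, fold: int) -> np.ndarray:
        return self.fold_of != fold


@dataclass
class AffinityGraph:
    """Symmetric non-negative patient-patient similarity graph.

    Diagonal convention: 1.0 for standalone per-omics affinity output,
    and the row-normalized value (1/2) on the fused consensus network.
    """

    sample_ids: list[str]
    weights: np.ndarray
    k: int
    modality: str = "fused"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        n = len(self.sample_ids)
        if self.weights.shape != (n, n):
            raise ValueError("weights must be n x n")
        if not np.isfinite(self.weights).all():
            raise ValueError("non-finite affinity weights")
        if (self.weights < 0).any():
            raise ValueError("negative affinity weights")
        if np.abs(self.weights - self.weights.T).max() > 1e-10:
            raise ValueError("affinity weights must be symmetric")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def n_components(self) -> int:
        """Number of connected components of the off-diagonal edge set."""
        from scipy.sparse.csgraph import connected_components

        off = self.weights.copy()
        np.fill_diagonal(off, 0.0)
        n_comp, _ = connected_components(off > 0, directed=False)
        return int(n_comp)


@dataclass
class LatentEmbedding:
    """Samples x latent-dim representation produced by a learning stage."""

    sample_ids: list[str]
    values: np.ndarray
    source: str  # "AE", "JK_CNA", ..., "JK_patient", "MOJKNET_FINAL"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.sample_ids):
            raise ValueError("embedding rows must match sample_ids")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite embedding values")

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"z{j}" for j in range(self.d)]
        return pd.DataFrame(self.values, index=self.sample_ids, columns=cols)
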