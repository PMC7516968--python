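"""Class balancing (SMOTE), z-score normalization, stratified splitting.

SMOTE oversamples the minority class by interpolation: a synthetic
point is ``x_i + u * (x_nn - x_i)`` with ``u ~ U[0, 1]`` and ``x_nn``
one of the k nearest minority-class neighbors of the minority point
``x_i`` (Euclidean distance).  Oversampling continues until both class
counts are equal.  Synthetic rows are flagged so downstream stages can
distinguish them, and the parent pair of each synthetic row is recorded
so the convex-combination property is exactly checkable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

from .fusion import FeatureMatrix

__all__ = ["LabeledDataset", "smote", "zscore_fit_apply", "split"]

DEFAULT_SMOTE_K = 5


@dataclass
class LabeledDataset:
    """Feature rows with labels and per-row provenance.

    ``provenance`` is "real" or "synthetic" per row; for synthetic rows
    ``parents`` holds the (row-index, row-index) pair of real minority
    rows it interpolates and ``mix`` the interpolation coefficient u.
    """

    X: np.ndarray
    y: np.ndarray
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]
    parents: np.ndarray | None = None  # (n_synthetic, 2) indices into X
    mix: np.ndarray | None = None  # (n_synthetic,) u in [0, 1]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if self.provenance is None:
            self.provenance = np.array(["real"] * self.X.shape[0])
        self.provenance = np.asarray(self.provenance)

    @property
    def class_counts(self) -> dict[int, int]:
        classes, counts = np.unique(self.y, return_counts=True)
        return {int(c): int(n) for c, n in zip(classes, counts)}


def smote(
    data: LabeledDataset, k_neighbors: int = DEFAULT_SMOTE_K, seed: int = 0
) -> LabeledDataset:
    """Oversample the minority class to parity by neighbor interpolation."""
    counts = data.class_counts
    if len(counts) != 2:
        raise ValueError(f"need exactly 2 classes, got {sorted(counts)}")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    minority = min(counts, key=counts.get)
    majority = next(c for c in counts if c != minority)
    n_min, n_maj = counts[minority], counts[majority]
    deficit = n_maj - n_min
    if deficit == 0:
        return LabeledDataset(
            X=data.X.copy(), y=data.y.copy(), provenance=data.provenance.copy()
        )
    if n_min < 2:
        raise ValueError("minority class needs at least 2 members for SMOTE")

    min_idx = np.flatnonzero(data.y == minority)
    x_min = data.X[min_idx]
    k_eff = min(k_neighbors, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(x_min)
    neighbors = nn.kneighbors(x_min, return_distance=False)[:, 1:]  # drop self

    rng = np.random.default_rng(seed)
    synth = np.empty((deficit, data.X.shape[1]))
    parents = np.empty((deficit, 2), dtype=np.int64)
    mix = rng.uniform(0.0, 1.0, size=deficit)
    base = rng.integers(0, n_min, size=deficit)
    pick = rng.integers(0, k_eff, size=deficit)
    for t in range(deficit):
        i = base[t]
        j = neighbors[i, pick[t]]
        synth[t] = x_min[i] + mix[t] * (x_min[j] - x_min[i])
        parents[t] = (min_idx[i], min_idx[j])

    return LabeledDataset(
        X=np.vstack([data.X, synth]),
        y=np.concatenate([data.y, np.full(deficit, minority, dtype=np.int64)]),
        provenance=np.concatenate([data.provenance, np.array(["synthetic"] * deficit)]),
        parents=parents,
        mix=mix,
    )


def zscore_fit_apply(
    train: FeatureMatrix, test: FeatureMatrix
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Standardize both partitions with mean/std estimated on train only.

    Columns with zero training standard deviation pass through unscaled
    (a warning is emitted): there is nothing to normalize.
    """
    if train.n < 1:
        raise ValueError("empty training partition")
    mu = train.X.mean(axis=0)
    sigma = train.X.std(axis=0)  # population std
    zero = sigma == 0
    if zero.any():
        names = [train.feature_names[j] for j in np.flatnonzero(zero)[:5]]
        warnings.warn(
            f"{int(zero.sum())} constant column(s) left unscaled (e.g. {names})",
            stacklevel=2,
        )
    sigma_safe = np.where(zero, 1.0, sigma)
    mu_eff = np.where(zero, 0.0, mu)

    def _apply(fm: FeatureMatrix) -> FeatureMatrix:
        return FeatureMatrix(
            X=(fm.X - mu_eff) / sigma_safe, feature_names=fm.feature_names, y=fm.y
        )

    return _apply(train), _apply(test)


def split(
    data: FeatureMatrix, train_fraction: float = 0.75, seed: int = 0
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Stratified random train/test split, deterministic given seed."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    idx_train, idx_test = train_test_split(
        np.arange(data.n),
        train_size=train_fraction,
        random_state=seed,
        stratify=data.y,
    )
    parts = []
    for idx in (np.sort(idx_train), np.sort(idx_test)):
        part = FeatureMatrix(
            X=data.X[idx], feature_names=data.feature_names, y=data.y[idx]
        )
        if len(np.unique(part.y)) < 2:
            raise ValueError("a class is absent from one partition; adjust sizes")
        parts.append(part)
    return parts[0], parts[1]
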