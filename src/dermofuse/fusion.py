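"""Mutual-information feature fusion.

Each feature column is scored by its mutual information (MI) with the
binary class label, and the features whose score exceeds the mean score
are kept.  MI between a continuous feature X and the discrete label Y is
estimated with Ross's k-nearest-neighbor estimator for mixed
discrete/continuous data:

    I(X; Y) = psi(N) - <psi(N_x)> + psi(k) - <psi(m)>

where psi is the digamma function, N the sample count, N_x the size of
point i's label class, k the neighbor count, and m_i the number of
points (any label) lying strictly within the distance from point i to
its k-th nearest neighbor *within its own class* (Chebyshev metric; in
one dimension this is |x_i - x_j|).  Negative estimates are clamped to
zero.  A plug-in equal-width binned estimator is provided as an
alternative for data that is naturally discrete.

All MI values are reported in nats.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma

__all__ = [
    "FeatureMatrix",
    "MIScores",
    "SelectionMask",
    "mi_knn",
    "mi_binned",
    "mi_scores",
    "select_features",
]

DEFAULT_K = 3
_JITTER_SCALE = 1e-10


@dataclass
class FeatureMatrix:
    """n instances x p features with binary labels."""

    X: np.ndarray
    feature_names: tuple[str, ...]
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if self.X.shape[0] < 2:
            raise ValueError("need at least 2 instances")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must match X columns")
        self.feature_names = tuple(self.feature_names)
        if not np.isfinite(self.X).all():
            raise ValueError("X contains missing or non-finite values")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class MIScores:
    scores: np.ndarray  # p nonnegative reals (nats)
    k: int
    estimator: str  # "knn" or "binned"


@dataclass(frozen=True)
class SelectionMask:
    keep: np.ndarray  # p booleans
    threshold: float  # mean MI


def _column_jitter(x: np.ndarray) -> np.ndarray:
    """Deterministic tie-breaking noise seeded from the column's content.

    Seeding from a checksum of the bytes makes duplicated columns receive
    identical jitter and hence identical scores.
    """
    seed = zlib.crc32(np.ascontiguousarray(x).tobytes()) & 0x7FFFFFFF
    rng = np.random.default_rng(seed)
    scale = _JITTER_SCALE * max(1.0, float(np.ptp(x)))
    return x + rng.standard_normal(x.shape) * scale


def _kth_within_class_distance(xs: np.ndarray, k: int) -> np.ndarray:
    """Distance from each point of a sorted 1-D array to its k-th nearest
    neighbor within the same array."""
    m = len(xs)
    best = np.full(m, np.inf)
    # the k-th NN of xs[t] lies in some window xs[j : j + k + 1] containing t
    for start_off in range(k + 1):
        j = np.arange(m) - start_off
        valid = (j >= 0) & (j + k < m)
        jv = j[valid]
        d = np.maximum(xs[valid] - xs[jv], xs[jv + k] - xs[valid])
        best[valid] = np.minimum(best[valid], d)
    return best


def mi_knn(x: np.ndarray, y: np.ndarray, k: int = DEFAULT_K) -> float:
    """Ross kNN estimate of I(X; Y) in nats for continuous x, discrete y.

    Raises if any label class has k or fewer members (lower k), or if
    only one class is present.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y).ravel()
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y lengths differ")
    if k < 1:
        raise ValueError("k must be >= 1")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both label classes must be present")
    if counts.min() <= k:
        raise ValueError(
            f"smallest class has {counts.min()} members, need > k={k}; lower k"
        )
    if np.ptp(x) == 0:
        return 0.0  # constant feature carries no information
    if len(np.unique(x)) < n:
        x = _column_jitter(x)

    radius = np.empty(n)
    n_x = np.empty(n)
    for cls, cnt in zip(classes, counts):
        sel = y == cls
        xv = x[sel]
        order = np.argsort(xv)
        xs = xv[order]
        d = _kth_within_class_distance(xs, k)
        r = np.empty(cnt)
        r[order] = d
        radius[sel] = r
        n_x[sel] = cnt
    # count points strictly inside the open interval (x - r, x + r):
    # self included, the k-th neighbor itself excluded
    xs_all = np.sort(x)
    lo = np.searchsorted(xs_all, x - radius, side="right")
    hi = np.searchsorted(xs_all, x + radius, side="left")
    m = hi - lo
    mi = (
        digamma(n)
        - np.mean(digamma(n_x))
        + digamma(k)
        - np.mean(digamma(np.maximum(m, 1)))
    )
    return float(max(0.0, mi))


def mi_binned(x: np.ndarray, y: np.ndarray, bins: int = 16) -> float:
    """Plug-in MI (nats) after equal-width discretization of x."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y).ravel()
    if len(x) != len(y):
        raise ValueError("x and y lengths differ")
    if np.ptp(x) == 0:
        b = np.zeros(len(x), dtype=int)
    else:
        edges = np.linspace(x.min(), x.max(), bins + 1)
        b = np.clip(np.digitize(x, edges[1:-1]), 0, bins - 1)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((bins, yi.max() + 1))
    np.add.at(joint, (b, yi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    pos = joint > 0
    return float((joint[pos] * np.log(joint[pos] / (px @ py)[pos])).sum())


def mi_scores(data: FeatureMatrix, k: int = DEFAULT_K) -> MIScores:
    """kNN MI of every feature column against the label, columnwise."""
    scores = np.empty(data.p)
    for j in range(data.p):
        try:
            scores[j] = mi_knn(data.X[:, j], data.y, k=k)
        except ValueError as exc:
            raise ValueError(
                f"MI estimation failed for feature "
                f"{data.feature_names[j]!r} (column {j}): {exc}"
            ) from exc
    return MIScores(scores=scores, k=k, estimator="knn")


def select_features(scores: MIScores) -> SelectionMask:
    """Keep features whose MI strictly exceeds the mean MI.

    If no feature qualifies (all scores equal), the single
    highest-scoring feature is kept, ties resolved by lowest index.
    """
    s = np.asarray(scores.scores, dtype=np.float64)
    if s.size < 1:
        raise ValueError("no scores to select from")
    threshold = float(s.mean())
    keep = s > threshold
    if not keep.any():
        keep = np.zeros(s.size, dtype=bool)
        keep[int(np.argmax(s))] = True
    return SelectionMask(keep=keep, threshold=threshold)
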