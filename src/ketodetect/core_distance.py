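"""Weighted elementwise time-series dissimilarity (DIMA) and its trained weights.

The dissimilarity between two equal-length series ``a`` and ``b`` is

    D(a, b; W, p) = ( sum_i sum_j |a_i - b_j|^p * W_ij )^(1/p)

a double sum over *all* index pairs, weighted by an ``n x n`` matrix ``W``.
With ``W`` the identity and ``p = 1`` this is the Manhattan distance; with a
diagonal positive ``W`` and ``p >= 1`` it is a weighted Minkowski metric.

The weight matrix used for classification is learned from class-mean series:
a sign matrix ``G`` encodes, for every index pair ``(i, j)``, whether the two
class centroids are better separated across classes than within classes at
that pair.  ``G`` is blended with the identity by a parameter ``lambda`` in
``[0, 1]``; ``lambda = 1`` recovers the plain Manhattan distance and
``lambda = 0`` uses the raw sign structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "HEALTHY",
    "SICK",
    "WeightMatrix",
    "DistanceSpec",
    "CentroidPair",
    "dima_distance",
    "build_sign_matrix",
    "blend_weights",
    "lambda_grid",
    "class_centroids",
    "write_weight_matrix_csv",
    "read_weight_matrix_csv",
]

#: integer class labels used throughout the package (sick = positive class)
HEALTHY: int = 0
SICK: int = 1


def _as_series(x, name: str = "series") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass(frozen=True)
class WeightMatrix:
    """An ``n x n`` weight matrix, optionally tagged with its blend parameter."""

    entries: np.ndarray
    lam: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.entries, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("weight matrix must be square")
        object.__setattr__(self, "entries", arr)

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    @property
    def is_symmetric(self) -> bool:
        return bool(np.array_equal(self.entries, self.entries.T))


@dataclass(frozen=True)
class DistanceSpec:
    """Exponent of the dissimilarity; the pointwise term is fixed to ``|a_i - b_j|``."""

    p: float = 1.0

    def __post_init__(self) -> None:
        if not (self.p > 0):
            raise ValueError("p must be positive")


@dataclass(frozen=True)
class CentroidPair:
    """Pointwise class-mean series for the healthy and sick classes."""

    healthy_mean: np.ndarray
    sick_mean: np.ndarray
    n_healthy: int
    n_sick: int

    def __post_init__(self) -> None:
        h = _as_series(self.healthy_mean, "healthy_mean")
        s = _as_series(self.sick_mean, "sick_mean")
        if h.shape != s.shape:
            raise ValueError("class means must have identical length")
        if self.n_healthy < 1 or self.n_sick < 1:
            raise ValueError("class counts must be >= 1")
        object.__setattr__(self, "healthy_mean", h)
        object.__setattr__(self, "sick_mean", s)

    @property
    def n(self) -> int:
        return self.healthy_mean.size


def dima_distance(a, b, w: WeightMatrix | np.ndarray, spec: DistanceSpec = DistanceSpec()) -> float:
    """Evaluate the weighted double-sum dissimilarity between two series.

    Parameters
    ----------
    a, b : array-like of shape (n,)
        The two series to compare.
    w : WeightMatrix or ndarray of shape (n, n)
        Index-pair weights.  For ``p != 1`` all weights must be non-negative
        (signed p-th roots are undefined).
    spec : DistanceSpec
        Carries the exponent ``p`` (default 1).

    Returns
    -------
    float
        ``( sum_ij |a_i - b_j|^p * w_ij )^(1/p)``.  Symmetric in ``(a, b)``
        whenever ``w`` is symmetric; reduces to the Manhattan distance for
        ``w = I`` and ``p = 1``.
    """
    a = _as_series(a, "a")
    b = _as_series(b, "b")
    W = w.entries if isinstance(w, WeightMatrix) else np.asarray(w, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if W.shape != (a.size, a.size):
        raise ValueError(f"weight matrix shape {W.shape} incompatible with series length {a.size}")
    p = spec.p
    if p != 1.0 and np.any(W < 0):
        raise ValueError("p != 1 requires non-negative weights")
    diff = np.abs(a[:, None] - b[None, :])
    if p == 1.0:
        total = float(np.einsum("ij,ij->", diff, W))
        return total
    total = float(np.einsum("ij,ij->", diff**p, W))
    return total ** (1.0 / p)


def class_centroids(series: Sequence, labels: Sequence[int]) -> CentroidPair:
    """Pointwise arithmetic class means of a labelled set of equal-length series."""
    X = np.asarray(series, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("series must form a 2-D array (examples x time)")
    if X.shape[0] != y.size:
        raise ValueError("series/labels length mismatch")
    mask_sick = y == SICK
    n_s = int(mask_sick.sum())
    n_h = int((~mask_sick).sum())
    if n_h == 0 or n_s == 0:
        raise ValueError("both classes must be present")
    return CentroidPair(
        healthy_mean=X[~mask_sick].mean(axis=0),
        sick_mean=X[mask_sick].mean(axis=0),
        n_healthy=n_h,
        n_sick=n_s,
    )


def build_sign_matrix(c: CentroidPair) -> WeightMatrix:
    """Learn the sign matrix ``G`` from a pair of class-mean series.

    For every index pair ``(i, j)``,

        G_ij = sign( min(|h_i - s_j|, |s_i - h_j|)
                     - max(|h_i - h_j|, |s_i - s_j|) )

    where ``h`` and ``s`` are the healthy and sick centroids.  ``G_ij`` is
    ``+1`` when the smallest between-class gap at the pair exceeds the largest
    within-class gap (the pair helps separate the classes), ``-1`` when it is
    dominated, and ``0`` on ties (``sign(0) = 0``).  ``G`` is symmetric by
    construction.
    """
    h = c.healthy_mean
    s = c.sick_mean
    cross1 = np.abs(h[:, None] - s[None, :])  # |h_i - s_j|
    cross2 = cross1.T  # |s_i - h_j|
    within_h = np.abs(h[:, None] - h[None, :])
    within_s = np.abs(s[:, None] - s[None, :])
    g = np.sign(np.minimum(cross1, cross2) - np.maximum(within_h, within_s))
    return WeightMatrix(entries=g, lam=None)


def blend_weights(G: WeightMatrix | np.ndarray, lam: float) -> WeightMatrix:
    """Blend a sign matrix with the identity: ``(1 - lam) * G + lam * I``.

    ``lam = 0`` returns ``G`` unchanged; ``lam = 1`` returns the identity, at
    which point the dissimilarity with ``p = 1`` is the Manhattan distance.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    M = G.entries if isinstance(G, WeightMatrix) else np.asarray(G, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("G must be square")
    blended = (1.0 - lam) * M + lam * np.eye(M.shape[0])
    return WeightMatrix(entries=blended, lam=float(lam))


def lambda_grid() -> np.ndarray:
    """The search grid for the blend parameter.

    The sorted union ``{2^-i : i = 0..15} | {1 - 2^-i : i = 0..15}`` with
    duplicates removed: 31 values covering both endpoints and 0.5 once.
    """
    lo = 2.0 ** -np.arange(16)
    return np.unique(np.concatenate([lo, 1.0 - lo]))


# -- dense CSV round-trip for inspection of learned weight matrices -----------


def write_weight_matrix_csv(w: WeightMatrix | np.ndarray, path: str | Path) -> None:
    M = w.entries if isinstance(w, WeightMatrix) else np.asarray(w, dtype=float)
    header = ",".join(str(j) for j in range(M.shape[1]))
    np.savetxt(path, M, delimiter=",", header=header, comments="")


def read_weight_matrix_csv(path: str | Path) -> WeightMatrix:
    M = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return WeightMatrix(entries=M)
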