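"""Per-stream nearest-centroid classifiers and the 4-of-5 ensemble vote.

One nearest-centroid classifier (NCC) is trained per behaviour stream (lying,
ruminating, inactive, active, highly active).  Each stores the class-mean
series, a sign matrix ``G`` learned from them, and a blend parameter
``lambda`` selected by minimising the leave-one-out balanced error over the
standard grid (ties broken toward the largest ``lambda``, i.e. toward the
plain Manhattan distance).

An animal is given an ensemble label only when at least ``votes_required``
(default 4) of the five stream classifiers agree; otherwise it is left
undecided and falls through to the feature-based stage.

The leave-one-out search exploits that the blended weight matrix is affine in
``lambda``: for a test series ``x`` and centroid ``c`` only two scalars are
needed — the double sum against ``G`` and the Manhattan term — after which
every grid value is a linear combination.  The scalar pass is a numba kernel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

from .core_distance import (
    HEALTHY,
    SICK,
    CentroidPair,
    DistanceSpec,
    WeightMatrix,
    blend_weights,
    build_sign_matrix,
    class_centroids,
    dima_distance,
    lambda_grid,
)

__all__ = [
    "STREAMS",
    "UNDECIDED",
    "StreamNCCModel",
    "EnsembleDecision",
    "fit_stream_ncc",
    "predict_stream",
    "predict_stream_batch",
    "loo_balanced_error",
    "select_lambda",
    "ensemble_vote",
]

#: canonical stream order; minutes per hour spent in each behaviour
STREAMS: tuple[str, ...] = ("lying", "ruminating", "inactive", "active", "highly_active")

#: sentinel for "no ensemble decision" (fewer than votes_required agreements)
UNDECIDED = None


@dataclass(frozen=True)
class StreamNCCModel:
    """A trained nearest-centroid classifier for one behaviour stream."""

    stream_name: str
    centroids: CentroidPair
    sign_matrix: WeightMatrix
    selected_lambda: float

    def __post_init__(self) -> None:
        if self.sign_matrix.n != self.centroids.n:
            raise ValueError("centroid and sign-matrix dimensions disagree")
        if not (0.0 <= self.selected_lambda <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "stream_name": self.stream_name,
            "healthy_mean": self.centroids.healthy_mean.tolist(),
            "sick_mean": self.centroids.sick_mean.tolist(),
            "n_healthy": self.centroids.n_healthy,
            "n_sick": self.centroids.n_sick,
            "sign_matrix": self.sign_matrix.entries.tolist(),
            "selected_lambda": self.selected_lambda,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "StreamNCCModel":
        d = json.loads(Path(path).read_text())
        return cls(
            stream_name=d["stream_name"],
            centroids=CentroidPair(
                healthy_mean=np.asarray(d["healthy_mean"]),
                sick_mean=np.asarray(d["sick_mean"]),
                n_healthy=d["n_healthy"],
                n_sick=d["n_sick"],
            ),
            sign_matrix=WeightMatrix(entries=np.asarray(d["sign_matrix"])),
            selected_lambda=d["selected_lambda"],
        )


@dataclass(frozen=True)
class EnsembleDecision:
    per_stream_labels: tuple
    decision: int | None
    votes_required: int = 4


def fit_stream_ncc(
    series: Sequence, labels: Sequence[int], lam: float, stream_name: str = "stream"
) -> StreamNCCModel:
    """Fit centroids and the sign matrix on the full training set at a given lambda."""
    c = class_centroids(series, labels)
    return StreamNCCModel(
        stream_name=stream_name,
        centroids=c,
        sign_matrix=build_sign_matrix(c),
        selected_lambda=float(lam),
    )


def predict_stream(model: StreamNCCModel, x) -> int:
    """Label of the nearer centroid under the blended dissimilarity.

    An exact tie is resolved toward sick: in a screening context missing a
    sick animal is the costlier mistake.
    """
    w = blend_weights(model.sign_matrix, model.selected_lambda)
    d_h = dima_distance(x, model.centroids.healthy_mean, w)
    d_s = dima_distance(x, model.centroids.sick_mean, w)
    return SICK if d_s <= d_h else HEALTHY


def predict_stream_batch(model: StreamNCCModel, X) -> np.ndarray:
    """Vectorised :func:`predict_stream` over the rows of ``X`` (m x n)."""
    X = np.asarray(X, dtype=float)
    w = blend_weights(model.sign_matrix, model.selected_lambda).entries
    d_h = np.einsum(
        "kij,ij->k", np.abs(X[:, :, None] - model.centroids.healthy_mean[None, None, :]), w
    )
    d_s = np.einsum(
        "kij,ij->k", np.abs(X[:, :, None] - model.centroids.sick_mean[None, None, :]), w
    )
    return np.where(d_s <= d_h, SICK, HEALTHY)


@njit(cache=True)
def _cross_terms(X, C, G):  # pragma: no cover - exercised via wrappers
    """Per-row scalars: sum_ij |X[k,i]-C[k,j]| G_ij and the Manhattan term."""
    m, n = X.shape
    sg = np.zeros(m)
    si = np.zeros(m)
    for k in range(m):
        s = 0.0
        t = 0.0
        for i in range(n):
            xi = X[k, i]
            t += abs(xi - C[k, i])
            for j in range(n):
                s += abs(xi - C[k, j]) * G[i, j]
        sg[k] = s
        si[k] = t
    return sg, si


def _loo_distance_terms(X: np.ndarray, y: np.ndarray, G: np.ndarray):
    """For every training example held out: scalars against both centroids.

    Returns ``(sg_own, si_own, sg_oth, si_oth)`` where the *own*-class
    centroid is recomputed without the example via the exact downdate
    ``(mean*n - x)/(n - 1)`` and the other-class centroid is the full mean.
    """
    m = X.shape[0]
    sums = {c: X[y == c].sum(axis=0) for c in (HEALTHY, SICK)}
    counts = {c: int((y == c).sum()) for c in (HEALTHY, SICK)}
    for c, k in counts.items():
        if k < 2:
            raise ValueError("each class needs >= 2 examples for leave-one-out")
    C_own = np.empty_like(X)
    C_oth = np.empty_like(X)
    for c in (HEALTHY, SICK):
        idx = y == c
        other = SICK if c == HEALTHY else HEALTHY
        C_own[idx] = (sums[c] - X[idx]) / (counts[c] - 1)
        C_oth[idx] = sums[other] / counts[other]
    sg_own, si_own = _cross_terms(X, C_own, G)
    sg_oth, si_oth = _cross_terms(X, C_oth, G)
    return sg_own, si_own, sg_oth, si_oth


def _balanced_errors_over_grid(
    X: np.ndarray, y: np.ndarray, G: np.ndarray, lams: np.ndarray
) -> np.ndarray:
    """Leave-one-out balanced error at every lambda, sharing the scalar pass."""
    sg_own, si_own, sg_oth, si_oth = _loo_distance_terms(X, y, G)
    is_sick = y == SICK
    errs = np.empty(lams.size)
    for k, lam in enumerate(lams):
        d_own = (1.0 - lam) * sg_own + lam * si_own
        d_oth = (1.0 - lam) * sg_oth + lam * si_oth
        # predicted sick: sick centroid at least as near (tie -> sick)
        d_sick = np.where(is_sick, d_own, d_oth)
        d_healthy = np.where(is_sick, d_oth, d_own)
        pred_sick = d_sick <= d_healthy
        sens = pred_sick[is_sick].mean()
        spec = (~pred_sick[~is_sick]).mean()
        errs[k] = 1.0 - 0.5 * (sens + spec)
    return errs


def loo_balanced_error(
    series: Sequence,
    labels: Sequence[int],
    lam: float,
    *,
    rebuild_sign_matrix: bool = False,
) -> float:
    """Leave-one-out balanced error of the stream NCC at one lambda.

    For each held-out example the class centroids are recomputed without it
    and the example is classified; the error is ``1 - (Sens + Spec)/2``.  By
    default the sign matrix is built once from the full set (it is a one-time
    construction from the training data); ``rebuild_sign_matrix=True``
    rebuilds it per split.
    """
    X = np.asarray(series, dtype=float)
    y = np.asarray(labels)
    if not rebuild_sign_matrix:
        G = build_sign_matrix(class_centroids(X, y)).entries
        return float(_balanced_errors_over_grid(X, y, G, np.asarray([lam]))[0])
    # strict variant: plain loop, per-split G
    preds = np.empty(y.size, dtype=bool)
    for i in range(y.size):
        mask = np.ones(y.size, dtype=bool)
        mask[i] = False
        c = class_centroids(X[mask], y[mask])
        w = blend_weights(build_sign_matrix(c), lam)
        d_h = dima_distance(X[i], c.healthy_mean, w)
        d_s = dima_distance(X[i], c.sick_mean, w)
        preds[i] = d_s <= d_h
    is_sick = y == SICK
    sens = preds[is_sick].mean()
    spec = (~preds[~is_sick]).mean()
    return float(1.0 - 0.5 * (sens + spec))


def select_lambda(
    series: Sequence, labels: Sequence[int], *, rebuild_sign_matrix: bool = False
) -> float:
    """Grid-search lambda by leave-one-out balanced error; ties -> largest lambda."""
    X = np.asarray(series, dtype=float)
    y = np.asarray(labels)
    lams = lambda_grid()
    if rebuild_sign_matrix:
        errs = np.asarray(
            [loo_balanced_error(X, y, lam, rebuild_sign_matrix=True) for lam in lams]
        )
    else:
        G = build_sign_matrix(class_centroids(X, y)).entries
        errs = _balanced_errors_over_grid(X, y, G, lams)
    best = 0
    for k in range(1, lams.size):
        if errs[k] <= errs[best]:  # grid ascending, so <= prefers larger lambda
            best = k
    return float(lams[best])


def ensemble_vote(per_stream_labels: Sequence[int], votes_required: int = 4) -> EnsembleDecision:
    """Combine per-stream labels; decide only on >= ``votes_required`` agreement.

    Fewer than five available labels are allowed (missing sensor weeks); the
    vote then needs the same absolute count, so an animal missing two or more
    streams can never reach a 4-of-5 decision.
    """
    labels = tuple(per_stream_labels)
    n_sick = sum(1 for l in labels if l == SICK)
    n_healthy = sum(1 for l in labels if l == HEALTHY)
    if n_sick >= votes_required:
        decision: int | None = SICK
    elif n_healthy >= votes_required:
        decision = HEALTHY
    else:
        decision = UNDECIDED
    return EnsembleDecision(per_stream_labels=labels, decision=decision, votes_required=votes_required)
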