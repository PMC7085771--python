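"""Stratified cross-validation fold assignment."""

from __future__ import annotations

import numpy as np

__all__ = ["stratified_kfold"]


def stratified_kfold(labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Assign each example to one of ``k`` folds, stratified by class.

    Within each class the indices are shuffled and dealt round-robin from a
    random starting fold, so every fold's per-class count is within one of
    every other fold's.  The partition is exhaustive, disjoint, and fully
    determined by ``seed``.
    """
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds = np.full(y.size, -1, dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < k:
            raise ValueError(f"class {cls!r} has {idx.size} examples, fewer than k={k}")
        rng.shuffle(idx)
        start = int(rng.integers(k))
        folds[idx] = (start + np.arange(idx.size)) % k
    return folds
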