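"""Relief feature ranking and a Gaussian naive Bayes stage tolerant of gaps.

The feature table holds 20 named health/location/climate features per animal,
with missingness kept explicit (NaN), never encoded as a sentinel value.
Relief (the original deterministic two-class variant: one full pass, nearest
hit and nearest miss by Manhattan distance on min-max normalised features)
ranks the features on the complete-case subset; an inner stratified
cross-validation picks how many top-ranked features to keep; and a Gaussian
naive Bayes classifier is fitted per class and feature on whatever values are
available, simply omitting the likelihood term of any feature missing at
prediction time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .core_distance import HEALTHY, SICK
from .validation import stratified_kfold

__all__ = [
    "FEATURE_NAMES",
    "LOCATION_FEATURES",
    "FEATURE_BOUNDS",
    "FeatureRanking",
    "GNBModel",
    "relief_rank",
    "select_feature_count",
    "fit_gnb",
    "predict_gnb",
    "predict_gnb_table",
    "tune_threshold",
]

#: canonical feature schema, in the order features are described:
#: body condition score and back-fat thickness at -8 w / -3 w / day 0,
#: maximal pre-partum NEFA, 305-day milk-yield equivalent, maximal
#: fat/protein ratio, parity (+1 multiparous / -1 primiparous), nine
#: barn-location summaries over the two pre-partum weeks, and hours of
#: moderate heat stress (THI >= 72) in the week before calving.
FEATURE_NAMES: tuple[str, ...] = (
    "bcs_8w",
    "bcs_3w",
    "bcs_d0",
    "bft_8w",
    "bft_3w",
    "bft_d0",
    "nefa_max",
    "milk305",
    "max_fp_ratio",
    "parity",
    "loc_only_fa1_ratio",
    "loc_fa3_gt_fa1_ratio",
    "loc_fa2_gt_fa1_ratio",
    "mean_fa1",
    "mean_fa2",
    "mean_fa3",
    "sd_fa1",
    "sd_fa2",
    "sd_fa3",
    "hours_thi_ge72",
)

#: the nine location-derived features (dropped when locations are excluded)
LOCATION_FEATURES: tuple[str, ...] = FEATURE_NAMES[10:19]

#: validation bounds (lo, hi); None = unbounded on that side
FEATURE_BOUNDS: dict[str, tuple[float | None, float | None]] = {
    "bcs_8w": (1.0, 5.0),
    "bcs_3w": (1.0, 5.0),
    "bcs_d0": (1.0, 5.0),
    "bft_8w": (0.0, None),
    "bft_3w": (0.0, None),
    "bft_d0": (0.0, None),
    "nefa_max": (0.0, None),
    "milk305": (0.0, None),
    "max_fp_ratio": (0.0, None),
    "parity": (-1.0, 1.0),
    "loc_only_fa1_ratio": (0.0, 1.0),
    "loc_fa3_gt_fa1_ratio": (0.0, 1.0),
    "loc_fa2_gt_fa1_ratio": (0.0, 1.0),
    "mean_fa1": (0.0, 60.0),
    "mean_fa2": (0.0, 60.0),
    "mean_fa3": (0.0, 60.0),
    "sd_fa1": (0.0, None),
    "sd_fa2": (0.0, None),
    "sd_fa3": (0.0, None),
    "hours_thi_ge72": (0.0, 168.0),
}


@dataclass(frozen=True)
class FeatureRanking:
    """Features ordered by descending Relief weight (ties by schema order)."""

    ordered_names: tuple[str, ...]
    weights: dict[str, float]

    def top(self, k: int) -> tuple[str, ...]:
        return self.ordered_names[:k]


def _complete_cases(features: pd.DataFrame) -> np.ndarray:
    return features.notna().all(axis=1).to_numpy()


def relief_rank(features: pd.DataFrame, labels) -> FeatureRanking:
    """Relief weights from one deterministic pass over all complete cases.

    Features are min-max normalised on the complete-case subset; for each
    complete example the nearest same-class example (hit) and nearest
    other-class example (miss) under Manhattan distance are found, and each
    feature accumulates ``|x_f - miss_f| - |x_f - hit_f|``, averaged over
    examples.  Larger weights mean better class separation.
    """
    y = np.asarray(labels)
    complete = _complete_cases(features)
    X = features.to_numpy(dtype=float)[complete]
    yc = y[complete]
    if X.shape[0] == 0:
        raise ValueError("no complete-case examples for Relief")
    for cls in (HEALTHY, SICK):
        if np.sum(yc == cls) < 2:
            raise ValueError("Relief needs >= 2 complete examples per class")
    lo = X.min(axis=0)
    rng_ = X.max(axis=0) - lo
    denom = np.where(rng_ > 0, rng_, 1.0)  # constant features contribute 0 anyway
    Z = (X - lo) / denom
    m = Z.shape[0]
    D = np.abs(Z[:, None, :] - Z[None, :, :]).sum(axis=2)
    np.fill_diagonal(D, np.inf)
    same = yc[:, None] == yc[None, :]
    d_hit = np.where(same, D, np.inf)
    d_miss = np.where(~same, D, np.inf)
    hits = d_hit.argmin(axis=1)
    misses = d_miss.argmin(axis=1)
    w = (np.abs(Z - Z[misses]) - np.abs(Z - Z[hits])).mean(axis=0)
    order = np.argsort(-w, kind="stable")  # stable: ties keep schema order
    names = tuple(features.columns[i] for i in order)
    return FeatureRanking(ordered_names=names, weights=dict(zip(features.columns, w)))


@dataclass(frozen=True)
class GNBModel:
    """Gaussian naive Bayes with per-class/feature moments from available values."""

    feature_names: tuple[str, ...]
    means: np.ndarray  # shape (2, k): rows HEALTHY, SICK
    variances: np.ndarray  # shape (2, k), floored
    priors: np.ndarray  # shape (2,), sums to 1
    threshold: float = 0.5

    def with_threshold(self, threshold: float) -> "GNBModel":
        return GNBModel(self.feature_names, self.means, self.variances, self.priors, threshold)


def fit_gnb(
    features: pd.DataFrame,
    labels,
    selected_features: Sequence[str],
    *,
    uniform_priors: bool = False,
    variance_floor_factor: float = 1e-9,
) -> GNBModel:
    """Fit class-conditional Gaussians on the available values of each feature.

    Missing entries are simply excluded from the per-class moments; priors
    are empirical class frequencies unless ``uniform_priors``.  Variances are
    floored at ``variance_floor_factor`` times the largest per-class/feature
    variance, so constant features stay usable.
    """
    y = np.asarray(labels)
    sel = tuple(selected_features)
    if not sel:
        raise ValueError("at least one feature must be selected")
    X = features[list(sel)].to_numpy(dtype=float)
    k = len(sel)
    means = np.empty((2, k))
    variances = np.empty((2, k))
    for cls in (HEALTHY, SICK):
        Xc = X[y == cls]
        for f in range(k):
            vals = Xc[:, f][np.isfinite(Xc[:, f])]
            if vals.size < 2:
                raise ValueError(
                    f"feature {sel[f]!r} observed fewer than 2 times in class {cls}"
                )
            means[cls, f] = vals.mean()
            variances[cls, f] = vals.var(ddof=1)
    vmax = variances.max()
    floor = variance_floor_factor * vmax if vmax > 0 else 1e-12
    variances = np.maximum(variances, floor)
    if uniform_priors:
        priors = np.array([0.5, 0.5])
    else:
        n_sick = float(np.sum(y == SICK))
        priors = np.array([1.0 - n_sick / y.size, n_sick / y.size])
    if priors.min() <= 0:
        raise ValueError("both classes must be present")
    return GNBModel(feature_names=sel, means=means, variances=variances, priors=priors)


def _sick_log_odds(model: GNBModel, X: np.ndarray) -> np.ndarray:
    """log P(sick|x) - log P(healthy|x) per row, omitting missing features."""
    obs = np.isfinite(X)
    Xz = np.where(obs, X, 0.0)
    out = np.full(X.shape[0], math.log(model.priors[SICK]) - math.log(model.priors[HEALTHY]))
    for cls, sign in ((SICK, 1.0), (HEALTHY, -1.0)):
        mu = model.means[cls]
        var = model.variances[cls]
        ll = -0.5 * (np.log(2 * np.pi * var) + (Xz - mu) ** 2 / var)
        out += sign * np.where(obs, ll, 0.0).sum(axis=1)
    return out


def predict_gnb_table(model: GNBModel, features: pd.DataFrame) -> np.ndarray:
    """Sick posteriors for every row; NaN where all selected features are missing."""
    X = features[list(model.feature_names)].to_numpy(dtype=float)
    any_obs = np.isfinite(X).any(axis=1)
    post = np.full(X.shape[0], np.nan)
    if any_obs.any():
        lo = _sick_log_odds(model, X[any_obs])
        post[any_obs] = expit(lo)
    return post


def predict_gnb(model: GNBModel, x) -> tuple[int | None, float | None]:
    """Classify one animal from its observed selected features.

    Returns ``(label, sick_posterior)``.  Features missing in ``x`` simply
    drop their likelihood term.  If every selected feature is missing the
    result is ``(None, None)`` — an undecided signal for the caller.
    """
    if isinstance(x, dict):
        x = pd.Series(x)
    row = pd.DataFrame([x.reindex(model.feature_names)])
    post = float(predict_gnb_table(model, row)[0])
    if math.isnan(post):
        return None, None
    label = SICK if post >= model.threshold else HEALTHY
    return label, post


def _balanced_accuracy(y_true: np.ndarray, pred_sick: np.ndarray) -> float:
    is_sick = y_true == SICK
    sens = pred_sick[is_sick].mean() if is_sick.any() else np.nan
    spec = (~pred_sick[~is_sick]).mean() if (~is_sick).any() else np.nan
    return float(0.5 * (sens + spec))


def select_feature_count(
    features: pd.DataFrame,
    labels,
    ranking: FeatureRanking,
    *,
    n_folds: int = 10,
    seed: int = 0,
    uniform_priors: bool = False,
) -> int:
    """Pick how many top-ranked features to keep by inner stratified CV.

    On the complete-case subset, for each prefix length ``k`` of the ranking
    a Gaussian naive Bayes model is scored by mean balanced accuracy across
    stratified folds; the smallest ``k`` attaining the maximum wins.  The
    fold count is reduced to the minority-class complete count when that is
    below ``n_folds`` (at least 2 per class is required).
    """
    y = np.asarray(labels)
    complete = _complete_cases(features[list(ranking.ordered_names)])
    Fc = features.loc[complete, list(ranking.ordered_names)]
    yc = y[complete]
    if Fc.shape[0] == 0:
        raise ValueError("no complete-case examples")
    min_class = min(int(np.sum(yc == HEALTHY)), int(np.sum(yc == SICK)))
    if min_class < 2:
        raise ValueError("each class needs >= 2 complete examples")
    folds_k = min(n_folds, min_class)
    if Fc.shape[0] < folds_k:
        raise ValueError("fewer complete cases than folds")
    folds = stratified_kfold(yc, k=folds_k, seed=seed)
    K = len(ranking.ordered_names)
    mean_ba = np.empty(K)
    for k in range(1, K + 1):
        sel = ranking.ordered_names[:k]
        scores = []
        for f in range(folds_k):
            tr = folds != f
            te = ~tr
            model = fit_gnb(Fc.loc[tr], yc[tr], sel, uniform_priors=uniform_priors)
            post = predict_gnb_table(model, Fc.loc[te])
            scores.append(_balanced_accuracy(yc[te], post >= model.threshold))
        mean_ba[k - 1] = float(np.mean(scores))
    best = 0
    for k in range(1, K):
        if mean_ba[k] > mean_ba[best]:  # strict: ties keep the smaller k
            best = k
    return best + 1


def tune_threshold(
    model: GNBModel, features: pd.DataFrame, labels, target_sensitivity: float
) -> float:
    """Largest posterior threshold classifying >= the target share of sick
    training animals as sick (decision rule: sick iff posterior >= threshold).

    With ``m = ceil(target * n_sick)`` the answer is the m-th largest sick
    training posterior; ``target = 0`` returns the maximal threshold 1.0.
    An unreachable target (too many sick animals without any observed
    feature) warns and returns the minimal defined posterior.
    """
    if not (0.0 <= target_sensitivity <= 1.0):
        raise ValueError("target sensitivity must lie in [0, 1]")
    y = np.asarray(labels)
    sick_rows = features.loc[y == SICK]
    if sick_rows.shape[0] == 0:
        raise ValueError("no sick training examples")
    post = predict_gnb_table(model, sick_rows)
    defined = post[np.isfinite(post)]
    m = math.ceil(target_sensitivity * sick_rows.shape[0])
    if m == 0:
        return 1.0
    if m > defined.size:
        warnings.warn("target sensitivity unreachable; returning minimal threshold")
        return float(defined.min()) if defined.size else 0.0
    return float(np.sort(defined)[::-1][m - 1])
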