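"""The complete detection algorithm under stratified 10-fold cross-validation.

Per outer fold, strictly on the training ~90%:

1. for each of the five behaviour streams, select the blend parameter
   ``lambda`` minimising the leave-one-out balanced error of the
   nearest-centroid classifier;
2. label a test animal sick or healthy when at least ``votes_required``
   (default 4 of 5) stream classifiers agree;
3. animals still undecided go to the feature stage: Relief ranks the 20 (or
   11, when location features are excluded) health features on the training
   set's complete cases, an inner stratified 10-fold CV picks the feature
   count by balanced accuracy, and a missing-tolerant Gaussian naive Bayes
   classifies from whatever features the animal has.

Out-of-fold predictions are pooled into one confusion matrix ("the results
are added up"), from which the measure battery is computed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_distance import HEALTHY, SICK
from .evaluation import ConfusionMatrix, MeasureBattery, performance_measures
from .feature_classifier import (
    FEATURE_NAMES,
    LOCATION_FEATURES,
    fit_gnb,
    predict_gnb,
    relief_rank,
    select_feature_count,
    tune_threshold,
)
from .ncc import STREAMS, fit_stream_ncc, predict_stream_batch, ensemble_vote, select_lambda
from .validation import stratified_kfold

__all__ = [
    "ExperimentConfig",
    "FoldResult",
    "ExperimentReport",
    "stratified_kfold",
    "run_fold",
    "run_experiment",
    "selection_frequencies",
]

logger = logging.getLogger("ketodetect.pipeline")


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment: a time frame x location-feature inclusion, plus knobs.

    ``target_sensitivity=None`` keeps the fixed 0.5 posterior threshold;
    a value in (0, 1] tunes the naive Bayes threshold on the training sick
    posteriors instead.  ``votes_required=5`` is the strict-vote variant.
    """

    time_frame: str = "post_partum"
    include_location_features: bool = True
    votes_required: int = 4
    seed: int = 0
    uniform_priors: bool = False
    target_sensitivity: float | None = None
    fallback_label: int = HEALTHY
    rebuild_sign_matrix: bool = False
    n_folds: int = 10

    def __post_init__(self) -> None:
        if self.time_frame not in ("pre_partum", "post_partum"):
            raise ValueError("time_frame must be 'pre_partum' or 'post_partum'")
        if self.votes_required not in (4, 5):
            raise ValueError("votes_required must be 4 or 5")

    @property
    def active_features(self) -> tuple[str, ...]:
        if self.include_location_features:
            return FEATURE_NAMES
        return tuple(f for f in FEATURE_NAMES if f not in LOCATION_FEATURES)


@dataclass(frozen=True)
class FoldResult:
    predictions: pd.Series  # predicted label per test animal id
    stages: pd.Series  # 'ensemble' | 'features' | 'fallback'
    lambdas: dict[str, float]
    selected_features: tuple[str, ...]


@dataclass(frozen=True)
class ExperimentReport:
    """Pooled cross-validated result of one experiment configuration."""

    config: ExperimentConfig
    confusion: ConfusionMatrix
    measures: MeasureBattery
    fold_lambdas: list[dict[str, float]]
    fold_features: list[tuple[str, ...]]
    n_ensemble_decided: int
    n_feature_resolved: int
    n_fallback: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "confusion": asdict(self.confusion),
            "measures": self.measures.as_dict(),
            "fold_lambdas": self.fold_lambdas,
            "fold_features": [list(f) for f in self.fold_features],
            "n_ensemble_decided": self.n_ensemble_decided,
            "n_feature_resolved": self.n_feature_resolved,
            "n_fallback": self.n_fallback,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentReport":
        d = json.loads(Path(path).read_text())
        cm = ConfusionMatrix(**d["confusion"])
        return cls(
            config=ExperimentConfig(**d["config"]),
            confusion=cm,
            measures=performance_measures(cm),
            fold_lambdas=d["fold_lambdas"],
            fold_features=[tuple(f) for f in d["fold_features"]],
            n_ensemble_decided=d["n_ensemble_decided"],
            n_feature_resolved=d["n_feature_resolved"],
            n_fallback=d["n_fallback"],
        )


def _stream_tables(bundle, config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    return bundle.series_pre if config.time_frame == "pre_partum" else bundle.series_post


def _complete_rows(df: pd.DataFrame, ids: Sequence[str]) -> list[str]:
    present = [i for i in ids if i in df.index]
    if not present:
        return []
    ok = df.loc[present].notna().all(axis=1)
    return [i for i in present if ok[i]]


def run_fold(bundle, train_ids: Sequence[str], test_ids: Sequence[str], config: ExperimentConfig) -> FoldResult:
    """Execute Steps 1-3 on one outer train/test split.

    Every test animal receives exactly one label: by the stream ensemble when
    enough classifiers agree, by the feature classifier otherwise, and by the
    configured fallback label when no feature is observed either.
    """
    streams = _stream_tables(bundle, config)
    y = bundle.labels
    y_train = y.loc[list(train_ids)]
    if y_train.nunique() < 2:
        raise ValueError("training fold must contain both classes")

    # Step 1: per-stream lambda by LOO balanced error, then fit on full fold
    models = {}
    lambdas: dict[str, float] = {}
    for stream in STREAMS:
        avail = _complete_rows(streams[stream], train_ids)
        ys = y.loc[avail].to_numpy()
        if min(np.sum(ys == SICK), np.sum(ys == HEALTHY)) < 2:
            continue  # stream unusable this fold
        X = streams[stream].loc[avail].to_numpy(dtype=float)
        lam = select_lambda(X, ys, rebuild_sign_matrix=config.rebuild_sign_matrix)
        models[stream] = fit_stream_ncc(X, ys, lam, stream_name=stream)
        lambdas[stream] = lam

    # Step 2: ensemble vote on the test animals
    stream_votes: dict[str, dict[str, int]] = {i: {} for i in test_ids}
    for stream, model in models.items():
        avail = _complete_rows(streams[stream], test_ids)
        if not avail:
            continue
        X = streams[stream].loc[avail].to_numpy(dtype=float)
        preds = predict_stream_batch(model, X)
        for i, p in zip(avail, preds):
            stream_votes[i][stream] = int(p)
    decided: dict[str, int] = {}
    undecided: list[str] = []
    for i in test_ids:
        votes = list(stream_votes[i].values())
        decision = ensemble_vote(votes, config.votes_required).decision
        if decision is None:
            undecided.append(i)
        else:
            decided[i] = decision

    # Step 3: feature classifier for the remaining animals
    stages = {i: "ensemble" for i in decided}
    n_fallback = 0
    selected: tuple[str, ...] = ()
    if undecided:
        F_train = bundle.features.reindex(list(train_ids))[list(config.active_features)]
        yt = y_train.to_numpy()
        ranking = relief_rank(F_train, yt)
        k = select_feature_count(
            F_train, yt, ranking, seed=config.seed, uniform_priors=config.uniform_priors
        )
        selected = ranking.top(k)
        gnb = fit_gnb(F_train, yt, selected, uniform_priors=config.uniform_priors)
        if config.target_sensitivity is not None:
            thr = tune_threshold(gnb, F_train, yt, config.target_sensitivity)
            gnb = gnb.with_threshold(thr)
        F_test = bundle.features.reindex(undecided)[list(config.active_features)]
        for i in undecided:
            label, _post = predict_gnb(gnb, F_test.loc[i])
            if label is None:
                label = config.fallback_label
                stages[i] = "fallback"
                n_fallback += 1
            else:
                stages[i] = "features"
            decided[i] = label
    preds = pd.Series({i: decided[i] for i in test_ids}, dtype=int)
    return FoldResult(
        predictions=preds,
        stages=pd.Series({i: stages[i] for i in test_ids}),
        lambdas=lambdas,
        selected_features=selected,
    )


def run_experiment(bundle, config: ExperimentConfig) -> ExperimentReport:
    """Stratified outer 10-fold CV; pooled confusion matrix and measures."""
    ids = np.asarray(bundle.labels.index)
    y = bundle.labels.to_numpy()
    folds = stratified_kfold(y, k=config.n_folds, seed=config.seed)
    all_preds: dict[str, int] = {}
    fold_lambdas: list[dict[str, float]] = []
    fold_features: list[tuple[str, ...]] = []
    n_ens = n_feat = n_fb = 0
    for f in range(config.n_folds):
        test_ids = ids[folds == f].tolist()
        train_ids = ids[folds != f].tolist()
        res = run_fold(bundle, train_ids, test_ids, config)
        logger.info(
            "fold %d: lambdas=%s features=%s", f, res.lambdas, list(res.selected_features)
        )
        all_preds.update(res.predictions.to_dict())
        fold_lambdas.append(res.lambdas)
        fold_features.append(res.selected_features)
        counts = res.stages.value_counts()
        n_ens += int(counts.get("ensemble", 0))
        n_feat += int(counts.get("features", 0))
        n_fb += int(counts.get("fallback", 0))
    pred = np.asarray([all_preds[i] for i in ids])
    cm = ConfusionMatrix.from_predictions(y, pred)
    return ExperimentReport(
        config=config,
        confusion=cm,
        measures=performance_measures(cm),
        fold_lambdas=fold_lambdas,
        fold_features=fold_features,
        n_ensemble_decided=n_ens,
        n_feature_resolved=n_feat,
        n_fallback=n_fb,
    )


def selection_frequencies(reports: Sequence[ExperimentReport]) -> pd.Series:
    """How often each feature entered the final naive Bayes, across all folds."""
    if not reports:
        raise ValueError("at least one report required")
    counts: dict[str, int] = {name: 0 for name in FEATURE_NAMES}
    for rep in reports:
        for feats in rep.fold_features:
            for f in feats:
                counts[f] += 1
    return pd.Series(counts, name="times_selected")
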