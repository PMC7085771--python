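"""CSV dialects, dataset bundles, and validation.

Series files are long-format CSV with columns ``animal_id, hour`` plus the
five stream columns (minutes per hour); hours are 0-based within each week
(pre-partum hour 167 is the hour before calving, post-partum hour 0 the
first after).  Feature files have one row per animal with the canonical
feature header; an empty cell is an explicit missing value.  Label files map
``animal_id`` to ``healthy``/``sick``.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_distance import HEALTHY, SICK
from .feature_classifier import FEATURE_BOUNDS, FEATURE_NAMES, LOCATION_FEATURES
from .ncc import STREAMS

__all__ = [
    "DatasetBundle",
    "read_series_csv",
    "write_series_csv",
    "read_features_csv",
    "write_features_csv",
    "read_labels_csv",
    "write_labels_csv",
    "save_bundle",
    "load_bundle",
    "bundle_from_cohort",
]

logger = logging.getLogger("ketodetect.io")

#: activity trio must add to 60 minutes within this tolerance
BUDGET_TOLERANCE = 1e-6

_TRIO = ("inactive", "active", "highly_active")
_LABEL_STR = {HEALTHY: "healthy", SICK: "sick"}
_STR_LABEL = {v: k for k, v in _LABEL_STR.items()}


@dataclass
class DatasetBundle:
    """Series tables for both time frames, the feature table, and labels."""

    series_pre: dict[str, pd.DataFrame]
    series_post: dict[str, pd.DataFrame]
    features: pd.DataFrame
    labels: pd.Series
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = set(self.labels.index)
        if len(ids) != self.labels.index.size:
            raise ValueError("duplicate animal ids in labels")
        if not set(self.features.index) <= ids:
            raise ValueError("feature table contains unknown animal ids")


def write_series_csv(series: dict[str, pd.DataFrame], path: str | Path) -> None:
    frames = []
    ids = series[STREAMS[0]].index
    hours = series[STREAMS[0]].columns
    for aid in ids:
        df = pd.DataFrame({"animal_id": aid, "hour": hours})
        for s in STREAMS:
            df[s] = series[s].loc[aid].to_numpy()
        frames.append(df)
    # full repr precision: the activity budget must survive the round trip
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_series_csv(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read and validate a long-format series file into per-stream tables.

    Validates the [0, 60] range per value and the exact 60-minute activity
    budget per hour; duplicate (animal, hour) rows are an error; missing
    hours are reported per animal via the module logger and become NaN.
    """
    df = pd.read_csv(path)
    expected = ["animal_id", "hour", *STREAMS]
    if list(df.columns) != expected:
        raise ValueError(f"malformed header: expected {expected}, got {list(df.columns)}")
    dup = df.duplicated(subset=["animal_id", "hour"])
    if dup.any():
        raise ValueError(f"duplicate (animal, hour) at row {int(np.flatnonzero(dup)[0])}")
    vals = df[list(STREAMS)].to_numpy(dtype=float)
    bad = (vals < 0) | (vals > 60)
    if bad.any():
        r = int(np.flatnonzero(bad.any(axis=1))[0])
        raise ValueError(f"value outside [0, 60] at row {r} (animal {df['animal_id'].iloc[r]!r})")
    trio = df[list(_TRIO)].to_numpy(dtype=float).sum(axis=1)
    off = np.abs(trio - 60.0) > BUDGET_TOLERANCE
    if off.any():
        r = int(np.flatnonzero(off)[0])
        raise ValueError(
            f"activity budget violated at row {r} (animal {df['animal_id'].iloc[r]!r}): sum={trio[r]}"
        )
    n_hours = int(df["hour"].max()) + 1
    out: dict[str, pd.DataFrame] = {}
    for s in STREAMS:
        wide = df.pivot(index="animal_id", columns="hour", values=s)
        wide = wide.reindex(columns=range(n_hours))
        out[s] = wide
    gaps = out[STREAMS[0]].isna().sum(axis=1)
    for aid, g in gaps[gaps > 0].items():
        logger.warning("animal %s is missing %d hour(s)", aid, int(g))
    return out


def write_features_csv(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, index_label="animal_id")


def read_features_csv(path: str | Path) -> pd.DataFrame:
    """Read the feature table; empty cells become explicit missing values."""
    df = pd.read_csv(path, index_col="animal_id")
    full = list(FEATURE_NAMES)
    no_loc = [f for f in FEATURE_NAMES if f not in LOCATION_FEATURES]
    if list(df.columns) not in (full, no_loc):
        unknown = set(df.columns) - set(full)
        if unknown:
            raise ValueError(f"unknown feature column(s): {sorted(unknown)}")
        raise ValueError("feature header must be the canonical 20- or 11-name set, in order")
    for name in df.columns:
        col = df[name].to_numpy(dtype=float)
        obs = np.isfinite(col)
        if name == "parity":
            ok = np.isin(col[obs], (-1.0, 1.0))
            if not ok.all():
                raise ValueError("parity must be -1 or +1")
            continue
        lo, hi = FEATURE_BOUNDS[name]
        if lo is not None and (col[obs] < lo).any() or hi is not None and (col[obs] > hi).any():
            raise ValueError(f"feature {name!r} outside its valid range [{lo}, {hi}]")
    return df


def write_labels_csv(labels: pd.Series, path: str | Path) -> None:
    out = labels.map(_LABEL_STR)
    out.rename("label").to_csv(path, index_label="animal_id")


def read_labels_csv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, index_col="animal_id")
    bad = ~df["label"].isin(_STR_LABEL)
    if bad.any():
        raise ValueError(f"unknown label value {df['label'][bad].iloc[0]!r}")
    return df["label"].map(_STR_LABEL).astype(int)


def save_bundle(bundle: DatasetBundle, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_series_csv(bundle.series_pre, d / "series_pre.csv")
    write_series_csv(bundle.series_post, d / "series_post.csv")
    write_features_csv(bundle.features, d / "features.csv")
    write_labels_csv(bundle.labels, d / "labels.csv")
    meta = dict(bundle.meta)
    meta.setdefault("created", datetime.datetime.now(datetime.timezone.utc).isoformat())
    (d / "meta.json").write_text(json.dumps(meta, indent=2))


def load_bundle(directory: str | Path) -> DatasetBundle:
    d = Path(directory)
    meta = {}
    if (d / "meta.json").exists():
        meta = json.loads((d / "meta.json").read_text())
    return DatasetBundle(
        series_pre=read_series_csv(d / "series_pre.csv"),
        series_post=read_series_csv(d / "series_post.csv"),
        features=read_features_csv(d / "features.csv"),
        labels=read_labels_csv(d / "labels.csv"),
        meta=meta,
    )


def bundle_from_cohort(cohort) -> DatasetBundle:
    """Wrap a :class:`~ketodetect.synthetic.SyntheticCohort` for the pipeline."""
    meta = {}
    if cohort.spec is not None:
        meta = {"seed": cohort.spec.seed, "n_animals": cohort.spec.n_animals}
    return DatasetBundle(
        series_pre=cohort.series_pre,
        series_post=cohort.series_post,
        features=cohort.features,
        labels=pd.Series(cohort.labels, index=list(cohort.animal_ids), name="label"),
        meta=meta,
    )
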