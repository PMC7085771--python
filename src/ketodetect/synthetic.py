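"""Synthetic cow cohorts with the statistical structure the method assumes.

No public accession of the original farm data exists, so every stage of the
package is exercised on simulated cohorts that emulate the documented
structure: a ~15.8% subclinical-ketosis prevalence, five hourly behaviour
streams over one-week pre- and post-partum windows under the exact 60-minute
budget (inactive + active + highly-active = 60 each hour), class-conditional
feature distributions matching the published per-class means/SDs, and
missing-completely-at-random feature gaps at the published per-feature rates
(with visit-paired BCS/BFT gaps and block-missing location features).

Streams are a diurnal sinusoid plus a class offset plus Gaussian noise;
the activity trio is drawn as a Dirichlet composition scaled to 60 so the
hourly budget holds exactly by construction rather than by clipping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .core_distance import HEALTHY, SICK
from .feature_classifier import FEATURE_BOUNDS, FEATURE_NAMES, LOCATION_FEATURES
from .ncc import STREAMS

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "DEFAULT_FEATURE_PARAMS",
    "DEFAULT_MISSING_RATES",
    "DEFAULT_STREAM_OFFSETS",
    "generate_cohort",
    "apply_missingness",
    "label_from_bhb",
]

#: blood BHB threshold (mmol/L) above which an animal is labelled sick
BHB_THRESHOLD: float = 1.2

#: per-class (mean_healthy, sd_healthy, mean_sick, sd_sick) for every
#: Gaussian feature; parity is handled separately as a +/-1 Bernoulli whose
#: class means match the published 0.096 (healthy) and 0.151 (sick).
DEFAULT_FEATURE_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "bcs_8w": (3.19, 0.432, 3.377, 0.446),
    "bcs_3w": (3.426, 0.428, 3.613, 0.445),
    "bcs_d0": (3.298, 0.41, 3.395, 0.424),
    "bft_8w": (13.425, 5.002, 15.527, 5.83),
    "bft_3w": (15.393, 5.261, 17.581, 5.261),
    "bft_d0": (15.248, 4.846, 16.892, 5.577),
    "nefa_max": (0.296, 0.222, 0.384, 0.256),
    "milk305": (11538.3, 1528.18, 11317.7, 1713.15),
    "max_fp_ratio": (1.686, 0.327, 1.676, 0.372),
    "loc_only_fa1_ratio": (0.703, 0.09, 0.748, 0.093),
    "loc_fa3_gt_fa1_ratio": (0.074, 0.032, 0.059, 0.026),
    "loc_fa2_gt_fa1_ratio": (0.098, 0.042, 0.08, 0.037),
    "mean_fa1": (50.658, 3.188, 52.285, 2.96),
    "mean_fa2": (5.564, 1.853, 4.705, 1.857),
    "mean_fa3": (3.563, 1.478, 2.825, 1.155),
    "sd_fa1": (16.821, 2.937, 15.336, 2.811),
    "sd_fa2": (11.711, 2.309, 10.538, 2.374),
    "sd_fa3": (10.233, 2.577, 8.799, 2.039),
    "hours_thi_ge72": (6.981, 11.911, 10.858, 12.576),
}

#: P(multiparous) per class, from the published +/-1 parity class means
PARITY_P_MULTI: dict[int, float] = {HEALTHY: (1 + 0.096) / 2, SICK: (1 + 0.151) / 2}

#: MCAR missingness per feature (fractions); BCS/BFT visit pairs share one
#: mask per animal, the nine location features are missing as a block.
DEFAULT_MISSING_RATES: dict[str, float] = {
    "bcs_8w": 0.3145,
    "bcs_3w": 0.1103,
    "bcs_d0": 0.0119,
    "bft_8w": 0.3145,
    "bft_3w": 0.1103,
    "bft_d0": 0.0119,
    "nefa_max": 0.0179,
    "milk305": 0.0015,
    "max_fp_ratio": 0.0,
    "parity": 0.0015,
    **{name: 0.2623 for name in LOCATION_FEATURES},
    "hours_thi_ge72": 0.0,
}

#: same-visit BCS/BFT pairs that are observed or missing together
VISIT_PAIRS: tuple[tuple[str, str], ...] = (
    ("bcs_8w", "bft_8w"),
    ("bcs_3w", "bft_3w"),
    ("bcs_d0", "bft_d0"),
)

#: class-mean stream offsets for sick animals, minutes per hour.  Sick cows
#: lie more, ruminate less, and shift activity toward inactivity; the three
#: activity offsets sum to zero so the 60-minute budget is preserved.
DEFAULT_STREAM_OFFSETS: dict[str, float] = {
    "lying": 2.0,
    "ruminating": -4.0,
    "inactive": 3.0,
    "active": -2.4,
    "highly_active": -0.6,
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated cohort.

    ``stream_offsets`` are sick-minus-healthy class mean differences in
    minutes per hour; ``animal_effect_sd`` is the SD (min/h) of per-animal
    random intercepts — the between-animal heterogeneity that keeps stream
    classification non-trivial even though hourly noise averages out over a
    week; ``correlation`` couples a per-animal severity latent into both
    stream and feature effects (0 = independent given the label).
    """

    n_animals: int = 671
    prevalence: float = 0.158
    stream_offsets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STREAM_OFFSETS)
    )
    stream_noise_sd: float = 6.0
    animal_effect_sd: float = 3.0
    composition_concentration: float = 60.0
    feature_params: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_PARAMS)
    )
    missing_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES)
    )
    series_length: int = 168
    seed: int = 0
    correlation: float = 0.0
    emit_bhb: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        trio = sum(self.stream_offsets[s] for s in ("inactive", "active", "highly_active"))
        if abs(trio) > 1e-9:
            raise ValueError("activity-trio offsets must sum to 0 (60-minute budget)")
        for s, off in self.stream_offsets.items():
            if s in ("lying", "ruminating") and not (-60 < off < 60):
                raise ValueError(f"offset for {s} leaves [0, 60]")
        if any(not (0.0 <= r <= 1.0) for r in self.missing_rates.values()):
            raise ValueError("missingness rates must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort: ids, labels, per-frame stream tables, features."""

    animal_ids: tuple[str, ...]
    labels: np.ndarray
    series_pre: dict[str, pd.DataFrame]  # stream -> (animals x hours)
    series_post: dict[str, pd.DataFrame]
    features: pd.DataFrame  # animals x 20, NaN = missing
    bhb: pd.DataFrame | None = None  # days 3/5/8 of lactation, mmol/L
    spec: CohortSpec | None = None


def label_from_bhb(bhb_day3: float, bhb_day5: float, bhb_day8: float) -> int:
    """Sick iff any available BHB value strictly exceeds 1.2 mmol/L."""
    vals = [v for v in (bhb_day3, bhb_day5, bhb_day8) if v is not None and not math.isnan(v)]
    if not vals:
        raise ValueError("all BHB values missing")
    return SICK if any(v > BHB_THRESHOLD for v in vals) else HEALTHY


def _diurnal_base(stream: str, hours: np.ndarray) -> np.ndarray:
    """Mean minutes/hour over the day for a healthy animal, per stream."""
    phase = 2 * np.pi * (hours % 24) / 24.0
    if stream == "lying":
        return 32.0 + 10.0 * np.cos(phase)  # most lying at night
    if stream == "ruminating":
        return 22.0 + 6.0 * np.cos(phase - np.pi / 2)
    raise ValueError(stream)


def _activity_proportions(hours: np.ndarray) -> np.ndarray:
    """Healthy-class mean composition (inactive, active, highly active)."""
    phase = 2 * np.pi * (hours % 24) / 24.0
    active = 16.0 + 6.0 * np.cos(phase - np.pi)  # more active during the day
    highly = 4.0 + 1.5 * np.cos(phase - np.pi)
    inactive = 60.0 - active - highly
    return np.stack([inactive, active, highly], axis=-1) / 60.0


def _truncated_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    """Gaussian draws with out-of-range tails re-drawn (not clipped)."""
    out = rng.normal(mean, sd, size)
    lo_ = -np.inf if lo is None else lo
    hi_ = np.inf if hi is None else hi
    for _ in range(100):
        bad = (out < lo_) | (out > hi_)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.clip(out, lo_, hi_)


def _simulate_streams(
    spec: CohortSpec, labels: np.ndarray, severity: np.ndarray, rng: np.random.Generator
) -> dict[str, pd.DataFrame]:
    n = spec.n_animals
    T = spec.series_length
    hours = np.arange(T)
    ids = [f"cow{i:04d}" for i in range(n)]
    effect = np.where(labels == SICK, 1.0, 0.0) * severity  # per-animal multiplier
    out: dict[str, pd.DataFrame] = {}
    for stream in ("lying", "ruminating"):
        base = _diurnal_base(stream, hours)[None, :]
        intercept = rng.normal(0.0, spec.animal_effect_sd, n)  # animal's own level
        offset = spec.stream_offsets[stream] * effect[:, None] + intercept[:, None]
        noise = rng.normal(0.0, spec.stream_noise_sd, (n, T))
        out[stream] = pd.DataFrame(
            np.clip(base + offset + noise, 0.0, 60.0), index=ids, columns=hours
        )
    # activity trio: Dirichlet around class-specific proportions, scaled to 60
    props = _activity_proportions(hours)[None, :, :]  # (1, T, 3)
    trio_off = np.array(
        [spec.stream_offsets[s] for s in ("inactive", "active", "highly_active")]
    )
    # per-animal tilt along the same budget-preserving direction as the
    # class offset, so individual habit differences also respect the 60 min
    tilt_dir = trio_off / np.linalg.norm(trio_off) if np.linalg.norm(trio_off) > 0 else np.zeros(3)
    tilt = rng.normal(0.0, spec.animal_effect_sd, n)[:, None, None] * tilt_dir[None, None, :]
    shift = (trio_off / 60.0)[None, None, :] * effect[:, None, None] + tilt / 60.0
    centred = np.clip(props + shift, 1e-3, None)
    centred /= centred.sum(axis=2, keepdims=True)
    alpha = spec.composition_concentration * centred
    draws = rng.standard_gamma(alpha)  # Dirichlet via normalised gammas
    draws /= draws.sum(axis=2, keepdims=True)
    trio = 60.0 * draws
    for k, stream in enumerate(("inactive", "active", "highly_active")):
        out[stream] = pd.DataFrame(trio[:, :, k], index=ids, columns=hours)
    return out


def _adjusted_loc(target_mean: float, sd: float, lo: float | None, hi: float | None) -> float:
    """Gaussian location whose [lo, hi]-truncation has the target mean.

    Redrawing out-of-range tails shifts the realised mean away from the
    nominal location (e.g. upward for a non-negative feature with mass near
    zero); solving for the location keeps the realised class means on the
    published values.
    """
    lo_ = -np.inf if lo is None else lo
    hi_ = np.inf if hi is None else hi
    if np.isinf(lo_) and np.isinf(hi_):
        return target_mean

    def gap(mu: float) -> float:
        a, b = (lo_ - mu) / sd, (hi_ - mu) / sd
        return truncnorm.mean(a, b, loc=mu, scale=sd) - target_mean

    if abs(gap(target_mean)) < 1e-12:
        return target_mean
    span = 10.0 * sd
    return brentq(gap, target_mean - span, target_mean + span, xtol=1e-10)


def _simulate_features(
    spec: CohortSpec, labels: np.ndarray, severity: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    n = spec.n_animals
    sick = labels == SICK
    cols: dict[str, np.ndarray] = {}
    for name in FEATURE_NAMES:
        if name == "parity":
            p = np.where(sick, PARITY_P_MULTI[SICK], PARITY_P_MULTI[HEALTHY])
            cols[name] = np.where(rng.random(n) < p, 1.0, -1.0)
            continue
        mh, sh, ms, ss = spec.feature_params[name]
        lo, hi = FEATURE_BOUNDS[name]
        mh_adj = _adjusted_loc(mh, sh, lo, hi)
        ms_adj = _adjusted_loc(ms, ss, lo, hi)
        mean = np.where(sick, mh_adj + (ms_adj - mh_adj) * severity, mh_adj)
        sd = np.where(sick, ss, sh)
        vals = rng.normal(mean, sd)
        lo_ = -np.inf if lo is None else lo
        hi_ = np.inf if hi is None else hi
        for _ in range(100):
            bad = (vals < lo_) | (vals > hi_)
            if not bad.any():
                break
            vals[bad] = rng.normal(mean[bad], sd[bad])
        cols[name] = np.clip(vals, lo_, hi_)
    ids = [f"cow{i:04d}" for i in range(n)]
    return pd.DataFrame(cols, index=ids, columns=list(FEATURE_NAMES))


def _simulate_bhb(labels: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """BHB (mmol/L) on days 3/5/8, consistent with the >1.2 case definition."""
    n = labels.size
    vals = rng.uniform(0.3, 1.15, (n, 3))  # healthy range, strictly <= 1.2
    sick = np.flatnonzero(labels == SICK)
    peak_day = rng.integers(0, 3, sick.size)
    vals[sick, peak_day] = rng.uniform(1.3, 3.0, sick.size)
    return pd.DataFrame(
        vals, index=[f"cow{i:04d}" for i in range(n)], columns=["day3", "day5", "day8"]
    )


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a fully observed cohort; apply_missingness adds the feature gaps."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_animals
    labels = np.where(rng.random(n) < spec.prevalence, SICK, HEALTHY)
    if spec.correlation > 0:
        z = rng.normal(0.0, 1.0, n)
        severity = np.clip(1.0 + spec.correlation * z, 0.0, 2.0)
    else:
        severity = np.ones(n)
    bhb = _simulate_bhb(labels, rng) if spec.emit_bhb else None
    if bhb is not None:
        labels = np.array(
            [label_from_bhb(*bhb.iloc[i]) for i in range(n)]
        )
    series_pre = _simulate_streams(spec, labels, severity, rng)
    series_post = _simulate_streams(spec, labels, severity, rng)
    features = _simulate_features(spec, labels, severity, rng)
    return SyntheticCohort(
        animal_ids=tuple(f"cow{i:04d}" for i in range(n)),
        labels=labels,
        series_pre=series_pre,
        series_post=series_post,
        features=features,
        bhb=bhb,
        spec=spec,
    )


def apply_missingness(
    cohort: SyntheticCohort, rates: dict[str, float] | None = None, seed: int = 0
) -> SyntheticCohort:
    """Mask feature entries MCAR at the given per-feature rates.

    BCS/BFT values from the same farm visit are masked jointly (one draw per
    visit per animal), and the nine location features are masked as a block
    (they come from a single positioning source).  Rates within a visit pair
    and within the location block must therefore agree.
    """
    rates = dict(DEFAULT_MISSING_RATES if rates is None else rates)
    missing = set(FEATURE_NAMES) - set(rates)
    if missing:
        raise ValueError(f"missing rates for features: {sorted(missing)}")
    for r in rates.values():
        if not (0.0 <= r <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
    for a, b in VISIT_PAIRS:
        if rates[a] != rates[b]:
            raise ValueError(f"visit pair {a}/{b} must share one rate")
    loc_rates = {rates[f] for f in LOCATION_FEATURES}
    if len(loc_rates) != 1:
        raise ValueError("location features must share one rate")
    rng = np.random.default_rng(seed)
    F = cohort.features.copy()
    n = F.shape[0]
    paired = {f for pair in VISIT_PAIRS for f in pair}
    for a, b in VISIT_PAIRS:
        mask = rng.random(n) < rates[a]
        F.loc[mask, [a, b]] = np.nan
    block = rng.random(n) < next(iter(loc_rates))
    F.loc[block, list(LOCATION_FEATURES)] = np.nan
    for name in FEATURE_NAMES:
        if name in paired or name in LOCATION_FEATURES:
            continue
        mask = rng.random(n) < rates[name]
        F.loc[mask, name] = np.nan
    return replace(cohort, features=F)
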