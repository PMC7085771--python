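"""Confusion-matrix measure battery and feature-screening statistics.

Sick is the positive class throughout.  The measure battery covers accuracy,
sensitivity, specificity, Youden's J (= Sens + Spec - 1), Cohen's kappa, the
F-score, precision, Matthews correlation, negative predictive value and Lift
(precision divided by class prevalence).  Feature screening compares each
feature's healthy and sick distributions with a two-sided Mann-Whitney U test
and flags significance at a Bonferroni-corrected level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .core_distance import SICK

__all__ = [
    "ConfusionMatrix",
    "MeasureBattery",
    "performance_measures",
    "youden_index",
    "f_score",
    "mann_whitney_u",
    "bonferroni_threshold",
    "compare_features",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Pooled 2x2 confusion matrix with sick as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        t = np.asarray(y_true) == SICK
        p = np.asarray(y_pred) == SICK
        return cls(
            tp=int(np.sum(t & p)),
            fp=int(np.sum(~t & p)),
            tn=int(np.sum(~t & ~p)),
            fn=int(np.sum(t & ~p)),
        )


@dataclass(frozen=True)
class MeasureBattery:
    acc: float
    sens: float
    spec: float
    j: float
    kappa: float
    f_score: float
    prec: float
    mcc: float
    npv: float
    lift: float

    def as_dict(self) -> dict[str, float]:
        return {
            "Acc": self.acc,
            "Sens": self.sens,
            "Spec": self.spec,
            "J": self.j,
            "kappa": self.kappa,
            "F": self.f_score,
            "Prec": self.prec,
            "MCC": self.mcc,
            "NPV": self.npv,
            "Lift": self.lift,
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else float("nan")


def youden_index(sens: float, spec: float) -> float:
    """Youden's J = Sens + Spec - 1."""
    return sens + spec - 1.0


def f_score(prec: float, sens: float) -> float:
    """F-score: harmonic mean of precision and sensitivity."""
    return _safe_div(2.0 * prec * sens, prec + sens)


def performance_measures(cm: ConfusionMatrix) -> MeasureBattery:
    """Standard measures of a 2x2 matrix; undefined ratios come back as NaN."""
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    prec = _safe_div(tp, tp + fp)
    npv = _safe_div(tn, tn + fn)
    acc = (tp + tn) / total
    j = youden_index(sens, spec)
    f = f_score(prec, sens)
    # Cohen's kappa: observed vs chance agreement of the two marginals
    p_yes = _safe_div((tp + fp) * (tp + fn), total * total)
    p_no = _safe_div((tn + fn) * (tn + fp), total * total)
    kappa = _safe_div(acc - (p_yes + p_no), 1.0 - (p_yes + p_no))
    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den)
    prevalence = (tp + fn) / total
    lift = _safe_div(prec, prevalence)
    return MeasureBattery(
        acc=acc, sens=sens, spec=spec, j=j, kappa=kappa,
        f_score=f, prec=prec, mcc=mcc, npv=npv, lift=lift,
    )


def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Exact null distribution of U (no ties): counts of each value 0..n1*n2.

    Standard recursion N(u; m, n) = N(u - n; m - 1, n) + N(u; m, n - 1).
    """
    umax = n1 * n2
    # dp[m, u] = N(u; m, n) for the current n; start at n = 0
    dp = np.zeros((n1 + 1, umax + 1))
    dp[:, 0] = 1.0  # n = 0: only u = 0, for any m
    for n in range(1, n2 + 1):
        new = np.zeros_like(dp)
        new[0, 0] = 1.0
        for m in range(1, n1 + 1):
            new[m] = dp[m]  # N(u; m, n-1)
            new[m, n:] += new[m - 1, : umax + 1 - n]  # N(u - n; m-1, n)
        dp = new
    return dp[n1]


def mann_whitney_u(x, y, *, exact_limit: int = 20) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with mid-rank ties.

    Returns ``(U, p)`` where ``U`` is the statistic of the first sample.  For
    samples of at most ``exact_limit`` per group without ties the p-value is
    computed from the exact null distribution of U; otherwise a tie-corrected
    normal approximation with continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))
    if n1 <= exact_limit and n2 <= exact_limit and not has_ties:
        counts = _u_null_counts(n1, n2)
        total = counts.sum()
        k = int(round(u1))
        p_le = counts[: k + 1].sum() / total
        p_ge = counts[k:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return float(u1), float(p)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # all pooled values identical
        return float(u1), 1.0
    u_big = max(u1, u2)
    z = (u_big - mu - 0.5) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * norm.sf(z))
    return float(u1), float(p)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance level alpha/m under Bonferroni correction."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def compare_features(features: pd.DataFrame, labels, alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature class means +/- SD and Mann-Whitney screening table.

    Each feature is compared on its pairwise-complete values (rows where the
    feature is observed).  SDs are sample SDs (ddof=1).  The ``significant``
    column flags p-values below ``alpha / n_features``.
    """
    y = np.asarray(labels)
    if features.shape[0] != y.size:
        raise ValueError("features/labels length mismatch")
    thr = bonferroni_threshold(alpha, features.shape[1])
    sick = y == SICK
    rows = []
    for name in features.columns:
        col = features[name].to_numpy(dtype=float)
        obs = np.isfinite(col)
        xh = col[obs & ~sick]
        xs = col[obs & sick]
        if xh.size == 0 or xs.size == 0:
            raise ValueError(f"feature {name!r} observed in only one class")
        _, p = mann_whitney_u(xh, xs)
        rows.append(
            {
                "feature": name,
                "mean_healthy": xh.mean(),
                "sd_healthy": xh.std(ddof=1) if xh.size > 1 else float("nan"),
                "mean_sick": xs.mean(),
                "sd_sick": xs.std(ddof=1) if xs.size > 1 else float("nan"),
                "p_value": p,
                "significant": p < thr,
            }
        )
    return pd.DataFrame(rows).set_index("feature")
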