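"""Tests for Relief ranking, feature-count selection, and the missing-tolerant GNB."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from conftest import toy_feature_table
from ketodetect.core_distance import HEALTHY, SICK
from ketodetect.feature_classifier import (
    FEATURE_NAMES,
    fit_gnb,
    predict_gnb,
    predict_gnb_table,
    relief_rank,
    select_feature_count,
    tune_threshold,
)


def naive_relief(X, y):
    """Independent straight-line Relief: normalise, nearest hit/miss, average."""
    X = np.asarray(X, dtype=float)
    lo, hi = X.min(axis=0), X.max(axis=0)
    denom = np.where(hi - lo > 0, hi - lo, 1.0)
    Z = (X - lo) / denom
    m, k = Z.shape
    w = np.zeros(k)
    for i in range(m):
        d = np.abs(Z - Z[i]).sum(axis=1)
        d[i] = np.inf
        hit = np.argmin(np.where(y == y[i], d, np.inf))
        miss = np.argmin(np.where(y != y[i], d, np.inf))
        w += np.abs(Z[i] - Z[miss]) - np.abs(Z[i] - Z[hit])
    return w / m


class TestRelief:
    def test_constant_feature_has_zero_weight_and_ranks_last(self):
        F, y = toy_feature_table(n=30, n_informative=2, seed=3)
        F["hours_thi_ge72"] = 5.0  # constant
        ranking = relief_rank(F, y)
        assert ranking.weights["hours_thi_ge72"] == 0.0
        # ranked below every feature with positive weight
        positives = [n for n, w in ranking.weights.items() if w > 0]
        idx = {n: i for i, n in enumerate(ranking.ordered_names)}
        assert all(idx[n] < idx["hours_thi_ge72"] for n in positives)

    def test_separating_feature_ranked_first(self):
        wins = 0
        for seed in range(100):
            F, y = toy_feature_table(n=40, n_informative=1, shift=4.0, seed=seed)
            ranking = relief_rank(F, y)
            wins += ranking.ordered_names[0] == FEATURE_NAMES[0]
        assert wins >= 90

    def test_matches_naive_trace_on_small_tables(self):
        for seed in range(10):
            F, y = toy_feature_table(n=12, n_informative=2, shift=1.0, seed=seed)
            ranking = relief_rank(F, y)
            expected = naive_relief(F.to_numpy(), y)
            got = np.array([ranking.weights[n] for n in F.columns])
            assert np.allclose(got, expected, atol=1e-12)

    def test_incomplete_rows_are_excluded(self):
        F, y = toy_feature_table(n=30, seed=1)
        F2 = F.copy()
        F2.iloc[:5, 0] = np.nan  # corrupt five rows
        complete = F.iloc[5:].reset_index(drop=True)
        r_masked = relief_rank(F2, y)
        r_subset = relief_rank(complete, y[5:])
        assert r_masked.ordered_names == r_subset.ordered_names

    def test_permutation_null_weights_centred_at_zero(self):
        rng = np.random.default_rng(0)
        means = []
        for seed in range(30):
            F, y = toy_feature_table(n=40, n_informative=3, shift=2.0, seed=seed)
            yp = rng.permutation(y)
            r = relief_rank(F, yp)
            means.append(np.mean(list(r.weights.values())))
        assert abs(np.mean(means)) < 0.02

    def test_single_class_raises(self):
        F, y = toy_feature_table(n=20)
        with pytest.raises(ValueError):
            relief_rank(F, np.zeros_like(y))


class TestFitGNB:
    def test_two_value_class_moments(self):
        F = pd.DataFrame({"nefa_max": [0.0, 2.0, 5.0, 7.0]})
        y = np.array([SICK, SICK, HEALTHY, HEALTHY])
        model = fit_gnb(F, y, ["nefa_max"])
        assert model.means[SICK, 0] == 1.0
        assert model.variances[SICK, 0] == 2.0  # sample variance of {0, 2}

    def test_missing_entries_excluded_from_moments(self):
        F = pd.DataFrame({"a": [1.0, 3.0, np.nan, 10.0, 20.0], "b": [0.0, 1.0, 2.0, 3.0, 4.0]})
        y = np.array([SICK, SICK, SICK, HEALTHY, HEALTHY])
        reduced = pd.DataFrame({"a": [1.0, 3.0, 10.0, 20.0], "b": [0.0, 1.0, 3.0, 4.0]})
        yr = np.array([SICK, SICK, HEALTHY, HEALTHY])
        m1 = fit_gnb(F, y, ["a"])
        m2 = fit_gnb(reduced, yr, ["a"])
        assert np.array_equal(m1.means, m2.means)
        assert np.array_equal(m1.variances, m2.variances)

    def test_moments_match_direct_computation(self, rng):
        F, y = toy_feature_table(n=50, seed=9)
        sel = list(FEATURE_NAMES[:4])
        model = fit_gnb(F, y, sel)
        for c in (HEALTHY, SICK):
            sub = F.loc[y == c, sel].to_numpy()
            assert np.allclose(model.means[c], sub.mean(axis=0))
            assert np.allclose(model.variances[c], sub.var(axis=0, ddof=1))

    def test_priors_empirical_and_uniform(self):
        F, y = toy_feature_table(n=40)
        m = fit_gnb(F, y, ["bcs_8w"])
        assert m.priors[SICK] == pytest.approx(np.mean(y == SICK))
        mu = fit_gnb(F, y, ["bcs_8w"], uniform_priors=True)
        assert np.array_equal(mu.priors, [0.5, 0.5])

    def test_insufficient_observations_raise(self):
        F = pd.DataFrame({"a": [1.0, np.nan, 2.0, 3.0]})
        y = np.array([SICK, SICK, HEALTHY, HEALTHY])
        with pytest.raises(ValueError):
            fit_gnb(F, y, ["a"])

    def test_recovers_planted_parameters(self):
        rng = np.random.default_rng(123)
        n = 2000
        y = np.array([SICK] * (n // 2) + [HEALTHY] * (n // 2))
        F = pd.DataFrame(
            {
                "a": np.where(y == SICK, rng.normal(3.0, 2.0, n), rng.normal(-1.0, 1.5, n)),
                "b": rng.normal(10.0, 4.0, n),
            }
        )
        model = fit_gnb(F, y, ["a", "b"])
        assert model.means[SICK, 0] == pytest.approx(3.0, rel=0.05)
        assert model.means[HEALTHY, 0] == pytest.approx(-1.0, rel=0.05)
        assert math.sqrt(model.variances[SICK, 0]) == pytest.approx(2.0, rel=0.05)
        assert math.sqrt(model.variances[HEALTHY, 1]) == pytest.approx(4.0, rel=0.05)


class TestPredictGNB:
    def _toy_model(self):
        F = pd.DataFrame(
            {"a": [0.0, 1.0, -1.0, 5.0, 6.0, 4.0], "b": [2.0, 3.0, 1.0, 9.0, 8.0, 10.0]}
        )
        y = np.array([HEALTHY] * 3 + [SICK] * 3)
        return fit_gnb(F, y, ["a", "b"], uniform_priors=True), F, y

    def test_point_at_healthy_means_is_healthy(self):
        model, _, _ = self._toy_model()
        x = pd.Series({"a": model.means[HEALTHY, 0], "b": model.means[HEALTHY, 1]})
        label, post = predict_gnb(model, x)
        assert label == HEALTHY
        assert post < 0.5

    def test_posterior_matches_hand_computed_bayes_rule(self):
        model, _, _ = self._toy_model()
        x = {"a": 2.0, "b": 5.0}
        like_s = like_h = 1.0
        for f, name in enumerate(["a", "b"]):
            like_s *= norm.pdf(x[name], model.means[SICK, f], math.sqrt(model.variances[SICK, f]))
            like_h *= norm.pdf(x[name], model.means[HEALTHY, f], math.sqrt(model.variances[HEALTHY, f]))
        expected = 0.5 * like_s / (0.5 * like_s + 0.5 * like_h)
        _, post = predict_gnb(model, x)
        assert post == pytest.approx(expected, rel=1e-10)

    def test_omission_consistency(self):
        """Masking a feature equals deleting its likelihood term entirely."""
        model, F, y = self._toy_model()
        model_a_only = fit_gnb(F, y, ["a"], uniform_priors=True)
        x_masked = pd.Series({"a": 2.5, "b": np.nan})
        _, post_masked = predict_gnb(model, x_masked)
        _, post_reduced = predict_gnb(model_a_only, pd.Series({"a": 2.5}))
        assert post_masked == pytest.approx(post_reduced, rel=1e-12)

    def test_all_missing_returns_undecided_signal(self):
        model, _, _ = self._toy_model()
        label, post = predict_gnb(model, pd.Series({"a": np.nan, "b": np.nan}))
        assert label is None and post is None


def test_gnb_labels_agree_with_reference_implementation():
    """On complete data the decisions match an independent GNB (sklearn)."""
    from sklearn.naive_bayes import GaussianNB

    F, y = toy_feature_table(n=80, n_informative=3, shift=1.5, seed=8)
    sel = list(FEATURE_NAMES[:6])
    model = fit_gnb(F, y, sel)
    ref = GaussianNB(var_smoothing=1e-12).fit(F[sel], y)
    post = predict_gnb_table(model, F)
    ours = post >= 0.5
    theirs = ref.predict(F[sel]) == SICK
    # variance conventions differ slightly (ddof); decisions should not
    assert np.mean(ours == theirs) >= 0.975


class TestSelectFeatureCount:
    def test_identical_copies_return_one(self):
        rng = np.random.default_rng(2)
        y = np.array([SICK] * 20 + [HEALTHY] * 20)
        base = rng.normal(0, 1, 40) + 2.0 * (y == SICK)
        F = pd.DataFrame({name: base for name in FEATURE_NAMES[:5]})
        ranking = relief_rank(F, y)
        assert select_feature_count(F, y, ranking, seed=0) == 1

    def test_informative_plus_noise_selects_few(self):
        small = 0
        for seed in range(10):
            F, y = toy_feature_table(n=60, n_informative=1, shift=4.0, seed=seed)
            ranking = relief_rank(F, y)
            k = select_feature_count(F, y, ranking, seed=seed)
            small += k <= 3
        assert small >= 7

    def test_matches_brute_force_prefix_evaluation(self):
        from ketodetect.validation import stratified_kfold

        F, y = toy_feature_table(n=40, n_informative=2, shift=2.0, seed=5)
        F = F[list(FEATURE_NAMES[:6])]
        ranking = relief_rank(F, y)
        got = select_feature_count(F, y, ranking, seed=7)
        # independent naive evaluation with explicit Gaussian densities
        folds = stratified_kfold(y, k=10, seed=7)
        best_k, best_ba = None, -1.0
        for k in range(1, 7):
            sel = list(ranking.ordered_names[:k])
            bas = []
            for f in range(10):
                tr, te = folds != f, folds == f
                post = []
                stats = {}
                for c in (HEALTHY, SICK):
                    sub = F.loc[tr & (y == c), sel].to_numpy()
                    stats[c] = (sub.mean(0), sub.var(0, ddof=1))
                vmax = max(stats[c][1].max() for c in stats)
                for c in stats:
                    stats[c] = (stats[c][0], np.maximum(stats[c][1], 1e-9 * vmax))
                prior_s = np.mean(y[tr] == SICK)
                for _, row in F.loc[te, sel].iterrows():
                    ls = np.log(prior_s) + norm.logpdf(
                        row.to_numpy(), stats[SICK][0], np.sqrt(stats[SICK][1])
                    ).sum()
                    lh = np.log(1 - prior_s) + norm.logpdf(
                        row.to_numpy(), stats[HEALTHY][0], np.sqrt(stats[HEALTHY][1])
                    ).sum()
                    post.append(1 / (1 + np.exp(lh - ls)))
                pred = np.asarray(post) >= 0.5
                ytest = y[te] == SICK
                bas.append(0.5 * (pred[ytest].mean() + (~pred[~ytest]).mean()))
            ba = float(np.mean(bas))
            if ba > best_ba:
                best_k, best_ba = k, ba
        assert got == best_k


class TestTuneThreshold:
    def _model_and_data(self, seed=0):
        F, y = toy_feature_table(n=40, n_informative=2, shift=2.0, seed=seed)
        model = fit_gnb(F, y, list(FEATURE_NAMES[:3]))
        return model, F, y

    def test_target_one_allows_every_sick_example(self):
        model, F, y = self._model_and_data()
        thr = tune_threshold(model, F, y, 1.0)
        post = predict_gnb_table(model, F.loc[y == SICK])
        assert thr == pytest.approx(post.min())
        assert np.mean(post >= thr) == 1.0

    def test_target_half_is_order_statistic_boundary(self):
        model, F, y = self._model_and_data()
        post = np.sort(predict_gnb_table(model, F.loc[y == SICK]))[::-1]
        m = math.ceil(0.5 * (y == SICK).sum())
        assert tune_threshold(model, F, y, 0.5) == pytest.approx(post[m - 1])

    def test_target_zero_returns_maximal_threshold(self):
        model, F, y = self._model_and_data()
        assert tune_threshold(model, F, y, 0.0) == 1.0

    def test_achieved_sensitivity_meets_target(self):
        model, F, y = self._model_and_data(seed=4)
        for target in (0.3, 0.6, 0.9):
            thr = tune_threshold(model, F, y, target)
            post = predict_gnb_table(model, F.loc[y == SICK])
            assert np.mean(post >= thr) >= target
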