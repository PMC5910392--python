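import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as trapezoid_auc

from miratio.signature_selection import (
    SignatureModel,
    _standardize,
    auc,
    auc_prefilter,
    bootstrap_lasso,
    brier,
    cv_lambda,
    final_model_and_roc,
    lambda_max,
    logistic_lasso_fit,
    variable_importance,
)


def brute_force_auc(scores, labels):
    """Exhaustive pair counting with half-credit ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([1, 2, 9, 10], [0, 0, 1, 1]) == 1.0

    def test_all_tied_scores(self):
        assert auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_one_swap_example(self):
        assert auc([1, 2, 3, 4], [0, 1, 0, 1]) == pytest.approx(0.75)
        assert brute_force_auc([1, 2, 3, 4], [0, 1, 0, 1]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 2], [1, 1])

    def test_matches_pair_counting_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = rng.integers(6, 25)
            scores = rng.integers(0, 6, size=n).astype(float)  # many ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_trapezoid_identity(self):
        from sklearn.metrics import roc_curve

        rng = np.random.default_rng(1)
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.4).astype(int)
        fpr, tpr, _ = roc_curve(labels, scores)
        assert auc(scores, labels) == pytest.approx(trapezoid_auc(fpr, tpr), abs=1e-10)


class TestAucPrefilter:
    def test_uninformative_feature_dropped_and_separating_kept(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        X = pd.DataFrame(
            {"flat": [1.0] * 6, "sep": [0, 0, 0, 1, 1, 1], "anti": [1, 1, 1, 0, 0, 0]}
        )
        keep, scores = auc_prefilter(X, y, min_auc=0.7)
        assert keep == ["sep", "anti"]  # orientation makes 'anti' an AUC-1 feature
        assert scores["flat"] == pytest.approx(0.5)

    def test_orientation_guarantees_half(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(30, 5)))
        X.columns = [f"f{j}" for j in range(5)]
        y = rng.integers(0, 2, size=30)
        keep, scores = auc_prefilter(X, y, min_auc=0.5)
        assert (scores >= 0.5).all()
        assert keep == [f for f in X.columns if scores[f] > 0.5]


class TestBrier:
    def test_perfect_and_constant(self):
        assert brier([1.0, 0.0], [1, 0]) == 0.0
        assert brier([0.5, 0.5, 0.5], [1, 0, 1]) == pytest.approx(0.25)

    def test_arithmetic(self):
        assert brier([0.8, 0.4], [1, 0]) == pytest.approx(0.10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            brier([1.2], [1])


class TestLassoFit:
    @staticmethod
    def _data(seed=0, n=80, p=8, strength=2.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        logits = strength * X[:, 0] - 0.3
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
        return X, y

    def test_full_shrinkage_at_lambda_max(self):
        X, y = self._data()
        Xs, _, _, _ = _standardize(X)
        lmax = lambda_max(Xs, y)
        model = logistic_lasso_fit(X, y, lmax * (1 + 1e-9))
        assert np.all(model.coef == 0.0)
        ybar = y.mean()
        assert model.intercept == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-9)

    def test_matches_independent_solver(self):
        X, y = self._data(seed=3)
        lam = 0.03
        model = logistic_lasso_fit(X, y, lam, tol=1e-10, max_iter=50000)
        Xs, _, _, _ = _standardize(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = LogisticRegression(
                penalty="l1", C=1 / (len(y) * lam), solver="saga",
                tol=1e-10, max_iter=500000, random_state=0,
            ).fit(Xs, y)
        assert np.max(np.abs(model.coef - ref.coef_[0])) < 1e-6
        assert model.intercept == pytest.approx(ref.intercept_[0], abs=1e-6)

    def test_duplicated_feature_predictions_match_single_fit(self):
        X, y = self._data(seed=4, p=3)
        lam = 0.05
        single = logistic_lasso_fit(X, y, lam, tol=1e-10, max_iter=50000)
        X_dup = np.column_stack([X, X[:, 0]])
        dup = logistic_lasso_fit(X_dup, y, lam, tol=1e-10, max_iter=50000)
        p1 = single.predict_proba(X)
        p2 = dup.predict_proba(X_dup)
        assert np.max(np.abs(p1 - p2)) < 1e-4

    def test_moderate_lambda_selects_informative_only(self):
        rng = np.random.default_rng(5)
        n = 200
        x_inf = rng.normal(size=n)
        x_noise = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-3 * x_inf))).astype(int)
        X = pd.DataFrame({"inf": x_inf, "noise": x_noise})
        model = logistic_lasso_fit(X, y, 0.08)
        assert model.nonzero_features() == ["inf"]

    def test_constant_feature_dropped_with_warning(self):
        X, y = self._data(seed=6, p=3)
        X[:, 2] = 7.7
        with pytest.warns(UserWarning, match="constant"):
            model = logistic_lasso_fit(X, y, 0.05)
        assert model.coef[2] == 0.0
        assert model.dropped == ["x2"]

    def test_single_class_rejected(self):
        X, _ = self._data()
        with pytest.raises(ValueError):
            logistic_lasso_fit(X, np.ones(len(X)), 0.1)

    def test_json_round_trip(self, tmp_path):
        X, y = self._data(seed=7)
        model = logistic_lasso_fit(X, y, 0.05)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = SignatureModel.from_json(path)
        assert back.features == model.features
        assert np.allclose(back.coef, model.coef)
        assert np.allclose(back.predict_proba(X), model.predict_proba(X))


class TestCvLambda:
    def test_pure_noise_keeps_heavy_penalty(self):
        """Without signal the Brier optimum sits at or near the all-zero
        boundary for most random draws."""
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 20))
            y = np.repeat([0, 1], 30)
            cv = cv_lambda(X, y, seed=seed, n_lambda=50)
            hits += cv.index_min < 10
        assert hits >= 3

    def test_informative_feature_beats_null_model(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=100)
        y = (rng.random(100) < 1 / (1 + np.exp(-4 * x))).astype(int)
        X = np.column_stack([x, rng.normal(size=100)])
        cv = cv_lambda(X, y, seed=1)
        null_brier = y.mean() * (1 - y.mean())
        assert cv.cv_brier.min() < null_brier

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 6))
        y = np.repeat([0, 1], 20)
        a = cv_lambda(X, y, seed=4)
        b = cv_lambda(X, y, seed=4)
        assert a.lambda_min == b.lambda_min
        assert np.array_equal(a.cv_brier, b.cv_brier)

    def test_too_few_per_class_rejected(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(8, 3))
        y = np.array([0, 0, 0, 0, 0, 0, 1, 1])
        with pytest.raises(ValueError, match="stratified"):
            cv_lambda(X, y, n_folds=5)


class TestBootstrap:
    @staticmethod
    def _null_data(seed=0, n=60, p=20):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"r{j}" for j in range(p)])
        y = np.repeat([0, 1], n // 2)
        return X, y

    def test_null_data_auc_near_chance(self):
        X, y = self._null_data()
        summary = bootstrap_lasso(X, y, n_iter=60, n_lambda=40, seed=3)
        assert 0.35 < summary.mean_auc < 0.65

    def test_same_seed_identical_summary(self):
        X, y = self._null_data(seed=1, n=30, p=5)
        a = bootstrap_lasso(X, y, n_iter=8, n_lambda=25, seed=7)
        b = bootstrap_lasso(X, y, n_iter=8, n_lambda=25, seed=7)
        assert np.array_equal(a.auc_values, b.auc_values)
        assert np.array_equal(a.coef_matrix, b.coef_matrix)

    def test_summary_invariants(self):
        X, y = self._null_data(seed=2, n=40, p=8)
        s = bootstrap_lasso(X, y, n_iter=12, n_lambda=25, seed=5)
        freq = s.selection_freq
        assert ((freq >= 0) & (freq <= 1)).all()
        assert np.all((s.auc_values >= 0) & (s.auc_values <= 1))
        lo, hi = s.auc_ci
        assert lo <= s.mean_auc <= hi

    def test_resample_first_variant_runs(self):
        X, y = self._null_data(seed=3, n=40, p=5)
        s = bootstrap_lasso(X, y, n_iter=5, n_lambda=25, seed=2, resample_first=True)
        assert len(s.auc_values) == 5


class TestVariableImportance:
    @staticmethod
    def _summary(coefs):
        from miratio.signature_selection import BootstrapSummary

        coefs = np.asarray(coefs, dtype=float)
        return BootstrapSummary(
            features=[f"f{j}" for j in range(coefs.shape[1])],
            auc_values=np.full(coefs.shape[0], 0.9),
            coef_matrix=coefs,
            lambda_values=np.full(coefs.shape[0], 0.1),
            seed=0,
            n_iter=coefs.shape[0],
        )

    def test_always_selected_ranks_first(self):
        s = self._summary([[1.0, 0.0], [0.5, 0.0], [1.5, 0.0]])
        vi = variable_importance(s)
        assert list(vi.index) == ["f0", "f1"]

    def test_tie_broken_by_mean_abs_coef(self):
        s = self._summary([[0.1, 2.0], [0.1, 2.0]])
        vi = variable_importance(s)
        assert list(vi.index) == ["f1", "f0"]

    def test_top_k_zero_and_overflow(self):
        s = self._summary([[1.0, 0.5]])
        assert len(variable_importance(s, top_k=0)) == 0
        with pytest.warns(UserWarning, match="truncating"):
            vi = variable_importance(s, top_k=10)
        assert len(vi) == 2


class TestFinalModel:
    def test_separable_single_feature_gives_auc_one(self):
        X = pd.DataFrame({"f": np.concatenate([np.zeros(10), np.ones(10) * 5])})
        y = np.repeat([0, 1], 10)
        model, roc, a = final_model_and_roc(X, y, seed=0)
        assert a == 1.0
        assert {"fpr", "tpr", "threshold"} <= set(roc.columns)

    def test_null_data_auc_at_least_half(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(40, 4)))
        X.columns = [f"f{j}" for j in range(4)]
        y = np.repeat([0, 1], 20)
        _, _, a = final_model_and_roc(X, y, seed=1)
        assert a >= 0.5
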