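"""Penalized logistic regression, lambda selection, CV and transfer."""

import numpy as np
import pytest

from erdswitch.classifier import (
    LAMBDA_MULTIPLIERS,
    _penalized_loss_grad,
    _stratified_folds,
    crossval_accuracy,
    fit_rllr,
    select_lambda,
    total_variance,
    transfer_accuracy,
)
from erdswitch.features_spectral import FeatureMatrix
import pandas as pd

from erdswitch.session_model import Condition


def _feature_matrix(X, names):
    meta = pd.DataFrame(
        {"channel": [f"c{i}" for i in range(X.shape[1])],
         "frequency_hz": 8.0, "window": "ERD"}
    )
    labels = [Condition(n, 2) for n in names]
    return FeatureMatrix(values=X, meta=meta, labels=labels)


class TestFitRllr:
    def test_separable_clusters_reach_perfect_training_accuracy(self, separable_features):
        X, y = separable_features
        model = fit_rllr(X, y, lam=1e-3)
        assert model.accuracy(X, y) == 1.0

    def test_huge_lambda_shrinks_weights_to_zero(self, separable_features):
        X, y = separable_features
        model = fit_rllr(X, y, lam=1e9 * total_variance(X))
        assert np.linalg.norm(model.weights) < 1e-3

    def test_gradient_vanishes_at_optimum(self, separable_features):
        # central-difference numerical gradient as the oracle
        X, y = separable_features
        lam = 2.0
        model = fit_rllr(X, y, lam=lam)
        Z = (X - model.feature_mean) / model.feature_scale
        ys = np.where(y == model.classes[1], 1.0, -1.0)
        p0 = np.r_[model.weights, model.bias]
        for i in range(len(p0)):
            e = np.zeros_like(p0)
            e[i] = 1e-6
            num = (
                _penalized_loss_grad(p0 + e, Z, ys, lam)[0]
                - _penalized_loss_grad(p0 - e, Z, ys, lam)[0]
            ) / 2e-6
            assert abs(num) < 1e-5

    def test_agrees_with_sklearn_on_standardized_features(self, separable_features):
        # independent implementation of the same penalized objective
        sklearn_linear = pytest.importorskip("sklearn.linear_model")
        X, y = separable_features
        lam = 3.7
        model = fit_rllr(X, y, lam=lam)
        Z = (X - model.feature_mean) / model.feature_scale
        ys = np.where(y == model.classes[1], 1.0, -1.0)
        sk = sklearn_linear.LogisticRegression(
            C=1.0 / (2.0 * lam), tol=1e-10, max_iter=10000
        ).fit(Z, ys)
        assert np.allclose(model.weights, sk.coef_[0], atol=1e-6)
        assert model.bias == pytest.approx(sk.intercept_[0], abs=1e-6)

    def test_monotone_shrinkage(self, separable_features):
        X, y = separable_features
        norms = [
            np.linalg.norm(fit_rllr(X, y, lam=l).weights)
            for l in (0.01, 0.1, 1.0, 10.0, 100.0)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_single_class_and_nonfinite_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError):
            fit_rllr(X, np.array(["a"] * 10), lam=1.0)
        Xbad = X.copy()
        Xbad[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_rllr(Xbad, np.array(["a"] * 5 + ["b"] * 5), lam=1.0)

    def test_json_round_trip(self, separable_features, tmp_path):
        from erdswitch.classifier import RllrModel

        X, y = separable_features
        model = fit_rllr(X, y, lam=1.0)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = RllrModel.from_json(path)
        assert np.allclose(back.weights, model.weights)
        assert np.array_equal(back.predict(X), model.predict(X))


class TestSelectLambda:
    def test_grid_has_six_candidates_scaled_by_total_variance(self):
        assert LAMBDA_MULTIPLIERS == (0.001, 0.01, 0.1, 1.0, 10.0, 100.0)

    def test_zero_variance_features_return_largest_candidate(self):
        X = np.ones((40, 3))
        y = np.array(["a", "b"] * 20)
        assert select_lambda(X, y, seed=0) == 0.0  # all candidates are 0

    def test_matches_exhaustive_grid_oracle(self, rng):
        # overlapping clusters so candidates genuinely differ
        X = np.vstack([rng.normal(-0.5, 1, (30, 8)), rng.normal(0.5, 1, (30, 8))])
        y = np.array(["none"] * 30 + ["attempted"] * 30)
        chosen = select_lambda(X, y, seed=4, k=5)
        tv = total_variance(X)
        folds = _stratified_folds(y, 5, 4)
        scores = []
        for mult in LAMBDA_MULTIPLIERS:
            lam = mult * tv
            correct = sum(
                int(np.sum(fit_rllr(X[tr], y[tr], lam=lam).predict(X[te]) == y[te]))
                for tr, te in folds
            )
            scores.append((correct, lam))
        best = max(scores)[1]  # ties resolved toward the larger lambda
        assert chosen == best


class TestCrossval:
    def test_separable_data_scores_perfectly(self, separable_features):
        X, y = separable_features
        cv = crossval_accuracy(X, y, k=10, seed=1, selection="flat")
        assert cv.overall_accuracy == 1.0
        assert len(cv.fold_accuracies) == 10

    def test_fold_sizes_and_stratification_for_162_trials(self, rng):
        X = rng.standard_normal((162, 4))
        y = np.array(["none"] * 81 + ["actual"] * 81)
        cv = crossval_accuracy(X, y, k=10, seed=0, selection="flat")
        sizes = np.bincount(cv.fold_assignment)
        assert set(sizes.tolist()) <= {16, 17}
        for f in range(10):
            fold_labels = y[cv.fold_assignment == f]
            n_pos = np.sum(fold_labels == "actual")
            assert abs(int(n_pos) - (len(fold_labels) - int(n_pos))) <= 1

    def test_every_trial_held_out_exactly_once(self, separable_features):
        X, y = separable_features
        cv = crossval_accuracy(X, y, k=10, seed=3, selection="flat")
        assert (cv.fold_assignment >= 0).all()
        assert cv.n_trials == len(y)
        # overall accuracy is the pooled fraction over held-out trials
        assert cv.overall_accuracy == pytest.approx(
            np.mean(cv.predictions == y)
        )

    def test_feature_column_permutation_leaves_accuracy_unchanged(self, rng):
        X = np.vstack([rng.normal(-0.6, 1, (30, 6)), rng.normal(0.6, 1, (30, 6))])
        y = np.array(["none"] * 30 + ["attempted"] * 30)
        perm = rng.permutation(6)
        a = crossval_accuracy(X, y, k=5, seed=2, selection="flat")
        b = crossval_accuracy(X[:, perm], y, k=5, seed=2, selection="flat")
        assert a.overall_accuracy == b.overall_accuracy

    def test_too_few_trials_per_class_suggests_smaller_k(self, rng):
        X = rng.standard_normal((10, 2))
        y = np.array(["a"] * 5 + ["b"] * 5)
        with pytest.raises(ValueError, match="smaller k"):
            crossval_accuracy(X, y, k=10)

    def test_null_features_score_near_chance(self, rng):
        # labels independent of features; small Monte-Carlo around 50%
        accs = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.standard_normal((80, 10))
            y = np.array(["none", "attempted"] * 40)
            accs.append(
                crossval_accuracy(X, y, k=5, seed=seed, selection="flat").overall_accuracy
            )
        assert 0.35 < np.mean(accs) < 0.65


class TestTransfer:
    def test_self_transfer_equals_training_accuracy(self, separable_features):
        X, y = separable_features
        acc, model = transfer_accuracy(
            X, y, test_features=X, test_labels=y, return_model=True
        )
        assert acc == model.accuracy(X, y)

    def test_metadata_mismatch_rejected(self, rng):
        X = np.vstack([rng.normal(-2, 0.5, (15, 3)), rng.normal(2, 0.5, (15, 3))])
        y = ["none"] * 15 + ["attempted"] * 15
        fa = _feature_matrix(X, y)
        fb = _feature_matrix(X, y)
        fb.meta.loc[0, "channel"] = "other"
        with pytest.raises(ValueError, match="metadata"):
            transfer_accuracy(fa, test_features=fb)

    def test_cross_condition_labels_mapped_by_role(self, rng):
        # train actual-vs-none, test attempted-vs-none with the same geometry
        Xtr = np.vstack([rng.normal(-2, 0.5, (30, 4)), rng.normal(2, 0.5, (30, 4))])
        ytr = np.array(["none"] * 30 + ["actual"] * 30)
        Xte = np.vstack([rng.normal(-2, 0.5, (20, 4)), rng.normal(2, 0.5, (20, 4))])
        yte = np.array(["none"] * 20 + ["attempted"] * 20)
        acc = transfer_accuracy(Xtr, ytr, test_features=Xte, test_labels=yte)
        assert acc == 1.0

    def test_null_training_gives_chance_on_separable_test(self):
        # weights learned from pure noise point in a random direction, so a
        # separable test set scores near 0 or 1 per seed; only the average
        # over many seeds is at chance (binomial sd 0.5/sqrt(60) ~ 0.065)
        accs = []
        for seed in range(60):
            r = np.random.default_rng(seed)
            Xtr = r.standard_normal((60, 5))
            ytr = np.array(["none", "attempted"] * 30)
            Xte = np.vstack([r.normal(-3, 0.3, (25, 5)), r.normal(3, 0.3, (25, 5))])
            yte = np.array(["none"] * 25 + ["attempted"] * 25)
            accs.append(transfer_accuracy(Xtr, ytr, test_features=Xte, test_labels=yte,
                                          seed=seed))
        assert np.mean(accs) == pytest.approx(0.5, abs=0.2)
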