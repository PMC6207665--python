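"""Classifier families: determinism, oracles, score contracts."""

import math

import numpy as np
import pytest

from fibrostage.models import (
    ANN_ARCHITECTURES,
    AnnNet,
    ClassifierSpec,
    _one_hot,
    feature_importance,
    predict_scores,
    standardize,
    train,
    train_ann,
    train_mlr,
    train_rf,
    train_svm,
)


@pytest.fixture(scope="module")
def five_clusters():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(3 * k, 0.3, size=(12, 4)) for k in range(5)])
    y = np.repeat(np.arange(5), 12)
    return X, y


class TestStandardize:
    def test_train_columns_centered_and_scaled(self):
        rng = np.random.default_rng(1)
        X = rng.normal(5, 3, (50, 4))
        Z, _, _ = standardize(X)
        assert np.allclose(Z.mean(0), 0, atol=1e-12)
        assert np.allclose(Z.std(0), 1, atol=1e-12)

    def test_constant_feature_guard(self):
        X = np.column_stack([np.full(10, 7.0), np.arange(10.0)])
        Z, _, (mean, scale) = standardize(X)
        assert scale[0] == 1.0
        assert np.allclose(Z[:, 0], 0.0)

    def test_stats_reproduce_training_transform(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        Z, Zc, (mean, scale) = standardize(X, X.copy())
        assert np.allclose(Z, Zc)


class TestANN:
    def test_stock_architectures(self):
        assert set(ANN_ARCHITECTURES.values()) == {(10,), (20,), (20, 20)}

    def test_separable_training_accuracy_is_perfect(self, five_clusters):
        X, y = five_clusters
        m = train_ann(X, y, ClassifierSpec(family="ann", epochs=500, seed=0))
        s = predict_scores(m, X)
        assert (s.argmax_labels(m.classes) == y).mean() == 1.0

    def test_seed_determinism(self, five_clusters):
        X, y = five_clusters
        spec = ClassifierSpec(family="ann", epochs=50, seed=3)
        m1, m2 = train_ann(X, y, spec), train_ann(X, y, spec)
        for W1, W2 in zip(m1.estimator.W, m2.estimator.W):
            assert np.array_equal(W1, W2)

    @pytest.mark.parametrize("layers", [(10,), (20,), (20, 20)])
    def test_gradient_matches_finite_differences(self, layers):
        rng = np.random.default_rng(4)
        net = AnnNet((3, *layers, 4), seed=5)
        X = rng.normal(size=(3, 3))
        Y = _one_hot(np.array([0, 2, 3]), np.arange(4))
        _, gW, gb = net.loss_and_grads(X, Y)
        eps = 1e-6
        for li in range(len(net.W)):
            for idx in [(0, 0), (net.W[li].shape[0] - 1,
                                 net.W[li].shape[1] - 1)]:
                net.W[li][idx] += eps
                lp, _, _ = net.loss_and_grads(X, Y)
                net.W[li][idx] -= 2 * eps
                lm, _, _ = net.loss_and_grads(X, Y)
                net.W[li][idx] += eps
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - gW[li][idx]) < 1e-5

    def test_non_finite_state_raises_with_epoch_and_rate(self):
        rng = np.random.default_rng(0)
        net = AnnNet((3, 5, 2), seed=0)
        net.W[0][0, 0] = np.inf  # corrupted state must be caught, not run
        X = rng.normal(size=(4, 3))
        Y = _one_hot(np.array([0, 1, 0, 1]), np.arange(2))
        with pytest.raises(RuntimeError, match="learning rate"):
            net.fit(X, Y, learning_rate=0.05, epochs=3)


class TestMLR:
    def test_two_by_two_slope_closed_form(self):
        a, b, c, d = 30, 10, 12, 40
        x = np.array([1.0] * (a + b) + [0.0] * (c + d))[:, None]
        y = np.array([1] * a + [0] * b + [1] * c + [0] * d)
        m = train_mlr(x, y, ClassifierSpec(family="mlr"))
        slope = m.estimator.coef_[0, 0] / m.scale[0]  # back to raw scale
        assert slope == pytest.approx(math.log(a * d / (b * c)), abs=1e-6)

    def test_complete_separation_flags_nonconvergence(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-2, 0.1, (10, 1)),
                       rng.normal(2, 0.1, (10, 1))])
        y = np.repeat([0, 1], 10)
        with pytest.warns(UserWarning, match="did not converge"):
            m = train_mlr(X, y, ClassifierSpec(family="mlr"))
        assert not m.converged

    def test_rank_deficient_design_flags_nonconvergence(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 40))  # p > n
        y = rng.integers(0, 2, 20)
        with pytest.warns(UserWarning):
            m = train_mlr(X, y, ClassifierSpec(family="mlr"))
        assert not m.converged

    def test_ridge_coefficients_shrink_monotonically(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 3))
        y = (X[:, 0] + 0.5 * rng.normal(size=60) > 0).astype(int)
        norms = []
        for lam in (0.01, 1.0, 100.0):
            m = train_mlr(X, y, ClassifierSpec(family="mlr",
                                               ridge_lambda=lam))
            norms.append(np.linalg.norm(m.estimator.coef_))
        assert norms[0] > norms[1] > norms[2]

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec(family="mlr", ridge_lambda=-1.0)


class TestSVM:
    def test_rbf_kernel_is_one_at_zero_distance(self):
        sigma = 2.0
        gamma = 1.0 / (2 * sigma**2)
        assert math.exp(-gamma * 0.0) == 1.0

    def test_two_point_problem_boundary_at_midpoint(self):
        X = np.array([[0.0], [4.0]])
        y = np.array([0, 1])
        m = train_svm(X, y, ClassifierSpec(family="svm", sigma=1.0, C=10.0))
        s = predict_scores(m, X)
        assert (s.argmax_labels(m.classes) == y).all()
        # decision value at the midpoint is 0 by symmetry
        mid = predict_scores(m, np.array([[2.0]])).scores[0]
        assert mid[0] == pytest.approx(mid[1], abs=1e-6)

    def test_kkt_residuals_small(self, five_clusters):
        X, y = five_clusters
        C = 1.0
        m = train_svm(X, y, ClassifierSpec(family="svm", C=C))
        Z = m.transform(X)
        for ci, svc in enumerate(m.estimator.estimators_):
            ybin = np.where(y == m.classes[ci], 1.0, -1.0)
            dec = svc.decision_function(Z)
            alpha = np.zeros(len(Z))
            alpha[svc.support_] = np.abs(svc.dual_coef_[0])
            margin = ybin * dec
            resid = 0.0
            for i in range(len(Z)):
                if alpha[i] < 1e-8:
                    resid = max(resid, max(0.0, 1.0 - margin[i]))
                elif alpha[i] > C - 1e-8:
                    resid = max(resid, max(0.0, margin[i] - 1.0))
                else:
                    resid = max(resid, abs(margin[i] - 1.0))
            assert resid <= 1e-3

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec(family="svm", sigma=0.0)


class TestRF:
    def test_default_hundred_trees(self, five_clusters):
        X, y = five_clusters
        spec = ClassifierSpec(family="rf")
        assert spec.n_trees == 100
        m = train_rf(X, y, spec)
        assert len(m.estimator.estimators_) == 100

    def test_entropy_values(self):
        from scipy.stats import entropy
        assert entropy([1.0, 0.0], base=2) == 0.0
        assert entropy([0.5, 0.5], base=2) == 1.0

    def test_single_tree_split_matches_exhaustive_information_gain(self):
        # 6-sample, 2-feature table; no bootstrap, no feature subsampling
        X = np.array([[1.0, 5.0], [2.0, 1.0], [3.0, 4.0],
                      [7.0, 2.0], [8.0, 6.0], [9.0, 3.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        from sklearn.tree import DecisionTreeClassifier
        tree = DecisionTreeClassifier(criterion="entropy", random_state=0)
        tree.fit(X, y)

        def entropy_bits(labels):
            _, counts = np.unique(labels, return_counts=True)
            p = counts / counts.sum()
            return -np.sum(p * np.log2(p))

        best = None
        for f in range(2):
            cuts = np.unique(X[:, f])
            for lo, hi in zip(cuts, cuts[1:]):
                thr = (lo + hi) / 2
                left = y[X[:, f] <= thr]
                right = y[X[:, f] > thr]
                gain = entropy_bits(y) - (
                    len(left) / len(y) * entropy_bits(left)
                    + len(right) / len(y) * entropy_bits(right))
                if best is None or gain > best[0] + 1e-12:
                    best = (gain, f, thr)
        assert tree.tree_.feature[0] == best[1]
        assert tree.tree_.threshold[0] == pytest.approx(best[2])

    def test_vote_fraction_rows_sum_to_one(self, five_clusters):
        X, y = five_clusters
        m = train_rf(X, y, ClassifierSpec(family="rf", n_trees=20, seed=1))
        s = predict_scores(m, X)
        assert np.allclose(s.scores.sum(1), 1.0, atol=1e-9)

    def test_seed_determinism(self, five_clusters):
        X, y = five_clusters
        spec = ClassifierSpec(family="rf", n_trees=30, seed=7)
        s1 = predict_scores(train_rf(X, y, spec), X).scores
        s2 = predict_scores(train_rf(X, y, spec), X).scores
        assert np.array_equal(s1, s2)


class TestFeatureImportance:
    def test_perfect_predictor_ranked_first(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 5))
        y = (X[:, 3] > 0).astype(int)
        m = train_rf(X, y, ClassifierSpec(family="rf", n_trees=50, seed=0))
        order, imp = feature_importance(m, X, y, seed=0)
        assert order[0] == 3

    def test_ranking_is_deterministic(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 4))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        m = train_rf(X, y, ClassifierSpec(family="rf", n_trees=30, seed=2))
        o1, _ = feature_importance(m, X, y, seed=5)
        o2, _ = feature_importance(m, X, y, seed=5)
        assert np.array_equal(o1, o2)

    def test_non_rf_model_rejected(self, five_clusters):
        X, y = five_clusters
        m = train_ann(X, y, ClassifierSpec(family="ann", epochs=10))
        with pytest.raises(ValueError, match="RF"):
            feature_importance(m, X, y)


class TestPredictScores:
    @pytest.mark.parametrize("family", ["ann", "mlr", "svm", "rf"])
    def test_probabilistic_rows_sum_to_one(self, family, five_clusters):
        X, y = five_clusters
        spec = ClassifierSpec(family=family, epochs=50, n_trees=20, seed=0)
        s = predict_scores(train(X, y, spec), X)
        assert s.scores.shape == (len(y), 5)
        assert np.allclose(s.scores.sum(1), 1.0, atol=1e-9)
        assert np.all(s.scores >= 0)

    def test_dimension_mismatch_names_expected_width(self, five_clusters):
        X, y = five_clusters
        m = train(X, y, ClassifierSpec(family="rf", n_trees=5))
        with pytest.raises(ValueError, match="4"):
            predict_scores(m, np.zeros((2, 7)))

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            ClassifierSpec(family="boost")
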