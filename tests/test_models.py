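import numpy as np
import pytest
from scipy import stats as sps

from delcall.models import (CARTModel, CARTNode, FitError, MRMModel,
                            bootstrap_training_curve, fit_cart, fit_mrm,
                            predict_cart, predict_mrm, roc_curves)


def three_blobs(rng, n=60, sep=1.0, p=4):
    y = np.repeat([0, 1, 2], n)
    centers = np.array([2.0, 1.0, 0.0]) * sep
    X = centers[y][:, None] + rng.normal(0, 0.1, (3 * n, p))
    return X, y


class TestMRM:
    def test_zero_coefficients_uniform_probabilities(self):
        model = MRMModel(feature_names=["f0", "f1"], coef_hom=np.zeros(3),
                         coef_norm=np.zeros(3), ridge=0.0, iterations=0,
                         final_loglik=0.0, converged=True)
        P, _ = predict_mrm(model, np.random.default_rng(0).normal(size=(10, 2)))
        np.testing.assert_allclose(P, 1.0 / 3.0, atol=1e-12)

    def test_separable_blobs_high_accuracy(self, rng):
        X, y = three_blobs(rng)
        model = fit_mrm(X, y)
        _, calls = predict_mrm(model, X)
        assert np.mean(calls == y) >= 0.99

    def test_null_labels_recover_class_frequencies(self, rng):
        X = rng.normal(size=(900, 3))
        y = rng.choice([0, 1, 2], size=900, p=[0.5, 0.3, 0.2])
        model = fit_mrm(X, y)
        P, _ = predict_mrm(model, X)
        freqs = np.bincount(y, minlength=3) / 900
        np.testing.assert_allclose(P.mean(axis=0), freqs, atol=0.05)

    def test_missing_class_unfittable(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.array([0, 1] * 15)
        with pytest.raises(FitError, match="three genotype classes"):
            fit_mrm(X, y)

    def test_probabilities_sum_to_one(self, rng):
        X, y = three_blobs(rng, n=30)
        model = fit_mrm(X, y)
        P, _ = predict_mrm(model, rng.normal(size=(50, 4)))
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_exact_tie_calls_lowest_code(self):
        model = MRMModel(feature_names=["f0"], coef_hom=np.zeros(2),
                         coef_norm=np.zeros(2), ridge=0.0, iterations=0,
                         final_loglik=0.0, converged=True)
        _, calls = predict_mrm(model, np.zeros((3, 1)))
        assert (calls == 0).all()  # all-1/3 tie resolves to WT

    def test_padding_oracle(self, rng):
        X, y = three_blobs(rng, n=30, p=3)
        model = fit_mrm(X, y)
        padded = MRMModel(feature_names=model.feature_names + ["pad"],
                          coef_hom=np.append(model.coef_hom, 0.0),
                          coef_norm=np.append(model.coef_norm, 0.0),
                          ridge=model.ridge, iterations=model.iterations,
                          final_loglik=model.final_loglik, converged=True)
        Xt = rng.normal(size=(40, 3))
        P1, c1 = predict_mrm(model, Xt)
        P2, c2 = predict_mrm(padded, np.column_stack([Xt, rng.normal(size=40)]))
        np.testing.assert_allclose(P1, P2, atol=1e-12)
        np.testing.assert_array_equal(c1, c2)

    def test_probe_mismatch_error(self, rng):
        X, y = three_blobs(rng, n=20, p=3)
        model = fit_mrm(X, y)
        with pytest.raises(FitError, match="feature"):
            predict_mrm(model, rng.normal(size=(5, 2)))

    def test_affine_rescaling_invariance_without_ridge(self, rng):
        X, y = three_blobs(rng, n=60, sep=0.4)  # overlapping classes
        m1 = fit_mrm(X, y, ridge=0.0)
        scale = np.array([2.0, 0.5, 4.0, 1.0])
        shift = np.array([1.0, -2.0, 0.3, 5.0])
        m2 = fit_mrm(X * scale + shift, y, ridge=0.0)
        _, c1 = predict_mrm(m1, X)
        _, c2 = predict_mrm(m2, X * scale + shift)
        assert np.mean(c1 == c2) >= 0.98

    def test_matches_sklearn_reference(self, rng):
        sklearn = pytest.importorskip("sklearn.linear_model")
        X, y = three_blobs(rng, n=50, sep=0.5)
        model = fit_mrm(X, y, ridge=1.0)
        _, calls = predict_mrm(model, X)
        ref = sklearn.LogisticRegression(C=1.0, max_iter=2000).fit(X, y)
        assert np.mean(calls == ref.predict(X)) >= 0.95

    def test_model_round_trips_through_dict(self, rng):
        X, y = three_blobs(rng, n=20)
        model = fit_mrm(X, y)
        back = MRMModel.from_dict(model.to_dict())
        P1, _ = predict_mrm(model, X)
        P2, _ = predict_mrm(back, X)
        np.testing.assert_allclose(P1, P2, atol=1e-12)


def brute_force_cart(X, y, min_node_size=5):
    """Independent exhaustive-split reference (plain loops, no shortcuts)."""
    def gini(labels):
        n = len(labels)
        if n == 0:
            return 0.0
        return 1.0 - sum((np.sum(labels == c) / n) ** 2 for c in (0, 1, 2))

    def grow(idx):
        labels = y[idx]
        node = {"n": len(idx), "counts": [int(np.sum(labels == c)) for c in (0, 1, 2)]}
        if len(idx) < min_node_size or gini(labels) == 0.0:
            return node
        best = None
        for f in range(X.shape[1]):
            vals = sorted(set(X[idx, f]))
            for lo, hi in zip(vals, vals[1:]):
                t = (lo + hi) / 2.0
                left = idx[X[idx, f] <= t]
                right = idx[X[idx, f] > t]
                score = (len(left) * gini(y[left]) + len(right) * gini(y[right])) / len(idx)
                if best is None or score < best[0] - 1e-15:
                    best = (score, f, t, left, right)
        if best is None or best[0] >= gini(labels) - 1e-12:
            return node
        node.update(feature=best[1], threshold=best[2],
                    left=grow(best[3]), right=grow(best[4]))
        return node

    return grow(np.arange(len(y)))


def predict_brute(node, row):
    while "feature" in node:
        node = node["left"] if row[node["feature"]] <= node["threshold"] else node["right"]
    return int(np.argmax(node["counts"]))


class TestCART:
    def test_separable_single_feature(self):
        X = np.array([[0.1], [0.2], [0.15], [0.5], [0.55], [0.6], [0.9], [0.95], [1.0]])
        y = np.array([2, 2, 2, 1, 1, 1, 0, 0, 0])
        model = fit_cart(X, y)
        assert np.array_equal(predict_cart(model, X), y)

    def test_small_node_becomes_leaf(self):
        # 4 samples < 5: never split, even though impure
        root = fit_cart(np.arange(12, dtype=float).reshape(-1, 1),
                        np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 1, 2])).root
        def check(node):
            if node.n < 5:
                assert node.is_leaf
            if not node.is_leaf:
                check(node.left)
                check(node.right)
        check(root)

    def test_brute_force_oracle_12_samples(self, rng):
        X = rng.normal(size=(12, 2)).round(2)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2])
        X[:4, 0] += 3
        X[8:, 1] += 3
        model = fit_cart(X, y)
        oracle = brute_force_cart(X, y)
        assert model.root.feature == oracle.get("feature")
        assert model.root.threshold == pytest.approx(oracle.get("threshold"))
        grid = rng.normal(size=(200, 2)) * 2
        ours = predict_cart(model, grid)
        theirs = [predict_brute(oracle, row) for row in grid]
        np.testing.assert_array_equal(ours, theirs)

    def test_piecewise_constant_under_subthreshold_perturbation(self, rng):
        X, y = three_blobs(rng, n=20, p=2)
        model = fit_cart(X, y)
        thresholds = []
        def collect(node):
            if not node.is_leaf:
                thresholds.append((node.feature, node.threshold))
                collect(node.left)
                collect(node.right)
        collect(model.root)
        x = X[5].copy()
        base = predict_cart(model, x[None, :])[0]
        for f in range(2):
            ts = sorted(t for ff, t in thresholds if ff == f)
            gaps = [t - x[f] for t in ts if t > x[f]]
            eps = (min(gaps) / 2 if gaps else 1.0)
            x2 = x.copy()
            x2[f] += eps * 0.5
            assert predict_cart(model, x2[None, :])[0] == base

    def test_feature_order_permutation_consistent(self, rng):
        X, y = three_blobs(rng, n=20, p=3)
        model = fit_cart(X, y)
        perm = [2, 0, 1]
        model_p = fit_cart(X[:, perm], y)
        np.testing.assert_array_equal(predict_cart(model, X),
                                      predict_cart(model_p, X[:, perm]))

    def test_leaf_tie_breaks_to_lowest_code(self):
        node = CARTNode(n=4, class_counts=np.array([2, 2, 0]))
        assert node.majority() == 0


class TestBootstrapCurve:
    def test_smoke_deterministic(self, rng):
        X, y = three_blobs(rng, n=60, sep=0.6)
        c1 = bootstrap_training_curve(X, y, "mrm", sizes=(50, 100), reps=2, seed=4)
        c2 = bootstrap_training_curve(X, y, "mrm", sizes=(50, 100), reps=2, seed=4)
        np.testing.assert_array_equal(c1.mean_accuracy, c2.mean_accuracy)
        assert c1.sizes == [50, 100]

    def test_accuracy_nondecreasing_in_n(self):
        rng = np.random.default_rng(8)
        X, y = three_blobs(rng, n=250, sep=0.35)
        curve = bootstrap_training_curve(X, y, "mrm", sizes=(30, 60, 120, 240, 480),
                                         reps=8, seed=1)
        rho = sps.spearmanr(curve.sizes, curve.mean_accuracy).statistic
        assert rho > 0

    def test_oversized_training_rejected(self, rng):
        X, y = three_blobs(rng, n=30)
        with pytest.raises(ValueError):
            bootstrap_training_curve(X, y, "mrm", sizes=(80,), reps=1)


class TestROC:
    def test_perfect_separation_auc_one(self):
        y = np.array([0, 0, 1, 1, 2, 2])
        P = np.eye(3)[y] * 0.8 + 0.1
        curves = roc_curves(P, y)
        for c in (0, 1, 2):
            assert curves[c].auc == pytest.approx(1.0)

    def test_shuffled_labels_auc_half(self):
        rng = np.random.default_rng(3)
        n = 2000
        P = rng.dirichlet([1, 1, 1], size=n)
        y = rng.integers(0, 3, size=n)
        curves = roc_curves(P, y)
        for c in (0, 1, 2):
            assert curves[c].auc == pytest.approx(0.5, abs=0.05)

    def test_monotone_transform_invariance(self, rng):
        y = rng.integers(0, 3, size=200)
        P = rng.random((200, 3))
        a1 = roc_curves(P, y)
        a2 = roc_curves(np.exp(3 * P), y)  # rank-preserving transform
        for c in (0, 1, 2):
            assert a1[c].auc == pytest.approx(a2[c].auc, abs=1e-12)

    def test_single_class_truth_error(self):
        with pytest.raises(ValueError):
            roc_curves(np.full((5, 3), 1 / 3), np.zeros(5, dtype=int))

    def test_matches_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        y = rng.integers(0, 3, size=300)
        P = rng.random((300, 3))
        curves = roc_curves(P, y)
        for c in (0, 1, 2):
            ref = sk.roc_auc_score((y == c).astype(int), P[:, c])
            assert curves[c].auc == pytest.approx(ref, abs=1e-10)


class TestParameterRecovery:
    def test_high_separation_sensitivity(self):
        # class-conditional Gaussians, n=100 training, separation >= 3 pooled sd
        rng = np.random.default_rng(5)
        X, y = three_blobs(rng, n=200, sep=0.3)  # centers 0.3 apart, sd 0.1
        idx = rng.choice(len(y), 100, replace=False)
        while len(np.unique(y[idx])) < 3:
            idx = rng.choice(len(y), 100, replace=False)
        hold = np.setdiff1d(np.arange(len(y)), idx)
        for fit, predict in ((fit_mrm, lambda m, X: predict_mrm(m, X)[1]),
                             (fit_cart, predict_cart)):
            model = fit(X[idx], y[idx])
            calls = predict(model, X[hold])
            truth = y[hold]
            sens_hom = np.mean(calls[truth == 2] == 2)
            assert sens_hom >= 0.95
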