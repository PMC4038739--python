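import numpy as np
import pytest

from chromsig.classifier import (
    SVMConfig,
    fit_binary,
    kernel,
    kkt_violations,
    model_from_json,
    model_to_json,
    polynomial_kernel,
    predict,
    predict_multiclass,
    train_decision_tree,
    train_multiclass,
    train_svm_smo,
)
from chromsig.errors import ContractError, DegenerateDataError

XOR_X = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
XOR_Y = np.array([1.0, 1.0, -1.0, -1.0])


class TestKernel:
    @pytest.mark.parametrize(
        "x, y, p, expected",
        [
            ([1, 1], [1, 1], 1, 2.0),
            ([1, 2], [3, 4], 2, 121.0),  # (3 + 8)^2
            ([1, 0], [0, 1], 1, 0.0),
            ([1, 0], [0, 1], 3, 0.0),
        ],
    )
    def test_homogeneous_values(self, x, y, p, expected):
        assert kernel(x, y, p) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            kernel([1, 2], [1, 2, 3], 1)

    def test_gram_matches_scalar(self, rng):
        X = rng.normal(size=(5, 3))
        K = polynomial_kernel(X, X, 2)
        for i in range(5):
            for j in range(5):
                assert K[i, j] == pytest.approx(kernel(X[i], X[j], 2))


class TestSMO:
    def test_two_point_closed_form_dual(self):
        # x1=0 (+1), x2=2 (-1): boundary at x=1, alpha = 2/||x1-x2||^2 = 0.5
        X = np.array([[0.0], [2.0]])
        y = np.array([1.0, -1.0])
        m = train_svm_smo(X, y, SVMConfig(C=1e6, standardize=False))
        assert np.allclose(m.train_alpha, 0.5, atol=1e-6)
        assert m.decision_function([[1.0]])[0] == pytest.approx(0.0, abs=1e-6)
        assert m.decision_function([[0.0]])[0] == pytest.approx(1.0, abs=1e-6)

    def test_midpoint_decision_value_zero(self):
        X = np.array([[1.0, 2.0], [3.0, 6.0]])
        y = np.array([1.0, -1.0])
        m = train_svm_smo(X, y, SVMConfig(C=1e6, standardize=False))
        mid = 0.5 * (X[0] + X[1])
        assert m.decision_function([mid])[0] == pytest.approx(0.0, abs=1e-6)

    def test_xor_solved_by_quadratic_but_not_linear_kernel(self):
        m2 = train_svm_smo(XOR_X, XOR_Y, SVMConfig(degree=2, C=1e3, standardize=False))
        assert np.all(np.sign(m2.decision_function(XOR_X)) == XOR_Y)
        m1 = train_svm_smo(XOR_X, XOR_Y, SVMConfig(degree=1, C=1e3, standardize=False))
        acc = np.mean(np.sign(m1.decision_function(XOR_X)) == XOR_Y)
        assert acc < 1.0

    def test_training_order_invariance(self, rng):
        X = rng.normal(size=(12, 4))
        y = np.where(X[:, 0] + 0.5 * X[:, 1] > 0, 1.0, -1.0)
        if len(set(y)) < 2:
            pytest.skip("degenerate draw")
        tight = SVMConfig(C=10.0, kkt_tol=1e-8, max_passes=2000)
        m = train_svm_smo(X, y, tight)
        perm = rng.permutation(12)
        mp = train_svm_smo(X[perm], y[perm], tight)
        probe = rng.normal(size=(6, 4))
        assert np.allclose(
            m.decision_function(probe), mp.decision_function(probe), atol=1e-6
        )

    def test_kkt_feasibility_on_random_fixtures(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n, d = int(rng.integers(6, 30)), int(rng.integers(2, 8))
            X = rng.normal(size=(n, d))
            y = np.where(X @ rng.normal(size=d) > 0, 1.0, -1.0)
            if len(set(y.tolist())) < 2:
                continue
            cfg = SVMConfig(C=float(rng.choice([0.5, 1.0, 10.0])))
            m = train_svm_smo(X, y, cfg)
            assert 0 <= m.train_alpha.min() and m.train_alpha.max() <= cfg.C + 1e-12
            assert abs(np.dot(m.train_alpha, y)) < cfg.kkt_tol
            assert kkt_violations(m, X, y) < 2 * cfg.kkt_tol

    def test_free_support_vector_sits_on_margin(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 3))
        y = np.where(X[:, 0] > 0, 1.0, -1.0)
        cfg = SVMConfig(C=5.0, standardize=False)
        m = train_svm_smo(X, y, cfg)
        f = m.decision_function(X)
        free = (m.train_alpha > 1e-8) & (m.train_alpha < cfg.C - 1e-8)
        assert free.any()
        assert np.all(np.abs(np.abs(f[free]) - 1.0) < 2 * cfg.kkt_tol)

    def test_separable_training_data_classified_perfectly(self, rng):
        X = np.vstack([rng.normal(-3, 0.5, (10, 2)), rng.normal(3, 0.5, (10, 2))])
        y = np.array([1.0] * 10 + [-1.0] * 10)
        m = train_svm_smo(X, y, SVMConfig(C=100.0))
        assert np.all(np.sign(m.decision_function(X)) == y)

    def test_sign_agreement_with_reference_solver(self):
        SVC = pytest.importorskip("sklearn.svm").SVC
        rng = np.random.default_rng(0)
        checked = 0
        for _ in range(25):
            n, d = int(rng.integers(6, 40)), int(rng.integers(2, 10))
            X = rng.normal(size=(n, d))
            y = np.where(X @ rng.normal(size=d) + 0.3 > 0, 1.0, -1.0)
            if len(set(y.tolist())) < 2:
                continue
            m = train_svm_smo(X, y, SVMConfig(C=100.0, standardize=False))
            sk = SVC(kernel="linear", C=100.0).fit(X, y)
            assert np.all(
                np.sign(m.decision_function(X)) == np.sign(sk.decision_function(X))
            )
            checked += 1
            if checked == 20:
                break
        assert checked == 20

    def test_single_class_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            train_svm_smo(np.ones((4, 2)), np.ones(4), SVMConfig())

    def test_margin_violations_never_grow_with_c(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 2))
        y = np.where(X[:, 0] + rng.normal(0, 1.2, 30) > 0, 1.0, -1.0)  # noisy labels
        counts = []
        for C in (0.1, 1.0, 10.0, 100.0):
            m = train_svm_smo(X, y, SVMConfig(C=C, standardize=False))
            f = m.decision_function(X)
            counts.append(int(np.sum(y * f < 1 - 1e-6)))
        assert all(a >= b - 1 for a, b in zip(counts, counts[1:]))


class TestPredictAndLabels:
    def test_string_labels_map_to_signs(self):
        X = np.array([[0.0], [2.0], [0.1], [1.9]])
        m = fit_binary(X, ["fusion", "wt", "fusion", "wt"], SVMConfig(C=100.0))
        lab, val = predict(m, [0.0])
        assert lab == "fusion" and val > 0
        lab, val = predict(m, [2.0])
        assert lab == "wt" and val < 0


class TestMulticlass:
    def test_two_classes_reduce_to_single_svm(self, rng):
        X = np.vstack([rng.normal(-2, 0.4, (8, 3)), rng.normal(2, 0.4, (8, 3))])
        labels = ["a"] * 8 + ["b"] * 8
        mm = train_multiclass(X, labels, SVMConfig(C=10.0))
        assert len(mm.pairwise_models) == 1
        single = fit_binary(X, labels, SVMConfig(C=10.0))
        for x in X:
            assert predict_multiclass(mm, x) == predict(single, x)[0]

    def test_three_blobs_perfect_training_accuracy(self, rng):
        centers = np.array([[0, 6], [-5, -3], [5, -3]], dtype=float)
        X = np.vstack([rng.normal(c, 0.5, (7, 2)) for c in centers])
        labels = sum([[f"c{k}"] * 7 for k in range(3)], [])
        mm = train_multiclass(X, labels, SVMConfig(C=10.0))
        assert len(mm.pairwise_models) == 3
        preds = [predict_multiclass(mm, x) for x in X]
        assert preds == labels


class TestDecisionTree:
    def test_one_dimensional_separable_is_depth_one(self):
        X = np.array([[1.0], [2.0], [8.0], [9.0]])
        tree = train_decision_tree(X, ["a", "a", "b", "b"])
        assert not tree.root.is_leaf
        assert tree.root.left.is_leaf and tree.root.right.is_leaf
        assert [tree.predict_one(x) for x in X] == ["a", "a", "b", "b"]

    def test_constant_features_give_majority_leaf(self):
        X = np.ones((5, 3))
        tree = train_decision_tree(X, ["a", "a", "a", "b", "b"])
        assert tree.root.is_leaf
        assert tree.root.label == "a"

    def test_xor_needs_depth_two(self):
        tree = train_decision_tree(XOR_X, ["p", "p", "n", "n"])
        preds = [tree.predict_one(x) for x in XOR_X]
        assert preds == ["p", "p", "n", "n"]
        depth_two = not tree.root.is_leaf and not (
            tree.root.left.is_leaf and tree.root.right.is_leaf
        )
        assert depth_two


class TestSerialization:
    def test_model_json_round_trip(self, tmp_path, rng):
        X = rng.normal(size=(10, 4))
        y = np.where(X[:, 0] > 0, 1.0, -1.0)
        if len(set(y.tolist())) < 2:
            pytest.skip("degenerate draw")
        m = train_svm_smo(X, y, SVMConfig(degree=2, C=3.0))
        path = tmp_path / "model.json"
        model_to_json(m, path)
        back = model_from_json(path)
        probe = rng.normal(size=(5, 4))
        assert np.allclose(m.decision_function(probe), back.decision_function(probe))
        assert back.class_labels == m.class_labels
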