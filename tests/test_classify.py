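import numpy as np
import pytest

from qpmcell.classify import (
    DEFAULT_C_GRID,
    TrainedClassifier,
    cross_validated_decisions,
    decision_value,
    decision_values,
    evaluate,
    grid_search_C,
    learning_curve,
    phantom_decision_curve,
    train_svm,
)
from qpmcell.features import FeatureVector


def mann_whitney_auc(decisions, labels):
    """Pairwise-comparison oracle: P(random positive > random negative),
    ties counted one half."""
    d = np.asarray(decisions, float)
    y = np.asarray(labels)
    pos = d[y == 1]
    neg = d[y == -1]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _gaussian_data(rng, n=60, sep=4.0, dim=3):
    Xp = rng.normal(+sep / 2, 1.0, (n, dim))
    Xn = rng.normal(-sep / 2, 1.0, (n, dim))
    X = np.vstack([Xp, Xn])
    y = np.array([1] * n + [-1] * n)
    return X, y


class TestTrainSvm:
    def test_separable_1d_classified_correctly(self):
        X = np.array([[-3.0], [-2.0], [-1.0], [1.0], [2.0], [3.0]])
        y = [-1, -1, -1, 1, 1, 1]
        clf = train_svm(X, y, C=1e3)
        d = decision_values(clf, X)
        assert np.all(np.sign(d) == y)

    def test_duplicated_dataset_same_solution(self, rng):
        X, y = _gaussian_data(rng, n=25)
        clf1 = train_svm(X, y, C=100.0)
        clf2 = train_svm(np.vstack([X, X]), np.concatenate([y, y]), C=100.0)
        np.testing.assert_allclose(clf1.w, clf2.w, rtol=1e-3, atol=1e-6)
        assert clf1.b == pytest.approx(clf2.b, rel=1e-3, abs=1e-6)

    def test_two_point_max_margin_solution(self):
        X = np.array([[1.0], [-1.0]])
        clf = train_svm(X, [1, -1], C=1e3)
        assert clf.w[0] == pytest.approx(1.0, rel=1e-6)
        assert clf.b == pytest.approx(0.0, abs=1e-6)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            train_svm(np.ones((4, 2)), [1, 1, 1, 1])


class TestDecisionValue:
    def test_arithmetic(self):
        clf = TrainedClassifier(w=np.array([3.0, 4.0]), b=0.0, C=1.0)
        assert decision_value(clf, np.array([1.0, 1.0])) == pytest.approx(1.4)

    def test_point_on_hyperplane(self):
        clf = TrainedClassifier(w=np.array([1.0, 2.0]), b=-3.0, C=1.0)
        assert decision_value(clf, np.array([1.0, 1.0])) == pytest.approx(0.0)

    def test_signed_euclidean_distance(self):
        clf = TrainedClassifier(w=np.array([1.0, 0.0]), b=-2.0, C=1.0)
        assert decision_value(clf, np.array([5.0, 9.0])) == pytest.approx(3.0)

    def test_rescaling_w_b_leaves_decisions_unchanged(self, rng):
        w = rng.normal(size=6)
        clf1 = TrainedClassifier(w=w, b=0.7, C=1.0)
        clf2 = TrainedClassifier(w=5.0 * w, b=3.5, C=1.0)
        x = rng.normal(size=6)
        assert decision_value(clf1, x) == pytest.approx(decision_value(clf2, x))

    def test_dimension_mismatch_raises(self):
        clf = TrainedClassifier(w=np.ones(3), b=0.0, C=1.0)
        with pytest.raises(ValueError):
            decision_value(clf, np.ones(5))

    def test_accepts_feature_vector(self):
        clf = TrainedClassifier(w=np.array([2.0]), b=0.0, C=1.0)
        fv = FeatureVector(np.array([3.0]), kind="hog")
        assert decision_value(clf, fv) == pytest.approx(3.0)


class TestCrossValidatedDecisions:
    def test_separable_classes_reach_auc_one(self, rng):
        X, y = _gaussian_data(rng, n=30, sep=10.0)
        d = cross_validated_decisions(X, y, C=1.0, seed=0)
        assert evaluate(d, y).auc == 1.0

    def test_permuted_labels_give_null_auc(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(500, 5))
        y = np.array([1] * 250 + [-1] * 250)
        d = cross_validated_decisions(X, rng.permutation(y), C=1.0, seed=0)
        auc = evaluate(d, rng.permutation(y)).auc
        assert 0.35 < auc < 0.65

    def test_deterministic_given_seed(self, rng):
        X, y = _gaussian_data(rng, n=20, sep=2.0)
        d1 = cross_validated_decisions(X, y, C=1.0, seed=3)
        d2 = cross_validated_decisions(X, y, C=1.0, seed=3)
        np.testing.assert_array_equal(d1, d2)

    def test_class_smaller_than_k_raises(self):
        X = np.ones((6, 2))
        y = [1, 1, 1, 1, -1, -1]
        with pytest.raises(ValueError):
            cross_validated_decisions(X, y, k=5)


class TestGridSearch:
    def test_default_grid_is_ten_powers_of_two(self):
        assert len(DEFAULT_C_GRID) == 10
        assert DEFAULT_C_GRID[0] == 0.5
        assert DEFAULT_C_GRID[-1] == 256.0

    def test_separable_data_ties_resolve_to_smallest_C(self, rng):
        X, y = _gaussian_data(rng, n=20, sep=10.0)
        cv = grid_search_C(X, y, seed=0)
        assert cv.best_C == 0.5
        assert all(a == 1.0 for _, a in cv.grid)

    def test_best_C_attains_grid_maximum(self, rng):
        X, y = _gaussian_data(rng, n=25, sep=1.0)
        cv = grid_search_C(X, y, seed=1)
        best = max(a for _, a in cv.grid)
        assert dict(cv.grid)[cv.best_C] == best

    def test_empty_grid_raises(self, rng):
        X, y = _gaussian_data(rng, n=10)
        with pytest.raises(ValueError):
            grid_search_C(X, y, grid=[])


class TestEvaluate:
    def test_perfect_separation(self):
        ev = evaluate([1.0, 2.0, -1.0, -2.0], [1, 1, -1, -1])
        assert ev.auc == 1.0
        assert ev.sensitivity == ev.specificity == ev.accuracy == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_auc_equals_mann_whitney_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        # quantized decisions force ties, exercising the half-count rule
        d = np.round(rng.normal(size=2 * n), 1)
        y = np.array([1] * n + [-1] * n)
        d[y == 1] += rng.uniform(0, 1)
        ev = evaluate(d, y)
        assert ev.auc == pytest.approx(mann_whitney_auc(d, y), abs=1e-12)

    def test_all_equal_decisions_give_half(self):
        ev = evaluate([0.3] * 8, [1, 1, 1, 1, -1, -1, -1, -1])
        assert ev.auc == pytest.approx(0.5)

    def test_det_is_complement_of_roc(self, rng):
        d = rng.normal(size=30)
        y = np.array([1] * 15 + [-1] * 15)
        ev = evaluate(d, y)
        np.testing.assert_allclose(ev.det_points[:, 0], ev.roc_points[:, 0])
        np.testing.assert_allclose(ev.det_points[:, 1],
                                   1.0 - ev.roc_points[:, 1])

    def test_roc_endpoints(self, rng):
        d = rng.normal(size=20)
        y = np.array([1] * 10 + [-1] * 10)
        ev = evaluate(d, y)
        np.testing.assert_allclose(ev.roc_points[0], [0.0, 0.0])
        np.testing.assert_allclose(ev.roc_points[-1], [1.0, 1.0])

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            evaluate([1.0, 2.0], [1, 1])


class TestLearningCurve:
    def test_full_size_equals_plain_cv_auc(self, rng):
        X, y = _gaussian_data(rng, n=30, sep=2.0)
        curve = learning_curve(X, y, sizes=[30], C=16.0, seed=0)
        d = cross_validated_decisions(X, y, C=16.0, seed=0)
        # full-size subsample is a permutation of the whole set
        assert curve[0][1] == pytest.approx(evaluate(d, y).auc, abs=0.02)

    def test_median_trend_non_decreasing(self):
        """On easy data the learning curve rises to a plateau; the
        median over seeds smooths sampling noise."""
        rng = np.random.default_rng(0)
        X, y = _gaussian_data(rng, n=60, sep=1.2)
        sizes = [8, 25, 60]
        curves = np.array([
            [a for _, a in learning_curve(X, y, sizes, C=16.0, seed=s)]
            for s in range(10)
        ])
        med = np.median(curves, axis=0)
        assert med[0] <= med[-1] + 1e-9

    def test_deterministic_given_seed(self, rng):
        X, y = _gaussian_data(rng, n=25, sep=2.0)
        c1 = learning_curve(X, y, [10, 25], C=16.0, seed=4)
        c2 = learning_curve(X, y, [10, 25], C=16.0, seed=4)
        assert c1 == c2

    def test_oversized_request_raises(self, rng):
        X, y = _gaussian_data(rng, n=10)
        with pytest.raises(ValueError):
            learning_curve(X, y, [11], seed=0)


@pytest.fixture(scope="module")
def hog_classifier(small_population):
    from qpmcell.pipeline import extract_features
    X, y, _ = extract_features(small_population, "OPL_PL", "hog")
    return train_svm(X, y, C=16.0, feature_kind="hog",
                     normalization_mode="OPL_PL")


class TestPhantomDecisionCurve:
    def test_smooth_phantom_is_positive(self, hog_classifier, smooth_phantom):
        (_, d), = phantom_decision_curve(hog_classifier, [smooth_phantom],
                                         heights=[0.0])
        assert d > 0

    def test_deterministic(self, hog_classifier, bumpy_phantom):
        d1 = phantom_decision_curve(hog_classifier, [bumpy_phantom])
        d2 = phantom_decision_curve(hog_classifier, [bumpy_phantom])
        assert d1 == d2

    def test_mode_mismatch_raises(self, hog_classifier, smooth_phantom):
        with pytest.raises(ValueError):
            phantom_decision_curve(hog_classifier, [smooth_phantom],
                                   mode="OPL_D")
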