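import numpy as np
import pytest
from scipy import stats

from pandaml import plsda


def random_instance(rng, n=20, p=10):
    X = rng.standard_normal((n, p))
    y = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    return X, rng.permutation(y)


def brute_force_mahalanobis(model, X_new):
    """Independent loop-based re-implementation of the classifier."""
    T = plsda.project(model, X_new)
    inv = np.linalg.inv(model.class_cov)
    dists = np.zeros((T.shape[0], len(model.class_levels)))
    for i in range(T.shape[0]):
        for k, c in enumerate(model.class_levels):
            d = T[i] - model.class_centroids[c]
            dists[i, k] = np.sqrt(float(d @ inv @ d))
    labels = [model.class_levels[int(np.argmin(dists[i]))]
              for i in range(T.shape[0])]
    return labels, dists


class TestNipalsFit:
    def test_matches_reference_nipals_up_to_sign(self):
        from sklearn.cross_decomposition import PLSRegression
        rng = np.random.default_rng(42)
        for _ in range(15):
            X, y = random_instance(rng)
            model = plsda.fit_pls(X, y, n_components=3)
            Y, _ = plsda.dummy_code(y)
            ref = PLSRegression(n_components=3, scale=False).fit(X, Y)
            for ours, theirs in ((model.x_weights, ref.x_weights_),
                                 (model.x_loadings, ref.x_loadings_),
                                 (model.scores, ref.x_scores_)):
                for k in range(3):
                    diff = min(np.abs(ours[:, k] - theirs[:, k]).max(),
                               np.abs(ours[:, k] + theirs[:, k]).max())
                    assert diff < 1e-8

    def test_first_weight_recovers_informative_direction(self):
        rng = np.random.default_rng(1)
        n, p = 40, 10
        direction = np.zeros(p)
        direction[3] = 1.0
        y = np.array(["a"] * 20 + ["b"] * 20)
        X = rng.standard_normal((n, p)) * 0.3
        X[:, 3] += np.where(y == "b", 3.0, 0.0)
        model = plsda.fit_pls(X, y, n_components=1)
        cosine = abs(model.x_weights[:, 0] @ direction)
        assert cosine > 0.95

    def test_score_orthogonality(self):
        rng = np.random.default_rng(2)
        X, y = random_instance(rng, n=30, p=12)
        model = plsda.fit_pls(X, y, n_components=5)
        G = model.scores.T @ model.scores
        off = np.abs(G - np.diag(np.diag(G))).max()
        assert off < 1e-8 * np.trace(G)

    def test_single_class_and_oversized_components_error(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((10, 4))
        with pytest.raises(ValueError):
            plsda.fit_pls(X, ["a"] * 10, n_components=2)
        with pytest.raises(ValueError, match="exceeds"):
            plsda.fit_pls(X, ["a"] * 5 + ["b"] * 5, n_components=5)


class TestProjection:
    def test_training_scores_reproduced(self):
        rng = np.random.default_rng(4)
        X, y = random_instance(rng)
        model = plsda.fit_pls(X, y, n_components=3)
        assert np.abs(plsda.project(model, X) - model.scores).max() < 1e-10

    def test_mean_vector_projects_to_origin(self):
        rng = np.random.default_rng(5)
        X, y = random_instance(rng)
        model = plsda.fit_pls(X, y, n_components=2)
        scores = plsda.project(model, X.mean(axis=0))
        assert np.abs(scores).max() < 1e-12

    def test_row_independence(self):
        rng = np.random.default_rng(6)
        X, y = random_instance(rng)
        model = plsda.fit_pls(X, y, n_components=2)
        X_new = rng.standard_normal((5, X.shape[1]))
        batch = plsda.project(model, X_new)
        single = plsda.project(model, X_new[2])
        np.testing.assert_allclose(single[0], batch[2], atol=1e-14)

    def test_feature_mismatch_errors(self):
        rng = np.random.default_rng(7)
        X, y = random_instance(rng)
        model = plsda.fit_pls(X, y, n_components=2)
        with pytest.raises(ValueError, match="feature count"):
            plsda.project(model, np.zeros((2, 3)))


class TestModelQualityMetrics:
    def test_r2y_reaches_one_in_exact_fit_limit(self):
        rng = np.random.default_rng(8)
        n = 30
        y = np.array(["a"] * 15 + ["b"] * 15)
        # Y is an exact linear function of one X column
        X = rng.standard_normal((n, 5)) * 0.01
        X[:, 0] = (y == "b").astype(float)
        model = plsda.fit_pls(X, y, n_components=5)
        assert plsda.r2y(model, X, y) > 1 - 1e-9

    def test_r2y_non_decreasing_in_components(self):
        rng = np.random.default_rng(9)
        X, y = random_instance(rng, n=30, p=12)
        vals = [plsda.r2y(plsda.fit_pls(X, y, n_components=k), X, y)
                for k in range(1, 9)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_q2_separated_beats_noise(self):
        rng = np.random.default_rng(10)
        n, p = 60, 20
        y = np.array(["a"] * 30 + ["b"] * 30)
        X_sep = rng.standard_normal((n, p))
        X_sep[:, :5] += np.where(y == "b", 3.0, 0.0)[:, None]
        assert plsda.q2(X_sep, y, n_components=3, seed=0) > 0.5
        X_null = rng.standard_normal((n, p))
        assert plsda.q2(X_null, y, n_components=3, seed=0) < 0.3

    def test_q2_deterministic_given_seed(self):
        rng = np.random.default_rng(11)
        X, y = random_instance(rng, n=30, p=10)
        assert plsda.q2(X, y, 3, seed=5) == plsda.q2(X, y, 3, seed=5)

    def test_q2_rarely_exceeds_r2y(self):
        rng = np.random.default_rng(12)
        ok = 0
        for i in range(20):
            X, y = random_instance(rng, n=30, p=10)
            model = plsda.fit_pls(X, y, n_components=2)
            if plsda.q2(X, y, 2, seed=i) <= plsda.r2y(model, X, y) + 0.05:
                ok += 1
        assert ok >= 18


class TestPermutationTest:
    def test_minimum_attainable_p_on_separated_classes(self):
        rng = np.random.default_rng(13)
        n = 24
        y = np.array(["a"] * 12 + ["b"] * 12)
        X = rng.standard_normal((n, 6))
        X[:, 0] += np.where(y == "b", 6.0, 0.0)
        quality = plsda.permutation_test(X, y, n_components=2, n_perm=199,
                                         seed=0, folds=4)
        assert quality.permutation_p == pytest.approx(1 / 200)

    def test_p_respects_add_one_lower_bound(self):
        rng = np.random.default_rng(14)
        X, y = random_instance(rng, n=20, p=6)
        q = plsda.permutation_test(X, y, n_components=2, n_perm=19, seed=0,
                                   folds=3)
        assert q.permutation_p >= 1 / 20
        assert q.n_permutations == 19

    def test_zero_permutations_error(self):
        rng = np.random.default_rng(15)
        X, y = random_instance(rng)
        with pytest.raises(ValueError):
            plsda.permutation_test(X, y, n_perm=0)


class TestConfidenceEllipse:
    def test_chi_square_radius_at_95(self):
        rng = np.random.default_rng(16)
        S = rng.standard_normal((500, 2))
        ell = plsda.confidence_ellipse(S)
        assert ell.squared_radius == pytest.approx(stats.chi2.ppf(0.95, 2))
        assert ell.squared_radius == pytest.approx(5.991, abs=5e-3)

    def test_zero_level_degenerate(self):
        rng = np.random.default_rng(17)
        S = rng.standard_normal((10, 2))
        ell = plsda.confidence_ellipse(S, level=0.0)
        assert ell.squared_radius == 0.0

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(18)
        S = rng.standard_normal((50, 2)) @ np.array([[2.0, 0.3], [0.3, 0.5]])
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        e1 = plsda.confidence_ellipse(S)
        e2 = plsda.confidence_ellipse(S @ R.T)
        np.testing.assert_allclose(e2.center, R @ e1.center, atol=1e-12)
        np.testing.assert_allclose(e2.covariance, R @ e1.covariance @ R.T,
                                   atol=1e-12)

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            plsda.confidence_ellipse(np.zeros((2, 2)))


class TestMahalanobisClassifier:
    def make_model(self, cov, centroids):
        """Minimal 2-component model with prescribed score geometry."""
        k = 2
        return plsda.PlsModel(
            n_components=k, x_weights=np.eye(k), x_loadings=np.eye(k),
            y_loadings=np.zeros((2, k)), x_rotations=np.eye(k),
            scores=np.zeros((4, k)), x_mean=np.zeros(k), x_sd=np.ones(k),
            y_mean=np.zeros(2), class_levels=list(centroids),
            class_centroids={c: np.asarray(v, float)
                             for c, v in centroids.items()},
            class_cov=np.asarray(cov, float))

    def test_hand_case_diag_cov(self):
        # Sigma=diag(4,1), centroid (0,0), point (2,1): d = sqrt(4/4+1/1)=sqrt 2
        model = self.make_model([[4.0, 0], [0, 1.0]],
                                {"a": [0, 0], "b": [10, 10]})
        _, dists = plsda.mahalanobis_classify(model, np.array([[2.0, 1.0]]))
        assert dists[0, 0] == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_point_at_centroid_has_zero_distance(self):
        model = self.make_model(np.eye(2), {"a": [1, 2], "b": [-3, 0]})
        labels, dists = plsda.mahalanobis_classify(model, np.array([[1.0, 2.0]]))
        assert labels == ["a"] and dists[0, 0] == 0.0

    def test_identity_cov_equals_euclidean(self):
        rng = np.random.default_rng(19)
        model = self.make_model(np.eye(2), {"a": [0, 0], "b": [3, 3]})
        pts = rng.standard_normal((6, 2))
        _, dists = plsda.mahalanobis_classify(model, pts)
        np.testing.assert_allclose(dists[:, 0], np.linalg.norm(pts, axis=1),
                                   atol=1e-12)

    def test_agrees_with_brute_force_exactly(self):
        rng = np.random.default_rng(20)
        X = rng.standard_normal((40, 8))
        y = np.array(["a", "b", "c", "d"] * 10)
        model = plsda.fit_pls(X, y, n_components=4)
        X_new = rng.standard_normal((15, 8))
        labels, dists = plsda.mahalanobis_classify(model, X_new)
        bl, bd = brute_force_mahalanobis(model, X_new)
        assert labels == bl
        np.testing.assert_array_equal(dists, bd)
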