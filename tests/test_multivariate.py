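"""PCA via SVD and PLS1-NIPALS with VIP: oracles, identities, cross-checks."""

import numpy as np
import pytest

from zebramet import autoscale, pca, plsda_fit, vip_scores


def random_model(seed, n=16, j=10, a=2):
    rng = np.random.default_rng(seed)
    X = autoscale(rng.normal(size=(n, j))).scaled
    y = np.array(["a", "b"] * (n // 2))
    return plsda_fit(X, y, n_components=a), j


class TestPca:
    def test_rank_one_matrix_is_fully_explained(self):
        v = np.array([1.0, -2.0, 0.5])
        X = np.outer([1.0, -1.0, 2.0, -2.0], v)
        model = pca(X, n_components=1)
        assert model.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_diagonal_covariance_fractions(self):
        # sample covariance diag(4, 1) up to a common factor -> (0.8, 0.2)
        X = np.array([[2.0, 0.0], [-2.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        model = pca(X, n_components=2)
        np.testing.assert_allclose(
            model.explained_variance_fraction, [0.8, 0.2], atol=1e-12
        )

    def test_loadings_orthonormal_and_fractions_bounded(self):
        rng = np.random.default_rng(3)
        X = autoscale(rng.normal(size=(20, 8))).scaled
        model = pca(X, n_components=5)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-8)
        frac = model.explained_variance_fraction
        assert np.all(np.diff(frac) <= 1e-12)
        assert frac.sum() <= 1 + 1e-12

    def test_reconstruction_error_matches_unexplained_variance(self):
        rng = np.random.default_rng(4)
        X = autoscale(rng.normal(size=(15, 6))).scaled
        model = pca(X, n_components=3)
        resid = X - model.scores @ model.loadings.T
        lhs = np.sum(resid**2) / np.sum(X**2)
        assert lhs == pytest.approx(
            1 - model.explained_variance_fraction.sum(), abs=1e-8
        )

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        X = autoscale(rng.normal(size=(12, 5))).scaled
        perm = rng.permutation(12)
        a = pca(X, n_components=3)
        b = pca(X[perm], n_components=3)
        np.testing.assert_allclose(a.loadings, b.loadings, atol=1e-10)
        np.testing.assert_allclose(
            a.explained_variance_fraction, b.explained_variance_fraction
        )
        np.testing.assert_allclose(a.scores[perm], b.scores, atol=1e-10)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(6)
        X = autoscale(rng.normal(size=(10, 4))).scaled
        model = pca(X, n_components=2)
        for a in range(2):
            col = model.loadings[:, a]
            assert col[np.argmax(np.abs(col))] > 0

    def test_components_beyond_rank_warn_with_zero_variance(self):
        v = np.array([1.0, -2.0, 0.5])
        X = np.outer([1.0, -1.0, 2.0], v)
        with pytest.warns(UserWarning, match="rank"):
            model = pca(X, n_components=2)
        assert model.explained_variance_fraction[1] == pytest.approx(0.0, abs=1e-12)


class TestPlsda:
    def informative_orthogonal_fixture(self):
        # feature 1 equals the class response, feature 2 orthogonal to it
        y = np.array(["hi", "hi", "lo", "lo"])
        f1 = np.array([1.0, 1.0, -1.0, -1.0])
        f2 = np.array([1.0, -1.0, 1.0, -1.0])  # orthogonal to f1
        X = autoscale(np.column_stack([f1, f2])).scaled
        return X, y

    def test_one_component_vip_closed_form(self):
        X, y = self.informative_orthogonal_fixture()
        model = plsda_fit(X, y, n_components=1)
        np.testing.assert_allclose(model.weights[:, 0], [1.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(
            vip_scores(model, 1), [np.sqrt(2), 0.0], atol=1e-12
        )
        assert model.r2y[0] == pytest.approx(1.0)

    def test_first_weight_is_normalized_covariance_direction(self):
        # independent direct computation: w1 = X'y / ||X'y||
        model, j = random_model(7, a=1)
        rng = np.random.default_rng(7)
        X = autoscale(rng.normal(size=(16, 10))).scaled
        y = np.array([1.0, -1.0] * 8)
        y = y - y.mean()
        direct = X.T @ y
        direct = direct / np.linalg.norm(direct)
        w = model.weights[:, 0]
        cos = abs(direct @ w)
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_mean_squared_vip_is_one(self):
        for seed in range(12):
            model, j = random_model(seed, a=3)
            for a in range(1, model.n_components + 1):
                v = vip_scores(model, a)
                assert np.mean(v**2) == pytest.approx(1.0, abs=1e-8)

    def test_equal_weights_give_unit_vip(self):
        # J features each identical to y: |w_j| = 1/sqrt(J) -> VIP = 1
        y = np.array(["a", "a", "a", "b", "b", "b"])
        f = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0])
        X = autoscale(np.column_stack([f] * 5)).scaled
        model = plsda_fit(X, y, n_components=1)
        np.testing.assert_allclose(model.vip, 1.0, atol=1e-12)

    def test_score_vector_is_deflated_x_times_weight(self):
        model, _ = random_model(9, a=3)
        # component 1: t1 = X w1 on the undeflated matrix
        rng = np.random.default_rng(9)
        X = autoscale(rng.normal(size=(16, 10))).scaled
        np.testing.assert_allclose(
            model.scores[:, 0], X @ model.weights[:, 0], atol=1e-10
        )

    def test_affine_label_recoding_leaves_weights_parallel(self):
        rng = np.random.default_rng(10)
        X = autoscale(rng.normal(size=(14, 6))).scaled
        y1 = np.array([0, 1] * 7)
        y2 = np.array(["ctrl", "dose"] * 7)
        w1 = plsda_fit(X, y1, 1).weights[:, 0]
        w2 = plsda_fit(X, y2, 1).weights[:, 0]
        assert abs(w1 @ w2) == pytest.approx(1.0, abs=1e-10)

    def test_agrees_with_sklearn_first_component(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(11)
        X = autoscale(rng.normal(size=(20, 9))).scaled
        y = np.array([1.0] * 10 + [-1.0] * 10)
        ours = plsda_fit(X, y, n_components=2)
        ref = PLSRegression(n_components=2, scale=False).fit(X, y - y.mean())
        for a in range(2):
            cos = abs(ours.weights[:, a] @ ref.x_weights_[:, a])
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(ValueError, match="two classes"):
            plsda_fit(X, ["a"] * 6, 1)

    def test_uninformative_x_truncates(self):
        # X orthogonal to y in every feature -> no component extractable
        y = np.array([1.0, 1.0, -1.0, -1.0])
        f2 = np.array([1.0, -1.0, 1.0, -1.0])
        X = np.column_stack([f2, 2 * f2])
        with pytest.raises(ValueError, match="no PLS component"):
            with pytest.warns(UserWarning, match="truncated"):
                plsda_fit(X, y, 1)

    def test_simulated_classes_separate_on_component_one(self, study_metrics):
        """LC10 vs half-LC10 scores separate with no overlap for the
        effect-carrying drugs in >= 90% of seeds."""
        flags = [
            m.separation_ok[d]
            for m in study_metrics
            for d in ("paracetamol", "tdf", "tfv")
        ]
        assert np.mean(flags) >= 0.9
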