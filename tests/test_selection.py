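"""PCA projection, NCA feature weighting, and the dropout-threshold search."""

import numpy as np
import pytest

from echopat.selection import (
    NCAWeights,
    RUSBoostClassifier,
    cv_accuracy,
    default_classifiers,
    dropout_search,
    nca_weights,
    pca_fit,
    pca_transform,
)
from sklearn.svm import SVC


def _blobs(rng, n_per_class=30, n_informative=2, n_noise=8, spread=4.0):
    """Gaussian class blobs in the first coordinates, noise elsewhere."""
    X, y = [], []
    for c in range(3):
        centre = np.zeros(n_informative + n_noise)
        centre[:n_informative] = spread * np.cos(2.1 * c + np.arange(n_informative))
        X.append(centre + rng.normal(size=(n_per_class, n_informative + n_noise)))
        y += [c] * n_per_class
    return np.vstack(X), np.array(y)


class TestPCA:
    def test_exact_low_rank_reconstruction(self, rng):
        basis = rng.normal(size=(2, 10))
        coords = rng.normal(size=(40, 2))
        X = coords @ basis + rng.normal(size=10)  # plane + offset
        model = pca_fit(X, 2)
        Z = pca_transform(model, X)
        recon = Z @ model.basis + model.column_means
        assert np.allclose(recon, X, atol=1e-8)

    def test_matches_svd_oracle_up_to_sign(self, rng):
        X = rng.normal(size=(25, 12))
        eta = 5
        model = pca_fit(X, eta)
        Z = pca_transform(model, X)
        # independent route: direct SVD of the centred matrix
        Xm = X - X.mean(axis=0)
        U, S, Vt = np.linalg.svd(Xm, full_matrices=False)
        Z_ref = (Vt[:eta] @ Xm.T).T
        for j in range(eta):
            assert np.allclose(Z[:, j], Z_ref[:, j], atol=1e-8) or np.allclose(
                Z[:, j], -Z_ref[:, j], atol=1e-8
            )
        assert np.allclose(model.singular_values, S[:eta])

    def test_singular_values_non_increasing(self, rng):
        X = rng.normal(size=(30, 8))
        sv = pca_fit(X, 6).singular_values
        assert np.all(np.diff(sv) <= 1e-9)

    def test_eta_out_of_range(self, rng):
        X = rng.normal(size=(10, 5))
        for eta in (0, 10):
            with pytest.raises(ValueError):
                pca_fit(X, eta)


class TestNCA:
    def test_informative_feature_gets_max_weight(self, rng):
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 10))
        X[:, 3] = y * 6 + rng.normal(scale=0.3, size=n)  # feature 3 separates
        w = nca_weights(X, y, seed=0).omega
        assert w.argmax() == 3 and w[3] == 1.0

    def test_duplicated_feature_shares_weight(self, rng):
        n = 60
        y = np.repeat([0, 1], n // 2)
        sig = y * 5 + rng.normal(scale=0.4, size=n)
        X = np.column_stack([sig, sig, rng.normal(size=(n, 4))])
        w = nca_weights(X, y, seed=0).omega
        assert abs(w[0] - w[1]) <= 0.2 * max(w[0], w[1])

    def test_identical_features_uniform(self, rng):
        y = np.repeat([0, 1], 10)
        col = rng.normal(size=20)
        X = np.tile(col[:, None], (1, 5))
        w = nca_weights(X, y, seed=0).omega
        assert np.allclose(w, w[0])
        assert w.max() == 1.0

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            nca_weights(rng.normal(size=(10, 3)), np.zeros(10))

    def test_deterministic(self, rng):
        X, y = _blobs(rng, n_per_class=15)
        w1 = nca_weights(X, y, seed=5).omega
        w2 = nca_weights(X, y, seed=5).omega
        assert np.array_equal(w1, w2)

    def test_weights_validated(self):
        with pytest.raises(ValueError):
            NCAWeights(omega=np.array([0.2, 0.5]))  # max != 1


class TestDropoutSearch:
    @pytest.fixture
    def data(self, rng):
        return _blobs(rng, n_per_class=20, n_informative=2, n_noise=8)

    def test_degenerate_grid_single_cell(self, data, rng):
        X, y = data
        w = NCAWeights(omega=np.linspace(0.1, 1.0, X.shape[1]) / 1.0 * 0 + np.linspace(0.1, 1, X.shape[1]) / np.linspace(0.1, 1, X.shape[1]).max())
        res = dropout_search(
            X, y, w, np.array([0.05]), {"svm": SVC(kernel="linear")}, cv_folds=3, seed=0
        )
        assert res.accuracy_table.shape == (1, 1)
        assert res.best_accuracy == res.accuracy_table[0, 0]

    def test_retained_counts_monotone(self, data, rng):
        X, y = data
        w = nca_weights(X, y, seed=1)
        grid = np.round(np.arange(0.1, 1.001, 0.05), 10)
        res = dropout_search(X, y, w, grid, {"svm": SVC(kernel="linear")}, cv_folds=3, seed=0)
        assert np.all(np.diff(res.n_retained) <= 0)

    def test_argmax_consistency_rescan(self, data):
        X, y = data
        w = nca_weights(X, y, seed=1)
        grid = np.round(np.arange(0.1, 1.001, 0.1), 10)
        clfs = {"lin": SVC(kernel="linear"), "rbf": SVC(kernel="rbf")}
        res = dropout_search(X, y, w, grid, clfs, cv_folds=3, seed=0)
        li, ki = np.unravel_index(np.argmax(res.accuracy_table), res.accuracy_table.shape)
        assert res.best_accuracy == res.accuracy_table.max()
        assert res.best_tau == grid[li]
        assert res.best_classifier == list(clfs)[ki]

    def test_tau_above_all_weights_scores_zero(self, data):
        X, y = data
        omega = np.full(X.shape[1], 0.3)
        omega[0] = 1.0
        w = NCAWeights(omega=omega)
        res = dropout_search(
            X, y, w, np.array([0.5, 1.0, 1.01]), {"svm": SVC(kernel="linear")}, 3, 0
        )
        assert res.n_retained[-1] == 0 and res.accuracy_table[-1, 0] == 0.0

    def test_noise_features_dropped_without_accuracy_loss(self, rng):
        X, y = _blobs(rng, n_per_class=25, n_informative=5, n_noise=45, spread=5.0)
        w = nca_weights(X, y, seed=2)
        grid = np.round(np.arange(0.1, 1.001, 0.1), 10)
        clfs = {"svm": SVC(kernel="linear")}
        res = dropout_search(X, y, w, grid, clfs, cv_folds=5, seed=2)
        baseline = cv_accuracy(clfs["svm"], X * w.omega, y, 5, 2)
        assert res.best_accuracy >= baseline - 0.02

    def test_empty_grid_rejected(self, data):
        X, y = data
        with pytest.raises(ValueError):
            dropout_search(X, y, NCAWeights(omega=np.ones(X.shape[1])), np.array([]))


class TestClassifierBank:
    def test_six_classifiers_in_order(self):
        bank = default_classifiers(0)
        assert list(bank) == [
            "svm_poly", "svm_rbf", "random_forest", "adaboost", "naive_bayes", "rus_boost",
        ]

    def test_rusboost_learns_separable_data(self, rng):
        X, y = _blobs(rng, n_per_class=30, n_informative=2, n_noise=2, spread=6.0)
        clf = RUSBoostClassifier(n_estimators=30, random_state=0).fit(X, y)
        assert (clf.predict(X) == y).mean() > 0.9

    def test_rusboost_deterministic_given_seed(self, rng):
        X, y = _blobs(rng, n_per_class=15)
        p1 = RUSBoostClassifier(random_state=3).fit(X, y).predict(X)
        p2 = RUSBoostClassifier(random_state=3).fit(X, y).predict(X)
        assert np.array_equal(p1, p2)

    def test_rusboost_handles_imbalance(self, rng):
        X = np.vstack([rng.normal(0, 1, (100, 3)), rng.normal(4, 1, (10, 3))])
        y = np.array([0] * 100 + [1] * 10)
        clf = RUSBoostClassifier(n_estimators=30, random_state=0).fit(X, y)
        minority_recall = (clf.predict(X[y == 1]) == 1).mean()
        assert minority_recall >= 0.8

    def test_knn_adaboost_option(self, rng):
        bank = default_classifiers(0, adaboost_weak="knn")
        X, y = _blobs(rng, n_per_class=20, n_informative=2, n_noise=2, spread=6.0)
        clf = bank["adaboost"].fit(X, y)
        assert (clf.predict(X) == y).mean() > 0.8
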