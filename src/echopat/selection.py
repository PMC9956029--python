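"""Feature selection: SVD-based PCA, NCA feature weighting, and the
dropout-threshold search over a bank of six classifiers.

The search works on the PCA-projected feature matrix.  Neighbourhood
component analysis assigns each projected feature a nonnegative weight by
maximising the expected leave-one-out nearest-neighbour accuracy; weights
are rescaled to a maximum of 1 so that the dropout-threshold grid
tau in [0.1, 1] is meaningful.  For every tau, features with weight below
tau are dropped, the survivors are scaled by their weights, each classifier
is scored by stratified k-fold cross-validation, and the best (tau,
classifier) cell of the accuracy table is selected (ties to the lower tau,
then classifier order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.decomposition import PCA
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PCAModel",
    "NCAWeights",
    "SearchResult",
    "pca_fit",
    "pca_transform",
    "nca_weights",
    "default_classifiers",
    "dropout_search",
    "RUSBoostClassifier",
]


@dataclass(frozen=True)
class PCAModel:
    """Column means, projection basis and singular values of a fitted PCA."""

    column_means: np.ndarray
    basis: np.ndarray  # (retained, D) rows of V^T
    singular_values: np.ndarray
    retained: int

    def __post_init__(self) -> None:
        sv = np.asarray(self.singular_values)
        if np.any(np.diff(sv) > 1e-9):
            raise ValueError("singular values must be non-increasing")


def pca_fit(X: np.ndarray, eta: int) -> PCAModel:
    """Centre ``X`` column-wise and retain the top ``eta`` SVD components.

    The projection of the training matrix equals V^T X_m^T (transposed to
    observations x components) up to per-component sign.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if not 1 <= eta <= min(n - 1, d):
        raise ValueError(f"eta must lie in [1, {min(n - 1, d)}], got {eta}")
    p = PCA(n_components=eta, svd_solver="full")
    p.fit(X)
    return PCAModel(
        column_means=p.mean_,
        basis=p.components_,
        singular_values=p.singular_values_,
        retained=eta,
    )


def pca_transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project observations onto the retained components."""
    X = np.asarray(X, dtype=float)
    return (X - model.column_means) @ model.basis.T


@dataclass(frozen=True)
class NCAWeights:
    """Per-feature NCA weights rescaled to max 1."""

    omega: np.ndarray
    objective: float = float("nan")

    def __post_init__(self) -> None:
        w = np.asarray(self.omega, dtype=float)
        if w.ndim != 1 or np.any(w < 0):
            raise ValueError("omega must be a 1-D nonnegative vector")
        if w.size and not np.isclose(w.max(), 1.0):
            raise ValueError("omega must be rescaled to max 1")


def _nca_objective(u, A, same, lam):
    """Negative regularised NCA leave-one-out objective and its gradient.

    Parametrised by u with per-feature weight w_r = u_r^2, so weights are
    nonnegative without constraints.  Distances are weighted L1:
    d_ij = sum_r w_r |x_ir - x_jr|.
    """
    n = A.shape[0]
    w = u * u
    d = A @ w  # (n, n) weighted distances
    np.fill_diagonal(d, np.inf)
    logk = -d
    logk -= logk.max(axis=1, keepdims=True)
    k = np.exp(logk)
    p = k / k.sum(axis=1, keepdims=True)  # p_ij, leave-one-out softmax
    p_i = (p * same).sum(axis=1)
    f = p_i.mean() - lam * np.sum(w * w)

    # dF/dw_r = (1/n) sum_i [ p_i * sum_j p_ij A_ijr - sum_{j in class} p_ij A_ijr ]
    coef = p * p_i[:, None] - p * same  # (n, n)
    grad_w = coef.reshape(-1) @ A.reshape(n * n, -1) / n - 2.0 * lam * w
    grad_u = 2.0 * u * grad_w
    return -f, -grad_u


def nca_weights(X: np.ndarray, y, seed: int = 0, reg: float | None = None) -> NCAWeights:
    """Diagonal NCA feature weighting.

    Maximises the expected leave-one-out soft-nearest-neighbour accuracy
    with an L2 penalty on the weights (default lambda = 1/N), by L-BFGS on
    an unconstrained square-root parametrisation.  Features are standardised
    internally; the returned weights are rescaled to max 1.  The optimiser
    is deterministic; ``seed`` is accepted for interface symmetry with the
    stochastic stages.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    if np.unique(y).size < 2:
        raise ValueError("NCA requires at least two classes")
    lam = 1.0 / n if reg is None else reg
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    A = np.abs(Z[:, None, :] - Z[None, :, :])  # (n, n, d) per-feature L1 gaps
    same = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)

    u0 = np.ones(d)
    res = minimize(
        _nca_objective, u0, args=(A, same, lam), jac=True, method="L-BFGS-B",
        options={"maxiter": 200},
    )
    w = res.x * res.x
    top = w.max()
    omega = np.ones(d) if top <= 0 else w / top
    return NCAWeights(omega=omega, objective=float(-res.fun))


class RUSBoostClassifier(BaseEstimator, ClassifierMixin):
    """Boosting with random undersampling (SAMME-style).

    Each round trains the weak learner (a shallow decision tree, depth 3 by
    default, as in the usual tree-based formulation) on a class-balanced
    random subsample drawn with probability proportional to the current
    boosting weights; weights are updated on the full set.  Designed for
    imbalanced data; on balanced data it behaves like a noisy AdaBoost.
    """

    def __init__(self, n_estimators: int = 50, random_state: int | None = None, estimator=None):
        self.n_estimators = n_estimators
        self.random_state = random_state
        self.estimator = estimator

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, yi = np.unique(y, return_inverse=True)
        k = self.classes_.size
        n = X.shape[0]
        rng = np.random.default_rng(self.random_state)
        base = self.estimator or DecisionTreeClassifier(max_depth=3)
        w = np.full(n, 1.0 / n)
        self.estimators_, self.alphas_ = [], []
        n_min = np.bincount(yi).min()
        for _ in range(self.n_estimators):
            idx = []
            for c in range(k):
                members = np.flatnonzero(yi == c)
                pc = w[members] / w[members].sum()
                take = min(n_min, members.size)
                idx.append(rng.choice(members, size=take, replace=False, p=pc)
                           if take < members.size else members)
            idx = np.concatenate(idx)
            est = clone(base)
            if isinstance(est, DecisionTreeClassifier):
                est.set_params(random_state=int(rng.integers(2**31 - 1)))
            est.fit(X[idx], yi[idx])
            pred = est.predict(X)
            err = float(w[pred != yi].sum())
            if err >= 1.0 - 1.0 / k:
                continue
            err = max(err, 1e-10)
            alpha = np.log((1.0 - err) / err) + np.log(k - 1.0)
            self.estimators_.append(est)
            self.alphas_.append(alpha)
            w *= np.exp(alpha * (pred != yi))
            w /= w.sum()
            if err < 1e-9:
                break
        if not self.estimators_:  # degenerate: fall back to a single stump
            est = clone(base)
            est.fit(X, yi)
            self.estimators_, self.alphas_ = [est], [1.0]
        return self

    def predict(self, X):
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=float)
        votes = np.zeros((X.shape[0], self.classes_.size))
        for est, alpha in zip(self.estimators_, self.alphas_):
            votes[np.arange(X.shape[0]), est.predict(X)] += alpha
        return self.classes_[votes.argmax(axis=1)]


def default_classifiers(seed: int = 0, adaboost_weak: str = "stump") -> dict:
    """The six-classifier bank, in fixed evaluation order.

    adaboost_weak selects the AdaBoost weak learner: "stump" (default) or
    "knn" (3-nearest-neighbour, boosted by weighted resampling).
    """
    if adaboost_weak == "stump":
        ada_base = DecisionTreeClassifier(max_depth=1)
    elif adaboost_weak == "knn":
        ada_base = _ResampledKNN(random_state=seed)
    else:
        raise ValueError("adaboost_weak must be 'stump' or 'knn'")
    return {
        "svm_poly": SVC(kernel="poly", degree=3, gamma="scale", coef0=1.0, random_state=seed),
        "svm_rbf": SVC(kernel="rbf", gamma="scale", random_state=seed),
        "random_forest": RandomForestClassifier(n_estimators=100, random_state=seed),
        "adaboost": AdaBoostClassifier(estimator=ada_base, n_estimators=50, random_state=seed),
        "naive_bayes": GaussianNB(),
        "rus_boost": RUSBoostClassifier(n_estimators=50, random_state=seed),
    }


class _ResampledKNN(BaseEstimator, ClassifierMixin):
    """KNN weak learner usable under AdaBoost: honours sample_weight by
    weighted resampling of the training set."""

    def __init__(self, n_neighbors: int = 3, random_state: int | None = None):
        self.n_neighbors = n_neighbors
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if sample_weight is not None:
            rng = np.random.default_rng(self.random_state)
            p = np.asarray(sample_weight, dtype=float)
            p = p / p.sum()
            idx = rng.choice(len(y), size=len(y), replace=True, p=p)
            X, y = X[idx], y[idx]
        k = min(self.n_neighbors, len(y))
        self._knn = KNeighborsClassifier(n_neighbors=k).fit(X, y)
        return self

    def predict(self, X):
        return self._knn.predict(X)


@dataclass(frozen=True)
class SearchResult:
    """Accuracy surface a(tau, classifier) and its argmax."""

    accuracy_table: np.ndarray  # (len(tau_grid), n_classifiers)
    tau_values: np.ndarray
    classifier_names: tuple[str, ...]
    best_tau: float
    best_classifier: str
    best_accuracy: float
    retained_features: np.ndarray  # indices kept at best_tau
    n_retained: np.ndarray  # per tau
    errors: tuple = ()

    def __post_init__(self) -> None:
        if not np.isclose(self.best_accuracy, np.max(self.accuracy_table)):
            raise ValueError("best accuracy must equal the table maximum")
        if np.any(np.diff(self.n_retained) > 0):
            raise ValueError("retained-feature count must be non-increasing in tau")


def cv_accuracy(clf, X: np.ndarray, y: np.ndarray, cv_folds: int, seed: int) -> float:
    """Mean stratified k-fold CV accuracy of a classifier."""
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        est = clone(clf)
        est.fit(X[tr], y[tr])
        accs.append(float(np.mean(est.predict(X[te]) == y[te])))
    return float(np.mean(accs))


def dropout_search(
    X: np.ndarray,
    y,
    weights: NCAWeights,
    tau_grid: np.ndarray,
    classifiers: dict | None = None,
    cv_folds: int = 10,
    seed: int = 0,
) -> SearchResult:
    """Scan the dropout-threshold grid and the classifier bank.

    For each tau: drop features with weight < tau (equality retains), scale
    the survivors by their weights, and score every classifier by stratified
    CV.  A tau that drops every feature scores 0 and is skipped for
    training.  The argmax breaks ties toward lower tau, then classifier
    order.  Classifier failures are recorded as accuracy 0, not raised.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    tau_grid = np.asarray(tau_grid, dtype=float)
    if tau_grid.size == 0:
        raise ValueError("tau_grid must be nonempty")
    classifiers = classifiers if classifiers is not None else default_classifiers(seed)
    if not classifiers:
        raise ValueError("classifiers must be nonempty")
    names = tuple(classifiers)
    omega = weights.omega

    table = np.zeros((tau_grid.size, len(names)))
    n_retained = np.zeros(tau_grid.size, dtype=int)
    errors = []
    for li, tau in enumerate(tau_grid):
        keep = omega >= tau
        n_retained[li] = int(keep.sum())
        if n_retained[li] == 0:
            continue
        Xs = X[:, keep] * omega[keep]
        for ki, name in enumerate(names):
            try:
                table[li, ki] = cv_accuracy(classifiers[name], Xs, y, cv_folds, seed)
            except Exception as exc:  # recorded, not fatal
                errors.append((float(tau), name, repr(exc)))
                table[li, ki] = 0.0

    best_li, best_ki = np.unravel_index(np.argmax(table), table.shape)
    best_tau = float(tau_grid[best_li])
    return SearchResult(
        accuracy_table=table,
        tau_values=tau_grid,
        classifier_names=names,
        best_tau=best_tau,
        best_classifier=names[best_ki],
        best_accuracy=float(table[best_li, best_ki]),
        retained_features=np.flatnonzero(omega >= best_tau),
        n_retained=n_retained,
        errors=tuple(errors),
    )
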