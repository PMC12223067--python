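"""Reference learners for the response-prediction engine.

Three sklearn-compatible estimators cover the model families the
prediction pipeline needs:

* :class:`ElasticNetLogit` — L1/L2-penalised logistic regression fitted by
  coordinate descent inside an IRLS loop (glmnet-style objective
  ``(1/n) * logloss + alpha * (l1_ratio*|b|_1 + (1-l1_ratio)/2*|b|_2^2)``).
* :class:`GradientBoostedTrees` — logistic-loss gradient boosting with
  depth-limited regression trees and Newton leaf updates.
* :class:`OrdinalRidge` — ridge regression on ordinal outcome codes
  (0=remission .. 3=high disease activity) treated as a regression.

All follow the sklearn estimator contract (``fit`` / ``predict`` /
``get_params``; fitted attributes carry a trailing underscore) and can be
used inside sklearn pipelines and model selection. Additional learners
can be registered through the adapter in :data:`LEARNERS`.
"""
from __future__ import annotations

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, clone
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "ElasticNetLogit",
    "GradientBoostedTrees",
    "OrdinalRidge",
    "SklearnAdapter",
    "LEARNERS",
    "register_learner",
    "make_learner",
]


def _soft_threshold(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


class ElasticNetLogit(BaseEstimator, ClassifierMixin):
    """Elastic-net penalised logistic regression by coordinate descent.

    Parameters
    ----------
    alpha
        Overall penalty strength (lambda).
    l1_ratio
        Mix between lasso (1.0) and ridge (0.0).
    standardize
        Internally standardise features before fitting (coefficients are
        kept on the standardised scale; prediction undoes the scaling).
    """

    def __init__(
        self,
        alpha: float = 0.1,
        l1_ratio: float = 0.5,
        max_iter: int = 100,
        cd_iter: int = 100,
        tol: float = 1e-7,
        standardize: bool = True,
    ):
        self.alpha = alpha
        self.l1_ratio = l1_ratio
        self.max_iter = max_iter
        self.cd_iter = cd_iter
        self.tol = tol
        self.standardize = standardize

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with rows matching y")
        self.classes_ = np.unique(y)
        if not set(self.classes_) <= {0.0, 1.0}:
            raise ValueError("y must be binary 0/1")
        n, p = X.shape
        self.x_mean_ = X.mean(axis=0)
        if self.standardize:
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            self.x_sd_ = sd
        else:
            self.x_sd_ = np.ones(p)
        Xs = (X - self.x_mean_) / self.x_sd_

        lam1 = self.alpha * self.l1_ratio
        lam2 = self.alpha * (1.0 - self.l1_ratio)
        beta = np.zeros(p)
        pbar = np.clip(y.mean(), 1e-6, 1 - 1e-6)
        b0 = float(np.log(pbar / (1 - pbar)))
        eta = np.full(n, b0)
        for _ in range(self.max_iter):
            mu = expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-5, None)
            z = eta + (y - mu) / w
            r = z - eta  # working residual
            beta_old = beta.copy()
            for _ in range(self.cd_iter):
                max_delta = 0.0
                # intercept (unpenalised)
                d0 = np.average(r, weights=w)
                b0 += d0
                r -= d0
                for j in range(p):
                    xj = Xs[:, j]
                    rho = (w * xj * (r + xj * beta[j])).sum() / n
                    denom = (w * xj * xj).sum() / n + lam2
                    new = _soft_threshold(rho, lam1) / denom
                    delta = new - beta[j]
                    if delta != 0.0:
                        r -= xj * delta
                        beta[j] = new
                        max_delta = max(max_delta, abs(delta))
                if max_delta < self.tol:
                    break
            eta = b0 + Xs @ beta
            if np.abs(beta - beta_old).max() < self.tol:
                break
        self.coef_ = beta
        self.intercept_ = b0
        self.n_features_in_ = p
        self.importance_ = np.abs(beta)
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        Xs = (X - self.x_mean_) / self.x_sd_
        return self.intercept_ + Xs @ self.coef_

    def predict_proba(self, X):
        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.decision_function(X) >= 0).astype(int)


class ElasticNetLinear(BaseEstimator, RegressorMixin):
    """Elastic-net penalised least squares by coordinate descent.

    Objective ``(1/2n) * ||y - b0 - X b||^2 + alpha*(l1_ratio*|b|_1 +
    (1-l1_ratio)/2*|b|_2^2)``. Used for embedded feature selection on the
    ordinal outcome.
    """

    def __init__(
        self,
        alpha: float = 0.1,
        l1_ratio: float = 1.0,
        max_iter: int = 200,
        tol: float = 1e-8,
        standardize: bool = True,
    ):
        self.alpha = alpha
        self.l1_ratio = l1_ratio
        self.max_iter = max_iter
        self.tol = tol
        self.standardize = standardize

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        self.x_mean_ = X.mean(axis=0)
        if self.standardize:
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            self.x_sd_ = sd
        else:
            self.x_sd_ = np.ones(p)
        Xs = (X - self.x_mean_) / self.x_sd_
        self.intercept_ = float(y.mean())
        r = y - self.intercept_
        beta = np.zeros(p)
        lam1 = self.alpha * self.l1_ratio
        lam2 = self.alpha * (1.0 - self.l1_ratio)
        col_ss = (Xs * Xs).sum(axis=0) / n
        for _ in range(self.max_iter):
            max_delta = 0.0
            for j in range(p):
                xj = Xs[:, j]
                rho = (xj * (r + xj * beta[j])).sum() / n
                new = _soft_threshold(rho, lam1) / (col_ss[j] + lam2)
                delta = new - beta[j]
                if delta != 0.0:
                    r -= xj * delta
                    beta[j] = new
                    max_delta = max(max_delta, abs(delta))
            if max_delta < self.tol:
                break
        self.coef_ = beta
        self.n_features_in_ = p
        self.importance_ = np.abs(beta)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self.intercept_ + ((X - self.x_mean_) / self.x_sd_) @ self.coef_


class GradientBoostedTrees(BaseEstimator, ClassifierMixin):
    """Gradient boosting for binary response with depth-limited trees.

    Each round fits a regression tree to the logistic-loss gradient and
    replaces leaf values with one Newton step
    ``sum(y - p) / sum(p * (1 - p))`` over the leaf. Variable importance
    accumulates the (unnormalised) impurity decrease of every split,
    i.e. total split gain.
    """

    def __init__(
        self,
        n_estimators: int = 100,
        learning_rate: float = 0.1,
        max_depth: int = 2,
        min_samples_leaf: int = 5,
        subsample: float = 1.0,
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.subsample = subsample
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        self.classes_ = np.unique(y)
        if not set(self.classes_) <= {0.0, 1.0}:
            raise ValueError("y must be binary 0/1")
        n, p = X.shape
        rng = np.random.default_rng(self.random_state)
        pbar = np.clip(y.mean(), 1e-6, 1 - 1e-6)
        self.init_ = float(np.log(pbar / (1 - pbar)))
        F = np.full(n, self.init_)
        self.trees_: list[tuple[DecisionTreeRegressor, np.ndarray]] = []
        self.importance_ = np.zeros(p)
        for m in range(self.n_estimators):
            prob = expit(F)
            grad = y - prob
            if self.subsample < 1.0:
                idx = rng.choice(n, size=max(2, int(round(self.subsample * n))), replace=False)
            else:
                idx = np.arange(n)
            tree = DecisionTreeRegressor(
                max_depth=self.max_depth,
                min_samples_leaf=self.min_samples_leaf,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[idx], grad[idx])
            leaves_fit = tree.apply(X[idx])
            leaf_values = {}
            hess = prob * (1.0 - prob)
            for leaf in np.unique(leaves_fit):
                mask = leaves_fit == leaf
                g = grad[idx][mask].sum()
                h = hess[idx][mask].sum()
                leaf_values[leaf] = g / max(h, 1e-12)
            value_arr = np.zeros(tree.tree_.node_count)
            for leaf, v in leaf_values.items():
                value_arr[leaf] = v
            leaves_all = tree.apply(X)
            # leaves unseen in the subsample keep value 0
            F = F + self.learning_rate * value_arr[leaves_all]
            self.importance_ += tree.tree_.compute_feature_importances(normalize=False)
            self.trees_.append((tree, value_arr))
        self.n_features_in_ = p
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        F = np.full(X.shape[0], self.init_)
        for tree, values in self.trees_:
            F = F + self.learning_rate * values[tree.apply(X)]
        return F

    def predict_proba(self, X):
        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.decision_function(X) >= 0).astype(int)


class OrdinalRidge(BaseEstimator, RegressorMixin):
    """Ridge regression on ordinal disease-activity codes.

    Fits ``y ~ b0 + X b`` with an L2 penalty (closed form on standardised
    features). Predictions are real-valued codes on the 0-3 scale; use
    :func:`synores.ml.ordinal_to_binary` to convert to a response
    probability.
    """

    def __init__(self, alpha: float = 1.0, standardize: bool = True):
        self.alpha = alpha
        self.standardize = standardize

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        self.x_mean_ = X.mean(axis=0)
        if self.standardize:
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            self.x_sd_ = sd
        else:
            self.x_sd_ = np.ones(p)
        Xs = (X - self.x_mean_) / self.x_sd_
        self.y_mean_ = float(y.mean())
        A = Xs.T @ Xs + self.alpha * np.eye(p)
        self.coef_ = np.linalg.solve(A, Xs.T @ (y - self.y_mean_))
        self.n_features_in_ = p
        self.importance_ = np.abs(self.coef_)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        Xs = (X - self.x_mean_) / self.x_sd_
        return self.y_mean_ + Xs @ self.coef_


class SklearnAdapter(BaseEstimator):
    """Adapter exposing any sklearn classifier under the learner contract.

    Importance is taken from ``|coef_|`` or ``feature_importances_``.
    """

    def __init__(self, estimator=None):
        self.estimator = estimator

    def fit(self, X, y):
        self.model_ = clone(self.estimator).fit(X, y)
        if hasattr(self.model_, "coef_"):
            self.importance_ = np.abs(np.ravel(self.model_.coef_))
        elif hasattr(self.model_, "feature_importances_"):
            self.importance_ = np.asarray(self.model_.feature_importances_)
        else:
            self.importance_ = np.zeros(np.asarray(X).shape[1])
        self.classes_ = getattr(self.model_, "classes_", None)
        return self

    def predict_proba(self, X):
        return self.model_.predict_proba(X)

    def predict(self, X):
        return self.model_.predict(X)


#: Registry of learner factories by name; ``plugin:<name>`` entries can be
#: added with :func:`register_learner`.
LEARNERS: dict[str, type] = {
    "elastic_net": ElasticNetLogit,
    "gradient_boosted_trees": GradientBoostedTrees,
    "ordinal_linear": OrdinalRidge,
}


def register_learner(name: str, factory) -> None:
    LEARNERS[f"plugin:{name}"] = factory


def make_learner(name: str, **params):
    if name not in LEARNERS:
        raise ValueError(f"unknown learner {name!r}; registered: {sorted(LEARNERS)}")
    return LEARNERS[name](**params)
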