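"""Pluggable base learners for the distribution-model ensemble.

Contract: ``make_learner(learner_id, random_state)`` returns an object with
``fit(X, y)`` (binary labels) and ``predict_proba(X) -> P(presence)``.
Five reference learners cover the usual SDM algorithm roles:

* ``glm``    — plain logistic regression
* ``gam``    — penalized spline logistic regression (smooth additive effects)
* ``rf``     — random forest
* ``gbm``    — gradient-boosted trees
* ``maxent`` — L1-regularized logistic regression on quadratic feature
               expansions (a common approximation of maximum-entropy models)
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler


class SklearnLearner:
    """Adapter exposing P(presence) from a scikit-learn classifier."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SklearnLearner":
        self.estimator.fit(X, np.asarray(y, dtype=int))
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        proba = self.estimator.predict_proba(X)
        classes = list(self.estimator.classes_)
        return proba[:, classes.index(1)]


class ConstantLearner:
    """Predicts the training prevalence everywhere; useful as a null member."""

    def fit(self, X, y):
        self.rate_ = float(np.mean(y))
        return self

    def predict_proba(self, X):
        return np.full(len(X), self.rate_)


def make_learner(learner_id: str, random_state: int = 0):
    if learner_id == "glm":
        return SklearnLearner(Pipeline([
            ("scale", StandardScaler()),
            ("logit", LogisticRegression(C=1e6, max_iter=2000)),
        ]))
    if learner_id == "gam":
        return SklearnLearner(Pipeline([
            ("spline", SplineTransformer(n_knots=6, degree=3)),
            ("logit", LogisticRegression(C=1.0, max_iter=2000)),
        ]))
    if learner_id == "rf":
        return SklearnLearner(RandomForestClassifier(
            n_estimators=200, min_samples_leaf=2, random_state=random_state))
    if learner_id == "gbm":
        return SklearnLearner(GradientBoostingClassifier(
            n_estimators=100, max_depth=3, random_state=random_state))
    if learner_id == "maxent":
        return SklearnLearner(Pipeline([
            ("poly", PolynomialFeatures(degree=2, include_bias=False)),
            ("scale", StandardScaler()),
            ("logit", LogisticRegression(l1_ratio=1.0, solver="liblinear", C=1.0,
                                         random_state=random_state)),
        ]))
    if learner_id == "constant":
        return ConstantLearner()
    raise ValueError(f"unknown learner {learner_id!r}")


DEFAULT_LEARNERS = ["glm", "gam", "rf", "gbm", "maxent"]
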