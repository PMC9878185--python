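"""Real-valued AdaBoost (SAMME.R) with probability-emitting base learners.

SAMME.R boosts base classifiers through their class-probability estimates
rather than their hard labels: at each stage the weighted class
probabilities p_k(x) are turned into additive contributions

    h_k(x) = (K - 1) * ( log p_k(x) - mean_k' log p_k'(x) )

and the sample weights are updated by

    w_i <- w_i * exp( -lr * (K-1)/K * sum_k y_ik log p_k(x_i) )

with y_ik = 1 for the true class and -1/(K-1) otherwise. The final
prediction is the argmax of the summed h_k. The base learner must accept
``sample_weight`` in fit() and implement predict_proba() — here typically
an RBF-kernel SVC with probability calibration enabled.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = ["SAMMERClassifier"]

_PROBA_EPS = np.finfo(float).eps


class SAMMERClassifier(ClassifierMixin, BaseEstimator):
    """AdaBoost with the SAMME.R (real) update rule.

    Parameters
    ----------
    estimator : classifier with predict_proba and sample_weight support
    n_estimators : int, number of boosting stages
    learning_rate : float in (0, 1], shrinkage on the weight update
    random_state : int or None; seeds per-stage base-learner randomness
    """

    def __init__(self, estimator=None, n_estimators: int = 50,
                 learning_rate: float = 1.0, random_state=None):
        self.estimator = estimator
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        X, y = validate_data(self, X, y)
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        if self.estimator is None:
            raise ValueError("a base estimator with predict_proba is required")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        K = len(self.classes_)
        if K < 2:
            raise ValueError("need at least 2 classes")
        n = X.shape[0]
        w = np.full(n, 1.0 / n) if sample_weight is None else np.asarray(sample_weight, float) / np.sum(sample_weight)
        # y coded as +1 / -1/(K-1) per class
        y_codes = np.full((n, K), -1.0 / (K - 1))
        y_codes[np.arange(n), y_idx] = 1.0

        rng = np.random.default_rng(self.random_state)
        self.estimators_ = []
        for _ in range(self.n_estimators):
            est = clone(self.estimator)
            if "random_state" in est.get_params():
                est.set_params(random_state=int(rng.integers(2**31 - 1)))
            with warnings.catch_warnings():
                # sklearn 1.9 deprecates SVC(probability=True); calibrated
                # probabilities are integral to the SAMME.R update, keep them
                warnings.simplefilter("ignore", FutureWarning)
                est.fit(X, y_idx, sample_weight=w)
            proba = np.clip(est.predict_proba(X), _PROBA_EPS, None)
            log_p = np.log(proba)
            self.estimators_.append(est)
            # weight update; renormalize to keep the distribution proper
            expo = -self.learning_rate * (K - 1) / K * np.sum(y_codes * log_p, axis=1)
            w = w * np.exp(expo)
            total = w.sum()
            if not np.isfinite(total) or total <= 0:
                break
            w /= total
        self.n_classes_ = K
        return self

    def _summed_h(self, X) -> np.ndarray:
        K = self.n_classes_
        out = np.zeros((X.shape[0], K))
        for est in self.estimators_:
            log_p = np.log(np.clip(est.predict_proba(X), _PROBA_EPS, None))
            out += (K - 1) * (log_p - log_p.mean(axis=1, keepdims=True))
        return out

    def decision_function(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        h = self._summed_h(X)
        if self.n_classes_ == 2:
            return h[:, 1] - h[:, 0]
        return h

    def predict_proba(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        h = self._summed_h(X) / max(len(self.estimators_), 1)
        h = h / (self.n_classes_ - 1)
        h -= h.max(axis=1, keepdims=True)
        p = np.exp(h)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.classes_[np.argmax(self._summed_h(X), axis=1)]
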