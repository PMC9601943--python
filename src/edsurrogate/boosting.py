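"""Multi-class AdaBoost: SAMME (discrete votes) and SAMME.R (real-valued
class-probability contributions), implemented from first principles.

Both boosters maintain a weight distribution w_i over the n training
points (initialised to 1/n, re-normalised after every round) and fit a
weak classifier T^(m) per round, by default a depth-1 decision tree.

SAMME: the round's weighted error err^(m) = sum_i w_i 1[c_i != T^(m)(x_i)]
gives the learner weight alpha^(m) = log((1-err)/err) + log(K-1);
misclassified points are up-weighted by exp(alpha).  With K = 2 classes
the log(K-1) term vanishes and SAMME reduces exactly to classical
two-class AdaBoost.  Prediction is the alpha-weighted plurality vote.

SAMME.R: the round's weighted class-probability estimates p_k^(m)(x) give
additive contributions h_k^(m)(x) = (K-1) (log p_k - (1/K) sum_k' log p_k'),
which sum to zero over classes at every x; weights update by
w_i <- w_i exp(-((K-1)/K) y_i^T log p^(m)(x_i)) with the symmetric coding
y_ik = 1 for the true class and -1/(K-1) otherwise.  Prediction is
argmax_k sum_m h_k^(m)(x).

Degenerate rounds: a zero-error round receives the large finite weight
log(1e10) and terminates boosting; a round no better than chance
(err >= 1 - 1/K) is discarded and boosting stops.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.tree import DecisionTreeClassifier

__all__ = ["DecisionStump", "SAMMEClassifier", "SAMMERClassifier", "PROB_FLOOR"]

PROB_FLOOR = 1e-10
_PERFECT_ALPHA = np.log(1e10)
_TIE_TOL = 1e-12


class DecisionStump(BaseEstimator, ClassifierMixin):
    """Weighted one-split decision stump with deterministic tie-breaking.

    Candidate thresholds are the midpoints between consecutive distinct
    feature values; each side predicts its weighted majority class.  Among
    candidates whose weighted errors agree within 1e-12 the stump prefers
    the lower feature index, then the lower threshold — so two runs (or two
    boosting implementations fed weight vectors that differ only in
    floating-point noise) always pick the same split.
    """

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        n = len(y)
        w = (np.full(n, 1.0 / n) if sample_weight is None
             else np.asarray(sample_weight, dtype=float))
        class_w = np.vstack([np.where(y == c, w, 0.0) for c in self.classes_])

        def majority(mask):
            totals = class_w[:, mask].sum(axis=1)
            # ties go to the first (lexicographically smallest) class
            k = int(np.flatnonzero(totals >= totals.max() - _TIE_TOL)[0])
            return self.classes_[k], float(w[mask].sum() - totals[k])

        # fallback: no split (constant majority prediction)
        const_label, const_err = majority(np.ones(n, dtype=bool))
        best = (const_err, -1, np.inf, const_label, const_label)
        for j in range(X.shape[1]):
            vals = np.unique(X[:, j])
            for thr in (vals[:-1] + vals[1:]) / 2.0:
                left = X[:, j] <= thr
                llab, lerr = majority(left)
                rlab, rerr = majority(~left)
                err = lerr + rerr
                cand = (err, j, thr, llab, rlab)
                if err < best[0] - _TIE_TOL:
                    best = cand
                elif err < best[0] + _TIE_TOL and (j, thr) < (best[1], best[2]):
                    best = cand
        self.error_, self.feature_, self.threshold_, self.left_, self.right_ = best
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.feature_ < 0:
            return np.full(len(X), self.left_, dtype=self.classes_.dtype)
        left = X[:, self.feature_] <= self.threshold_
        return np.where(left, self.left_, self.right_).astype(self.classes_.dtype)


def _default_tree(random_state):
    return DecisionTreeClassifier(max_depth=1, random_state=random_state)


class _BaseBooster:
    def __init__(self, n_estimators=50, base_estimator=None, learning_rate=1.0,
                 class_balanced_init=False, random_state=None):
        self.n_estimators = n_estimators
        self.base_estimator = base_estimator
        self.learning_rate = learning_rate
        self.class_balanced_init = class_balanced_init
        self.random_state = random_state

    def _setup(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.n_classes_ = len(self.classes_)
        n = len(y)
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.class_balanced_init:
            # inverse class-frequency start instead of the uniform 1/n
            _, inv = np.unique(y, return_inverse=True)
            freq = np.bincount(inv) / n
            w = (1.0 / freq[inv])
            w /= w.sum()
        else:
            w = np.full(n, 1.0 / n)
        self.estimators_ = []
        self.weight_history_ = [w.copy()]
        return X, y, w

    def _weak(self):
        base = self.base_estimator
        if base is None:
            return _default_tree(self.random_state)
        return clone(base)

    def _prep_predict(self, X):
        X = np.asarray(X, dtype=float)
        return X[:, None] if X.ndim == 1 else X


class SAMMEClassifier(_BaseBooster):
    """Multi-class AdaBoost with discrete weak-learner votes."""

    def fit(self, X, y):
        X, y, w = self._setup(X, y)
        self.alphas_ = []
        self.errors_ = []
        K = self.n_classes_
        if K < 2:
            # single observed class: trivial constant classifier
            self.constant_ = self.classes_[0]
            return self
        self.constant_ = None
        for _ in range(self.n_estimators):
            est = self._weak().fit(X, y, sample_weight=w)
            pred = est.predict(X)
            miss = pred != y
            err = float(w[miss].sum())
            if err <= 0.0:
                self.estimators_.append(est)
                self.alphas_.append(_PERFECT_ALPHA)
                self.errors_.append(0.0)
                break
            if err >= 1.0 - 1.0 / K:
                break  # no better than chance: discard round, stop
            alpha = self.learning_rate * (np.log((1.0 - err) / err) + np.log(K - 1.0))
            self.estimators_.append(est)
            self.alphas_.append(alpha)
            self.errors_.append(err)
            w = w * np.exp(alpha * miss)
            w = w / w.sum()
            self.weight_history_.append(w.copy())
        if not self.estimators_ and self.constant_ is None:
            # first round already no better than chance: plurality fallback
            vals, counts = np.unique(y, return_counts=True)
            self.constant_ = vals[np.argmax(counts)]
        return self

    def decision_function(self, X):
        X = self._prep_predict(X)
        votes = np.zeros((len(X), self.n_classes_))
        lookup = {c: k for k, c in enumerate(self.classes_)}
        for est, alpha in zip(self.estimators_, self.alphas_):
            pred = est.predict(X)
            idx = np.fromiter((lookup[p] for p in pred), count=len(pred), dtype=int)
            votes[np.arange(len(X)), idx] += alpha
        return votes

    def predict(self, X):
        X = self._prep_predict(X)
        if self.constant_ is not None:
            return np.full(len(X), self.constant_, dtype=self.classes_.dtype)
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


class SAMMERClassifier(_BaseBooster):
    """Multi-class AdaBoost driven by weighted class-probability estimates."""

    def fit(self, X, y):
        X, y, w = self._setup(X, y)
        K = self.n_classes_
        if K < 2:
            self.constant_ = self.classes_[0]
            return self
        self.constant_ = None
        class_idx = np.searchsorted(self.classes_, y)
        # symmetric class coding: +1 for the true class, -1/(K-1) elsewhere
        Y = np.full((len(y), K), -1.0 / (K - 1.0))
        Y[np.arange(len(y)), class_idx] = 1.0
        for m in range(self.n_estimators):
            est = self._weak().fit(X, y, sample_weight=w)
            logp = self._log_proba(est, X, m)
            w = w * np.exp(-self.learning_rate * ((K - 1.0) / K)
                           * np.sum(Y * logp, axis=1))
            total = w.sum()
            if not np.isfinite(total) or total <= 0:
                raise FloatingPointError(
                    f"sample weights degenerated in boosting round {m + 1}"
                )
            w = w / total
            self.estimators_.append(est)
            self.weight_history_.append(w.copy())
        return self

    def _log_proba(self, est, X, m):
        proba = est.predict_proba(X)
        if proba.shape[1] != self.n_classes_:
            # weak learner dropped a class (zero weight): rebuild full matrix
            full = np.zeros((len(X), self.n_classes_))
            cols = np.searchsorted(self.classes_, est.classes_)
            full[:, cols] = proba
            proba = full
        proba = np.clip(proba, PROB_FLOOR, None)
        logp = np.log(proba)
        if not np.isfinite(logp).all():
            raise FloatingPointError(
                f"non-finite log-probability in boosting round {m + 1}"
            )
        return logp

    def _contribution(self, est, X, m):
        K = self.n_classes_
        logp = self._log_proba(est, X, m)
        return (K - 1.0) * (logp - logp.mean(axis=1, keepdims=True))

    def staged_contributions(self, X):
        """Yield each round's h_k^(m)(x) matrix (n_samples x K)."""
        X = self._prep_predict(X)
        for m, est in enumerate(self.estimators_):
            yield self._contribution(est, X, m)

    def decision_function(self, X):
        X = self._prep_predict(X)
        total = np.zeros((len(X), self.n_classes_))
        for h in self.staged_contributions(X):
            total += h
        return total

    def predict(self, X):
        X = self._prep_predict(X)
        if self.constant_ is not None:
            return np.full(len(X), self.constant_, dtype=self.classes_.dtype)
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]
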