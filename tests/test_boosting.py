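import numpy as np
import pytest
from sklearn.tree import DecisionTreeClassifier

from edsurrogate import DecisionStump, SAMMEClassifier, SAMMERClassifier
from edsurrogate.boosting import PROB_FLOOR


def classic_adaboost_predict(X, y, M, X_query):
    """Independent oracle: textbook two-class discrete AdaBoost.

    The boosting recursion is coded here from scratch (beta = err/(1-err)
    down-weighting of correct points, vote weight log(1/beta)); only the
    weak learner — a deterministic stump — is shared with the package, so
    both sides boost the same hypothesis class.  Degenerate-round
    conventions match the documented ones: a zero-error round gets vote
    weight log(1e10) and stops; err >= 0.5 discards the round and stops.
    """
    X = np.asarray(X, float).reshape(len(y), -1)
    y = np.asarray(y)
    classes = np.unique(y)
    n = len(y)
    w = np.full(n, 1.0 / n)
    ests, alphas = [], []
    for _ in range(M):
        t = DecisionStump()
        t.fit(X, y, sample_weight=w)
        miss = t.predict(X) != y
        err = float(w[miss].sum())
        if err <= 0.0:
            ests.append(t)
            alphas.append(np.log(1e10))
            break
        if err >= 0.5:
            break
        beta = err / (1.0 - err)
        ests.append(t)
        alphas.append(np.log(1.0 / beta))
        w = np.where(miss, w, w * beta)
        w = w / w.sum()
    Xq = np.asarray(X_query, float).reshape(-1, X.shape[1])
    if not ests:
        vals, counts = np.unique(y, return_counts=True)
        return np.full(len(Xq), vals[np.argmax(counts)])
    votes = np.zeros((len(Xq), len(classes)))
    for t, a in zip(ests, alphas):
        pred = t.predict(Xq)
        for k, c in enumerate(classes):
            votes[:, k] += a * (pred == c)
    return classes[np.argmax(votes, axis=1)]


X8 = np.arange(8.0).reshape(-1, 1)


def test_two_class_alpha_drops_the_log_k_term():
    # K=2: alpha = log((1-err)/err) exactly, as in classical AdaBoost
    X = np.arange(6.0).reshape(-1, 1)
    y = np.array(["A", "A", "B", "B", "B", "A"])  # x=5 mislabeled
    clf = SAMMEClassifier(n_estimators=1, random_state=0).fit(X, y)
    assert clf.errors_[0] == pytest.approx(1 / 6)
    assert clf.alphas_[0] == pytest.approx(np.log(5.0))


def test_weight_update_hand_computed():
    # after round 1 the single misclassified point holds half the mass
    X = np.arange(6.0).reshape(-1, 1)
    y = np.array(["A", "A", "B", "B", "B", "A"])
    clf = SAMMEClassifier(n_estimators=2, random_state=0).fit(X, y)
    w1 = clf.weight_history_[1]
    assert w1[5] == pytest.approx(0.5)
    assert w1[:5] == pytest.approx(np.full(5, 0.1))


def test_separable_data_early_stops_and_fits():
    X = np.array([0.0, 1.0, 2.0, 3.0]).reshape(-1, 1)
    y = np.array(["A", "A", "B", "B"])
    clf = SAMMEClassifier(n_estimators=5, random_state=0).fit(X, y)
    assert len(clf.estimators_) == 1
    assert clf.errors_ == [0.0]
    assert (clf.predict(X) == y).all()


@pytest.mark.parametrize("labels", [
    "AABBBABA", "ABABABAB", "AAAABBBB", "BBAABBAA",
])
def test_samme_two_class_matches_classical_adaboost(labels):
    y = np.array(list(labels))
    clf = SAMMEClassifier(n_estimators=3, base_estimator=DecisionStump()).fit(X8, y)
    assert (clf.predict(X8) == classic_adaboost_predict(X8, y, 3, X8)).all()


def test_stump_minimizes_weighted_error():
    # brute-force check over every (threshold, side-labeling) on 6 points
    r = np.random.default_rng(5)
    X = np.arange(6.0).reshape(-1, 1)
    y = np.array(list("ABABBA"))
    w = r.uniform(0.1, 1.0, size=6)
    w /= w.sum()
    s = DecisionStump().fit(X, y, sample_weight=w)
    best = min(
        sum(wi for xi, yi, wi in zip(X[:, 0], y, w)
            if (yi != (ll if xi <= thr else rl)))
        for thr in np.arange(0.5, 6.0)
        for ll in "AB" for rl in "AB"
    )
    assert s.error_ == pytest.approx(best)
    assert np.mean(w * (s.predict(X) != y)) <= best / 6 + 1e-12


def test_weights_remain_distribution_every_round():
    r = np.random.default_rng(0)
    X = r.normal(size=(40, 2))
    y = np.where(X[:, 0] + r.normal(scale=0.5, size=40) > 0, "u", "v")
    for cls in (SAMMEClassifier, SAMMERClassifier):
        clf = cls(n_estimators=8, random_state=0).fit(X, y)
        for w in clf.weight_history_:
            assert w.sum() == pytest.approx(1.0)
            assert (w >= 0).all()


def test_more_rounds_never_hurt_training_on_separable_data():
    r = np.random.default_rng(3)
    X = r.normal(size=(30, 2))
    y = np.where(X[:, 0] > 0, "a", "b")  # separable by one stump
    errs = []
    for M in (1, 2, 4, 8):
        clf = SAMMEClassifier(n_estimators=M, random_state=0).fit(X, y)
        errs.append(np.mean(clf.predict(X) != y))
    assert all(a >= b for a, b in zip(errs, errs[1:]))


def test_sammer_contributions_sum_to_zero():
    r = np.random.default_rng(1)
    X = r.normal(size=(12, 1))
    y = np.array(list("abc") * 4)
    clf = SAMMERClassifier(n_estimators=4, random_state=0).fit(X, y)
    for h in clf.staged_contributions(X):
        assert np.allclose(h.sum(axis=1), 0.0, atol=1e-9)


def test_sammer_one_hot_probabilities_fit_separable_set():
    X = np.array([0, 1, 2, 3.0]).reshape(-1, 1)
    y = np.array(["A", "A", "B", "B"])
    clf = SAMMERClassifier(n_estimators=1, random_state=0).fit(X, y)
    assert (clf.predict(X) == y).all()


def test_sammer_matches_stepwise_manual_execution():
    """Two rounds on a K=3 toy set, checked against an independently coded
    step-by-step run of the probability-based update."""
    X = np.array([0, 1, 2, 3, 4, 5, 6, 7.0]).reshape(-1, 1)
    y = np.array(["a", "a", "a", "b", "b", "c", "c", "c"])
    K = 3
    classes = np.unique(y)
    Y = np.full((8, K), -1.0 / (K - 1))
    Y[np.arange(8), np.searchsorted(classes, y)] = 1.0
    w = np.full(8, 1 / 8)
    H = np.zeros((8, K))
    for _ in range(2):
        t = DecisionTreeClassifier(max_depth=1, random_state=0)
        t.fit(X, y, sample_weight=w)
        p = np.clip(t.predict_proba(X), PROB_FLOOR, None)
        logp = np.log(p)
        H += (K - 1) * (logp - logp.mean(axis=1, keepdims=True))
        w = w * np.exp(-((K - 1) / K) * np.sum(Y * logp, axis=1))
        w = w / w.sum()
    expected = classes[np.argmax(H, axis=1)]

    clf = SAMMERClassifier(n_estimators=2, random_state=0).fit(X, y)
    assert (clf.predict(X) == expected).all()
    assert np.allclose(clf.decision_function(X), H)
    assert np.allclose(clf.weight_history_[-1], w)


def test_single_class_degenerates_to_constant():
    X = np.arange(4.0)
    y = np.array(["z"] * 4)
    for cls in (SAMMEClassifier, SAMMERClassifier):
        clf = cls(n_estimators=3).fit(X, y)
        assert (clf.predict([[0.5], [9.0]]) == "z").all()


def test_class_balanced_initial_weights():
    X = np.arange(6.0)
    y = np.array(["a", "a", "a", "a", "b", "b"])
    clf = SAMMEClassifier(n_estimators=1, class_balanced_init=True,
                          random_state=0).fit(X, y)
    w0 = clf.weight_history_[0]
    assert w0[:4].sum() == pytest.approx(0.5)
    assert w0[4:].sum() == pytest.approx(0.5)
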