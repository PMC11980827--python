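"""Classifier training, RAPS conformal sets, and the temporal solver."""

import numpy as np
import pytest
from sklearn.datasets import make_blobs

from myodecode import (
    ClassifierConfig,
    ConformalCalibrator,
    PredictionSet,
    SolverState,
    calibrate_raps,
    predict_set,
    predict_stream,
    raps_scores,
    temporal_solve,
    train_classifier,
)
from myodecode.decode import FrameClassifier


class OneHotModel:
    """Stub model that is perfectly confident and always right."""

    def __init__(self, n_classes=4):
        self.classes_ = np.arange(n_classes)

    def predict_proba(self, X):
        P = np.zeros((len(X), len(self.classes_)))
        P[np.arange(len(X)), np.asarray(X, dtype=int)[:, 0]] = 1.0
        return P


def blob_problem(seed, n=600, n_classes=4, cluster_std=1.0):
    X, y = make_blobs(n_samples=n, centers=n_classes, n_features=8,
                      cluster_std=cluster_std, random_state=seed)
    return X, y


class TestClassifier:
    def test_separable_problem_high_heldout_accuracy(self):
        X, y = blob_problem(0, cluster_std=0.5)
        model = train_classifier(X[:400], y[:400],
                                 ClassifierConfig(backend="logistic"))
        assert np.mean(model.predict(X[400:]) == y[400:]) >= 0.95

    def test_permuted_labels_fall_to_chance(self, rng):
        X, y = blob_problem(1, n=2000, cluster_std=0.5)
        y_perm = rng.permutation(y)
        model = train_classifier(X[:1500], y_perm[:1500],
                                 ClassifierConfig(backend="logistic"))
        acc = np.mean(model.predict(X[1500:]) == y_perm[1500:])
        # chance is 0.25; allow a generous binomial band around it
        assert abs(acc - 0.25) < 0.08

    def test_probabilities_sum_to_one(self, rng):
        X, y = blob_problem(2)
        model = train_classifier(X, y, ClassifierConfig(backend="logistic"))
        P = model.predict_proba(rng.normal(size=(1000, 8)))
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            train_classifier(np.zeros((10, 3)), np.zeros(10))

    def test_gbt_backend_deterministic_under_seed(self):
        X, y = blob_problem(3, n=300)
        cfg = ClassifierConfig(n_iterations=20, rng_seed=9)
        P1 = train_classifier(X, y, cfg).predict_proba(X)
        P2 = train_classifier(X, y, cfg).predict_proba(X)
        np.testing.assert_array_equal(P1, P2)

    def test_unknown_backend_rejected(self):
        with pytest.raises(ValueError, match="backend"):
            train_classifier(np.zeros((10, 3)), np.arange(10) % 2,
                             ClassifierConfig(backend="svm"))


class TestRapsCalibration:
    def test_confident_correct_model_scores_one_and_singletons(self):
        model = OneHotModel()
        X = np.arange(4).repeat(30)[:, None]
        y = X[:, 0]
        cal = calibrate_raps(model, X, y, alpha=0.1)
        scores = raps_scores(model.predict_proba(X), y, model.classes_,
                             cal.lam, cal.k_reg)
        np.testing.assert_allclose(scores, 1.0)
        s = predict_set(cal, model.predict_proba(X[:1])[0])
        assert len(s) == 1 and s.top == y[0]

    def test_alpha_to_zero_grows_sets_toward_all_classes(self):
        rng = np.random.default_rng(4)
        probs_cal = rng.dirichlet(np.ones(4), size=400)
        y = np.array([rng.choice(4, p=p) for p in probs_cal])

        class Stub:
            classes_ = np.arange(4)
            def __init__(self, P): self.P = P
            def predict_proba(self, X): return self.P[:len(X)]

        test_prob = np.array([0.4, 0.3, 0.2, 0.1])
        sizes = []
        for alpha in (0.5, 0.1, 0.01, 0.001):
            cal = calibrate_raps(Stub(probs_cal), np.zeros((400, 1)), y,
                                 alpha=alpha, lam=0.0)
            sizes.append(len(predict_set(cal, test_prob)))
        assert sizes == sorted(sizes)
        assert sizes[-1] == 4  # alpha -> 0: qhat -> max score, full set

    def test_small_calibration_set_warns(self):
        model = OneHotModel()
        X = np.arange(4).repeat(2)[:, None]
        with pytest.warns(UserWarning, match="small"):
            calibrate_raps(model, X, X[:, 0], alpha=0.1)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            ConformalCalibrator(alpha=1.5)


class TestPredictionSets:
    @staticmethod
    def brute_force_set(probs, qhat, lam, k_reg):
        """Enumerate the inclusion rule directly."""
        order = np.argsort(-np.asarray(probs), kind="stable")
        included = []
        cum = 0.0
        for j, cls in enumerate(order, start=1):
            cum += probs[cls]
            if cum + lam * max(0, j - k_reg) <= qhat:
                included.append(cls)
            else:
                break
        return included or [order[0]]

    def test_matches_bruteforce_inclusion_rule(self, rng):
        for _ in range(200):
            p = rng.dirichlet(np.ones(5))
            qhat = float(rng.uniform(0.1, 1.1))
            lam = float(rng.choice([0.0, 0.01, 0.1]))
            cal = ConformalCalibrator(alpha=0.1, lam=lam, k_reg=1,
                                      classes_=np.arange(5), qhat=qhat)
            got = predict_set(cal, p).classes.tolist()
            assert got == self.brute_force_set(p, qhat, lam, 1)

    def test_high_qhat_includes_both_of_two_classes(self):
        cal = ConformalCalibrator(lam=0.0, classes_=np.array([0, 1]), qhat=1.0)
        s = predict_set(cal, np.array([0.9, 0.1]))
        assert sorted(s.classes.tolist()) == [0, 1]

    def test_never_empty_even_with_tiny_qhat(self, rng):
        cal = ConformalCalibrator(classes_=np.arange(4), qhat=1e-9)
        for _ in range(50):
            s = predict_set(cal, rng.dirichlet(np.ones(4)))
            assert len(s) >= 1

    def test_unfitted_calibrator_rejected(self):
        cal = ConformalCalibrator(classes_=np.arange(3))
        with pytest.raises(ValueError, match="not been fitted"):
            predict_set(cal, np.array([0.5, 0.3, 0.2]))


def make_set(classes, probs=None):
    classes = np.asarray(classes)
    probs = np.linspace(0.6, 0.1, len(classes)) if probs is None \
        else np.asarray(probs)
    return PredictionSet(classes=classes, probs=probs)


class TestTemporalSolver:
    def test_singleton_stream_passes_through(self):
        state = SolverState()
        for _ in range(100):
            assert temporal_solve(state, make_set(["A"])) == "A"

    def test_majority_over_history_resolves_uncertain_set(self):
        state = SolverState()
        for _ in range(74):
            temporal_solve(state, make_set(["A"]))
        out = temporal_solve(state, make_set(["A", "B"]))
        assert out == "A"  # tally A:75, B:1

    def test_cold_start_uncertain_set_uses_top_probability(self):
        state = SolverState()
        out = temporal_solve(state, make_set(["B", "A"], probs=[0.6, 0.4]))
        assert out == "B"

    def test_tie_keeps_previous_output(self):
        state = SolverState(history_len=4)
        temporal_solve(state, make_set(["A"]))
        temporal_solve(state, make_set(["B"]))
        # history {A}, {B}, now {A,B}: tally A:2 B:2 -> keep last output B
        assert temporal_solve(state, make_set(["A", "B"])) == "B"

    def test_history_capped_at_75(self):
        state = SolverState()
        for _ in range(200):
            temporal_solve(state, make_set(["A"]))
        assert len(state.history) == 75

    def test_no_extra_lag_when_certain(self):
        """A sustained switch to a new certain class shows up immediately."""
        state = SolverState()
        for _ in range(75):
            temporal_solve(state, make_set(["A"]))
        assert temporal_solve(state, make_set(["B"])) == "B"


class TestPredictStream:
    def _fitted(self, seed=0):
        X, y = blob_problem(seed, n=1200, cluster_std=1.5)
        model = train_classifier(X[:600], y[:600],
                                 ClassifierConfig(backend="logistic"))
        cal = calibrate_raps(model, X[600:900], y[600:900], alpha=0.1)
        return model, cal, X[900:], y[900:]

    def test_outputs_aligned_and_deterministic(self):
        model, cal, X, _ = self._fitted()
        n1, c1, s1 = predict_stream(model, cal, SolverState(), X)
        n2, c2, _ = predict_stream(model, cal, SolverState(), X)
        assert len(n1) == len(c1) == len(X)
        np.testing.assert_array_equal(n1, n2)
        np.testing.assert_array_equal(c1, c2)

    def test_conformal_equals_naive_when_all_sets_singleton(self):
        model, cal, X, _ = self._fitted()
        naive, conformal, sets = predict_stream(model, cal, SolverState(), X)
        singleton = np.array([len(s) == 1 for s in sets])
        np.testing.assert_array_equal(naive[singleton], conformal[singleton])

    def test_unfitted_calibrator_rejected(self):
        model, _, X, _ = self._fitted()
        with pytest.raises(ValueError):
            predict_stream(model, ConformalCalibrator(), SolverState(), X)


class TestCoverageProperty:
    def test_marginal_coverage_on_exchangeable_data(self):
        """Split-conformal coverage >= 1 - alpha within Monte-Carlo error."""
        alpha = 0.1
        for seed in (0, 1, 2):
            X, y = blob_problem(seed, n=2400, cluster_std=3.0)
            model = train_classifier(X[:800], y[:800],
                                     ClassifierConfig(backend="logistic"))
            cal = calibrate_raps(model, X[800:1600], y[800:1600], alpha=alpha)
            P = model.predict_proba(X[1600:])
            covered = [y[1600 + i] in predict_set(cal, P[i])
                       for i in range(len(P))]
            n = len(covered)
            sd = np.sqrt(alpha * (1 - alpha) / n)
            assert np.mean(covered) >= 1 - alpha - 2 * sd
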