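"""Classification with uncertainty-aware conformal prediction.

The decoder is a probabilistic multiclass classifier (gradient-boosted
trees by default, any scikit-learn-style estimator pluggable) wrapped in
split conformal prediction using regularized adaptive prediction sets
(RAPS).  For a frame with sorted class probabilities p_(1) >= p_(2) >= ...,
the nonconformity score of the class at rank j is

    s_j = p_(1) + ... + p_(j) + lambda * max(0, j - k_reg)

i.e. the cumulative probability mass through that class plus a rank
penalty that discourages large sets.  Calibration computes the scores of
the true classes on held-out data and takes qhat as the
ceil((n+1)(1-alpha))/n empirical quantile; at prediction time the set
contains every class whose score is <= qhat, and always at least the
top-1 class, so sets are never empty.  Under exchangeability the set
covers the true class with probability at least 1 - alpha.

A set of size one is treated as a *certain* prediction.  Uncertain
(multi-class) sets are resolved by a temporal solver that tallies class
occurrences over the last 75 prediction sets and outputs the most
frequent class, which trades a little reaction speed for control
stability — the output holds its state until a clear new intent emerges.
"""

from __future__ import annotations

import warnings
from collections import Counter, deque
from dataclasses import dataclass, field
from math import ceil
from typing import Iterable, Sequence

import numpy as np

HISTORY_LEN = 75


@dataclass(frozen=True)
class ClassifierConfig:
    """Backend selection for the frame classifier.

    ``gradient_boosted_trees`` (LightGBM, 1000 boosting iterations) is the
    default; ``logistic`` is a fast linear alternative useful for quick
    experiments.  Any object with fit/predict_proba can be passed to
    :func:`train_classifier` directly via ``estimator``.
    """

    backend: str = "gradient_boosted_trees"
    n_iterations: int = 1000
    rng_seed: int = 0
    learning_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.n_iterations <= 0:
            raise ValueError("n_iterations must be positive")


class FrameClassifier:
    """Thin wrapper giving a stable predict_proba surface over any backend."""

    def __init__(self, estimator, classes: np.ndarray):
        self._est = estimator
        self.classes_ = np.asarray(classes)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        with warnings.catch_warnings():
            # LightGBM's sklearn wrapper warns about feature names even
            # when both fit and predict receive plain arrays
            warnings.filterwarnings("ignore", message=".*feature names.*")
            P = np.asarray(self._est.predict_proba(np.asarray(X, dtype=float)))
        return P

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def _make_estimator(cfg: ClassifierConfig):
    if cfg.backend == "gradient_boosted_trees":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            n_estimators=cfg.n_iterations,
            learning_rate=cfg.learning_rate,
            random_state=cfg.rng_seed,
            deterministic=True,
            force_row_wise=True,
            n_jobs=1,
            verbosity=-1,
        )
    if cfg.backend == "logistic":
        from sklearn.linear_model import LogisticRegression

        return LogisticRegression(max_iter=2000, random_state=cfg.rng_seed)
    raise ValueError(f"unknown classifier backend {cfg.backend!r}")


def train_classifier(X: np.ndarray, y: np.ndarray,
                     cfg: ClassifierConfig | None = None,
                     estimator=None) -> FrameClassifier:
    """Fit the per-participant frame classifier on z-scored features.

    Requires at least two classes; returns a model whose predict_proba
    rows sum to one and that is deterministic under a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain at least 2 classes")
    if estimator is None:
        estimator = _make_estimator(cfg or ClassifierConfig())
    estimator.fit(X, y)
    return FrameClassifier(estimator, getattr(estimator, "classes_", classes))


# ---------------------------------------------------------------------------
# RAPS conformal calibration
# ---------------------------------------------------------------------------

@dataclass
class PredictionSet:
    """Candidate classes for one frame, in descending-probability order."""

    classes: np.ndarray
    probs: np.ndarray

    def __len__(self) -> int:
        return len(self.classes)

    def __contains__(self, cls) -> bool:
        return cls in self.classes

    @property
    def is_certain(self) -> bool:
        return len(self.classes) == 1

    @property
    def top(self):
        return self.classes[0]


@dataclass
class ConformalCalibrator:
    """RAPS calibrator: miscoverage level, penalty and calibrated quantile."""

    alpha: float = 0.1
    lam: float = 0.01
    k_reg: int = 1
    classes_: np.ndarray | None = None
    qhat: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.k_reg < 0:
            raise ValueError("k_reg must be non-negative")


def raps_scores(probs: np.ndarray, y: np.ndarray, classes: np.ndarray,
                lam: float, k_reg: int) -> np.ndarray:
    """Nonconformity score of the true class for each row of probabilities.

    Classes are sorted by descending probability (stable, so ties break by
    class order, deterministically); the score is the cumulative mass
    through the true class plus lam * max(0, rank - k_reg) with rank
    counted from 1.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    y = np.asarray(y)
    class_index = {c: i for i, c in enumerate(classes)}
    order = np.argsort(-probs, axis=1, kind="stable")
    scores = np.empty(probs.shape[0])
    for i in range(probs.shape[0]):
        o = order[i]
        cum = np.cumsum(probs[i, o])
        rank = int(np.flatnonzero(o == class_index[y[i]])[0]) + 1
        scores[i] = cum[rank - 1] + lam * max(0, rank - k_reg)
    return scores


def calibrate_raps(model: FrameClassifier, X_cal: np.ndarray, y_cal: np.ndarray,
                   alpha: float = 0.1, lam: float = 0.01,
                   k_reg: int = 1) -> ConformalCalibrator:
    """Split-conformal calibration on data disjoint from training.

    qhat is the ceil((n+1)(1-alpha))-th smallest calibration score
    (clipped to the maximum when (n+1)(1-alpha) exceeds n, the small-n /
    small-alpha regime where the guarantee needs the whole support).
    """
    cal = ConformalCalibrator(alpha=alpha, lam=lam, k_reg=k_reg,
                              classes_=model.classes_)
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal)
    n = len(y_cal)
    if n == 0:
        raise ValueError("empty calibration set")
    if n < 10 / alpha:
        warnings.warn(
            f"calibration set of {n} examples is small for alpha={alpha}; "
            "the quantile estimate is unstable", stacklevel=2)
    scores = raps_scores(model.predict_proba(X_cal), y_cal, model.classes_,
                         lam, k_reg)
    k = min(ceil((n + 1) * (1 - alpha)), n)
    cal.qhat = float(np.sort(scores)[k - 1])
    return cal


def predict_set(cal: ConformalCalibrator, probs: np.ndarray) -> PredictionSet:
    """Build the RAPS prediction set for one probability vector.

    Includes classes in descending-probability order while the running
    score (cumulative mass plus rank penalty) stays <= qhat; the top-1
    class is always included, so the set is never empty.
    """
    if cal.qhat is None:
        raise ValueError("calibrator has not been fitted")
    p = np.asarray(probs, dtype=float).ravel()
    order = np.argsort(-p, kind="stable")
    cum = np.cumsum(p[order])
    ranks = np.arange(1, p.size + 1)
    scores = cum + cal.lam * np.maximum(0, ranks - cal.k_reg)
    k = int(np.searchsorted(scores > cal.qhat, True))  # first rank exceeding qhat
    k = max(1, k)  # never empty
    sel = order[:k]
    classes = cal.classes_ if cal.classes_ is not None else np.arange(p.size)
    return PredictionSet(classes=np.asarray(classes)[sel], probs=p[sel])


# ---------------------------------------------------------------------------
# Temporal uncertainty solver
# ---------------------------------------------------------------------------

@dataclass
class SolverState:
    """Rolling memory of the last 75 prediction sets and the last output."""

    history_len: int = HISTORY_LEN
    history: deque = field(default_factory=lambda: deque(maxlen=HISTORY_LEN))
    last_output: object | None = None

    def __post_init__(self) -> None:
        if self.history.maxlen != self.history_len:
            self.history = deque(self.history, maxlen=self.history_len)


def temporal_solve(state: SolverState, s: PredictionSet):
    """Resolve one prediction set to a single class.

    A singleton set is certain and passes straight through.  An uncertain
    set is resolved by counting each class's occurrences across the last
    75 sets (the incoming set included) and emitting the most frequent
    class; a tie keeps the previous output (state holding beats
    switching), and on a cold start with no previous output the set's
    top-probability member is used.
    """
    state.history.append(s)
    if s.is_certain:
        out = s.top
    else:
        counts = Counter()
        for past in state.history:
            counts.update(past.classes.tolist())
        best = max(counts.values())
        winners = {c for c, n in counts.items() if n == best}
        if len(winners) == 1:
            out = next(iter(winners))
        elif state.last_output is not None:
            out = state.last_output
        else:
            out = s.top
    state.last_output = out
    return out


def predict_stream(model: FrameClassifier, cal: ConformalCalibrator,
                   solver: SolverState, X: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, list[PredictionSet]]:
    """Decode a stream of feature frames two ways.

    Returns per-frame naive predictions (argmax class), conformal
    predictions (temporal-solved RAPS sets) and the sets themselves.
    """
    if cal.qhat is None:
        raise ValueError("calibrator has not been fitted")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    P = model.predict_proba(X)
    naive = model.classes_[np.argmax(P, axis=1)]
    sets = [predict_set(cal, P[i]) for i in range(P.shape[0])]
    conformal = np.array([temporal_solve(solver, s) for s in sets])
    return naive, conformal, sets
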