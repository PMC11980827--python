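"""Labeling, session management, splitting and normalization.

Recordings pair each feature frame with the guide-hand state it was
collected under.  Because involuntary (non-task-modulated) motor-unit
activity can linger after a movement, every movement recording is split
into an *active* state and a *rest* state by thresholding the guide
activation at 50% of full flexion: frames at or above the threshold get
the movement's class, everything below becomes rest.  With the default
sinusoidal guide (symmetric cycles), three 30-s recordings therefore
yield 45 s of rest and 15 s of active data per movement.

Splits are chronological, never shuffled: streamed EMG features are
strongly autocorrelated and the decoder is validated on temporally later
data.  Normalization statistics come from the training partition only and
are applied unchanged to test and real-time data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import FeatureFrame
from .simulate import Movement, MovementTemplate, template_for

REST_CLASS = 0
DEFAULT_THRESHOLD = 0.5
SD_FLOOR = 1e-8


@dataclass(frozen=True)
class LabeledExample:
    """One classifier example: 32 RMS features and an integer class.

    ``class_id`` 0 is rest; 1..M index the movements of the class map.
    ``source_movement`` records which recording the frame came from,
    which is not the same thing as its class (sub-threshold frames of a
    grasp recording are labeled rest but still originate from grasp).
    """

    features: np.ndarray
    class_id: int
    source_movement: Movement
    t_end: float


def activation_of(state: np.ndarray, template: MovementTemplate) -> float:
    """Scalar movement activation of a 9D state under a movement template.

    The maximum over the template's driven (nonzero-target) components;
    multi-digit movements like grasp or the pinches thus reduce to one
    scalar while preserving the 50%-of-full-flexion semantics.  Rest has
    no driven components and always reads 0.
    """
    driven = template.driven_components
    if driven.size == 0:
        return 0.0
    return float(np.max(np.asarray(state, dtype=float)[driven]))


def assign_class(frame: FeatureFrame, movement: Movement | MovementTemplate,
                 class_id: int, threshold: float = DEFAULT_THRESHOLD) -> LabeledExample:
    """Label one frame from a recording of ``movement``.

    The frame gets the movement's class when the guide activation is at
    or above the threshold (boundary inclusive), rest otherwise.  Frames
    from a rest recording are always rest.
    """
    template = movement if isinstance(movement, MovementTemplate) \
        else template_for(movement)
    a = activation_of(frame.label_state, template)
    cls = class_id if a >= threshold else REST_CLASS
    return LabeledExample(features=frame.rms, class_id=cls,
                          source_movement=template.movement_id, t_end=frame.t_end)


def label_recording(frames: list[FeatureFrame], movement: Movement | MovementTemplate,
                    class_id: int,
                    threshold: float = DEFAULT_THRESHOLD) -> list[LabeledExample]:
    """Apply the threshold rule to every frame of one recording."""
    return [assign_class(f, movement, class_id, threshold) for f in frames]


def active_mask(states: np.ndarray, template: MovementTemplate,
                threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Boolean active/rest mask for raw guide states (n, 9).

    Useful for frame-rate-level accounting of labeled durations and for
    ground truth during validation replays.
    """
    states = np.asarray(states, dtype=float)
    driven = template.driven_components
    if driven.size == 0:
        return np.zeros(states.shape[0], dtype=bool)
    return states[:, driven].max(axis=1) >= threshold


# ---------------------------------------------------------------------------
# Sessions
# ---------------------------------------------------------------------------

@dataclass
class Session:
    """One recorded (or simulated) movement session with its frames."""

    session_id: str
    movement: Movement
    frames: list[FeatureFrame] = field(default_factory=list)


class SessionStore:
    """Mutable collection of sessions backing an experiment's dataset.

    Sessions can be appended, removed and re-recorded (an atomic
    remove+append that must preserve the movement identity), so a bad
    recording never forces restarting the experiment.
    """

    def __init__(self) -> None:
        self._sessions: dict[str, Session] = {}

    def __len__(self) -> int:
        return len(self._sessions)

    def __contains__(self, session_id: str) -> bool:
        return session_id in self._sessions

    @property
    def sessions(self) -> list[Session]:
        return list(self._sessions.values())

    def append(self, session: Session) -> None:
        if session.session_id in self._sessions:
            raise ValueError(f"session {session.session_id!r} already present")
        self._sessions[session.session_id] = session

    def remove(self, session_id: str) -> Session:
        if session_id not in self._sessions:
            raise KeyError(f"unknown session {session_id!r}")
        return self._sessions.pop(session_id)

    def rerecord(self, session: Session) -> None:
        old = self._sessions.get(session.session_id)
        if old is None:
            raise KeyError(f"unknown session {session.session_id!r}")
        if old.movement != session.movement:
            raise ValueError(
                f"rerecord movement mismatch: {old.movement} -> {session.movement}"
            )
        self._sessions[session.session_id] = session

    def class_counts(self, class_map: dict[Movement, int],
                     threshold: float = DEFAULT_THRESHOLD) -> dict[int, int]:
        counts: dict[int, int] = {}
        for rec in self.labeled(class_map, threshold):
            for ex in rec:
                counts[ex.class_id] = counts.get(ex.class_id, 0) + 1
        return counts

    def labeled(self, class_map: dict[Movement, int],
                threshold: float = DEFAULT_THRESHOLD) -> list[list[LabeledExample]]:
        """Labeled examples grouped per session, in session order."""
        out = []
        for s in self._sessions.values():
            cls = class_map.get(s.movement, REST_CLASS)
            out.append(label_recording(s.frames, s.movement, cls, threshold))
        return out


def default_class_map(movements: list[Movement | str]) -> dict[Movement, int]:
    """Class ids 1..M for the given movements; rest is always class 0."""
    cmap = {Movement.REST: REST_CLASS}
    nxt = 1
    for m in movements:
        m = Movement(m)
        if m == Movement.REST or m in cmap:
            continue
        cmap[m] = nxt
        nxt += 1
    return cmap


# ---------------------------------------------------------------------------
# Split and normalization
# ---------------------------------------------------------------------------

def split_sessions(examples_per_recording: list[list[LabeledExample]],
                   train_fraction: float = 0.8
                   ) -> tuple[list[LabeledExample], list[LabeledExample]]:
    """Chronological split, per recording: first 80% train, last 20% test."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if not examples_per_recording or all(not r for r in examples_per_recording):
        raise ValueError("no examples to split")
    train: list[LabeledExample] = []
    test: list[LabeledExample] = []
    for rec in examples_per_recording:
        k = int(len(rec) * train_fraction)
        train.extend(rec[:k])
        test.extend(rec[k:])
    counts: dict[int, int] = {}
    for ex in train:
        counts[ex.class_id] = counts.get(ex.class_id, 0) + 1
    thin = [c for c, n in counts.items() if n < 5]
    if thin:
        warnings.warn(f"classes {thin} have fewer than 5 training examples",
                      stacklevel=2)
    return train, test


def as_arrays(examples: list[LabeledExample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack examples into (X, y) arrays for model fitting."""
    if not examples:
        raise ValueError("no examples")
    X = np.stack([e.features for e in examples])
    y = np.array([e.class_id for e in examples], dtype=int)
    return X, y


@dataclass(frozen=True)
class NormalizationStats:
    """Per-feature z-scoring statistics, fitted on the training split only."""

    mean: np.ndarray
    sd: np.ndarray


def fit_normalizer(train: list[LabeledExample] | np.ndarray) -> NormalizationStats:
    """Mean and SD over the training features; SD floored to stay finite.

    A dead electrode yields a (near-)constant feature; its SD is floored
    at a tiny epsilon and a warning emitted rather than producing NaN.
    """
    X = train if isinstance(train, np.ndarray) else as_arrays(train)[0]
    if X.size == 0:
        raise ValueError("empty training set")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd < SD_FLOOR):
        warnings.warn(
            f"{int(np.sum(sd < SD_FLOOR))} constant feature(s); SD floored "
            f"at {SD_FLOOR} (dead electrode?)", stacklevel=2)
    return NormalizationStats(mean=mean, sd=np.maximum(sd, SD_FLOOR))


def apply_normalizer(stats: NormalizationStats, features: np.ndarray) -> np.ndarray:
    """Stateless z-score transform using frozen training statistics."""
    return (np.asarray(features, dtype=float) - stats.mean) / stats.sd
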