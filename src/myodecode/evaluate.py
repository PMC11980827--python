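"""Replay scoring: frame-wise accuracy, confusion, stability.

Validation replays are scored frame by frame over the whole replay,
rest between repetitions included (rest misclassifications count against
accuracy).  Per-movement accuracy is the fraction of that movement's
frames decoded correctly; the overall figure is the mean +- SD *across
movements* (not across frames), matching how per-participant accuracies
are conventionally summarised.  Both the naive (argmax) and the
conformal (uncertainty-solved) scheme are reported side by side, along
with output transition counts — a stability measure: fewer spurious
state switches means steadier control — and the prediction-set size
histogram.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix

from .decode import PredictionSet
from .simulate import Movement, MovementTemplate, TrajectoryConfig


@dataclass
class SchemeReport:
    """Metrics of one decoding scheme (naive or conformal)."""

    per_class_accuracy: dict[int, float]
    overall_mean: float
    overall_sd: float
    confusion: np.ndarray
    n_transitions: int


@dataclass
class EvalReport:
    """Side-by-side evaluation of naive and conformal decoding."""

    classes: list[int]
    class_names: dict[int, str]
    n_frames: int
    naive: SchemeReport
    conformal: SchemeReport
    set_size_hist: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def scheme(r: SchemeReport) -> dict:
            return {
                "per_class_accuracy": {str(k): v for k, v in
                                       r.per_class_accuracy.items()},
                "overall_mean": r.overall_mean,
                "overall_sd": r.overall_sd,
                "confusion": r.confusion.tolist(),
                "n_transitions": r.n_transitions,
            }
        return {
            "classes": self.classes,
            "class_names": {str(k): v for k, v in self.class_names.items()},
            "n_frames": self.n_frames,
            "naive": scheme(self.naive),
            "conformal": scheme(self.conformal),
            "set_size_hist": {str(k): v for k, v in self.set_size_hist.items()},
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def to_table(self) -> str:
        """Human-readable accuracy table, conformal with naive in parentheses."""
        lines = [f"{'class':<14}{'conformal':>12}{'naive':>12}"]
        for c in self.classes:
            name = self.class_names.get(c, str(c))
            lines.append(
                f"{name:<14}{self.conformal.per_class_accuracy[c]:>11.1%} "
                f"({self.naive.per_class_accuracy[c]:.1%})"
            )
        lines.append(
            f"{'overall':<14}"
            f"{self.conformal.overall_mean:>7.1%} +- {self.conformal.overall_sd:.1%} "
            f"({self.naive.overall_mean:.1%} +- {self.naive.overall_sd:.1%})"
        )
        lines.append(f"transitions   conformal {self.conformal.n_transitions}, "
                     f"naive {self.naive.n_transitions}")
        return "\n".join(lines)


def count_transitions(preds: np.ndarray) -> int:
    """Number of output state switches along a prediction sequence."""
    preds = np.asarray(preds)
    if preds.size < 2:
        return 0
    return int(np.sum(preds[1:] != preds[:-1]))


def _scheme_report(truth: np.ndarray, preds: np.ndarray,
                   classes: list[int]) -> SchemeReport:
    cm = confusion_matrix(truth, preds, labels=classes)
    row_sums = cm.sum(axis=1)
    acc = {}
    for i, c in enumerate(classes):
        acc[c] = float(cm[i, i] / row_sums[i]) if row_sums[i] else float("nan")
    present = [c for i, c in enumerate(classes) if row_sums[i]]
    vals = np.array([acc[c] for c in present])
    return SchemeReport(
        per_class_accuracy=acc,
        overall_mean=float(vals.mean()) if vals.size else float("nan"),
        overall_sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        confusion=cm,
        n_transitions=count_transitions(preds),
    )


def score_replay(truth: np.ndarray, naive: np.ndarray, conformal: np.ndarray,
                 class_names: dict[int, str] | None = None,
                 sets: list[PredictionSet] | None = None) -> EvalReport:
    """Score one validation replay under both decoding schemes.

    ``truth``, ``naive`` and ``conformal`` are aligned per-frame class
    sequences of equal length; ``sets`` optionally supplies the RAPS
    prediction sets for the set-size histogram.
    """
    truth = np.asarray(truth)
    naive = np.asarray(naive)
    conformal = np.asarray(conformal)
    if not (len(truth) == len(naive) == len(conformal)):
        raise ValueError(
            f"sequence lengths differ: truth {len(truth)}, naive {len(naive)}, "
            f"conformal {len(conformal)}")
    if len(truth) == 0:
        raise ValueError("nothing to score")
    classes = sorted(set(np.unique(truth)) | set(np.unique(naive))
                     | set(np.unique(conformal)))
    classes = [int(c) for c in classes]
    hist: dict[int, int] = {}
    if sets is not None:
        for s in sets:
            hist[len(s)] = hist.get(len(s), 0) + 1
    return EvalReport(
        classes=classes,
        class_names=class_names or {c: str(c) for c in classes},
        n_frames=len(truth),
        naive=_scheme_report(truth, naive, classes),
        conformal=_scheme_report(truth, conformal, classes),
        set_size_hist=hist,
    )


def validation_protocol(movements: list[Movement | str], reps: int = 6,
                        span_s: float = 45.0, hold_time_s: float = 1.5,
                        sample_rate_hz: float = 60.0
                        ) -> list[tuple[Movement, TrajectoryConfig]]:
    """Guide schedule for validation: per movement, ``reps`` activation
    cycles within ``span_s`` (default six repetitions in 45 s), rest
    interleaved by the cycle shape itself.

    Returns (movement, trajectory config) pairs that drive the simulator
    for validation replays; total duration is len(movements) * span_s.
    """
    if not movements:
        raise ValueError("movements must be non-empty")
    if reps <= 0:
        raise ValueError("reps must be positive")
    cycle = span_s / reps
    if cycle <= 2 * hold_time_s:
        raise ValueError(
            f"{reps} reps in {span_s} s leaves no ramp time with "
            f"{hold_time_s} s holds")
    cfg = TrajectoryConfig(hold_time_s=hold_time_s, cycle_period_s=cycle,
                           duration_s=span_s, sample_rate_hz=sample_rate_hz)
    return [(Movement(m), cfg) for m in movements]
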