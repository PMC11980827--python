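"""End-to-end record -> train -> validate orchestration.

These functions chain the library stages the way the interactive
software's three panels do, but headlessly: simulate (or load) one
training recording per movement, extract features, threshold-label,
split chronologically, normalize with training statistics, train the
classifier, calibrate the conformal wrapper on the first half of the
held-out tail, measure holdout accuracy on the second half, and finally
score a fresh validation replay (six repetitions in 45 s per movement)
under both the naive and the conformal scheme.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import joblib
import numpy as np

from . import dataset as ds
from . import decode, evaluate, preprocess, simulate

ARTIFACT_SCHEMA = 1


@dataclass
class RunConfig:
    """Everything one experiment run needs, serialized beside artifacts."""

    movements: list[str] = field(default_factory=lambda: ["thumb", "index", "grasp"])
    trajectory: simulate.TrajectoryConfig = field(default_factory=simulate.TrajectoryConfig)
    classifier: decode.ClassifierConfig = field(default_factory=decode.ClassifierConfig)
    alpha: float = 0.1
    lam: float = 0.01
    k_reg: int = 1
    history: int = decode.HISTORY_LEN
    train_fraction: float = 0.8
    threshold: float = ds.DEFAULT_THRESHOLD
    seed: int = 0
    involuntary_rate_hz: float = 0.0
    dead_channels: list[int] = field(default_factory=list)
    cuff_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.movements:
            raise ValueError("at least one movement is required")

    def cuff(self, seed_offset: int = 0) -> simulate.CuffModel:
        kw = dict(self.cuff_kwargs)
        if "involuntary_duration_s" in kw:
            kw["involuntary_duration_s"] = tuple(kw["involuntary_duration_s"])
        return simulate.CuffModel(
            involuntary_rate_hz=self.involuntary_rate_hz,
            dead_channels=frozenset(self.dead_channels),
            rng_seed=self.seed + seed_offset,
            **kw,
        )

    def to_json(self) -> str:
        d = asdict(self)
        d["trajectory"] = asdict(self.trajectory)
        d["classifier"] = asdict(self.classifier)
        return json.dumps(d, indent=2)

    @staticmethod
    def from_json(text: str) -> "RunConfig":
        d = json.loads(text)
        d["trajectory"] = simulate.TrajectoryConfig(**d.get("trajectory", {}))
        d["classifier"] = decode.ClassifierConfig(**d.get("classifier", {}))
        return RunConfig(**d)


@dataclass
class TrainedDecoder:
    """A trained, calibrated decoder plus its frozen preprocessing stats."""

    model: decode.FrameClassifier
    normalizer: ds.NormalizationStats
    calibrator: decode.ConformalCalibrator
    class_map: dict[simulate.Movement, int]
    holdout_accuracy: float
    n_train: int
    n_test: int

    @property
    def class_names(self) -> dict[int, str]:
        return {cls: mov.value for mov, cls in self.class_map.items()}

    def save(self, path: str | Path) -> None:
        joblib.dump({"schema_version": ARTIFACT_SCHEMA, "decoder": self}, path)

    @staticmethod
    def load(path: str | Path) -> "TrainedDecoder":
        blob = joblib.load(path)
        if blob.get("schema_version") != ARTIFACT_SCHEMA:
            raise ValueError("unsupported artifact schema")
        return blob["decoder"]


def simulate_training_sessions(cfg: RunConfig
                               ) -> list[tuple[simulate.Trajectory, np.ndarray]]:
    """One (trajectory, EMG windows) recording per configured movement."""
    out = []
    for i, mov in enumerate(cfg.movements):
        traj, windows = simulate.simulate_recording(
            mov, cfg.trajectory, cfg.cuff(seed_offset=1 + i))
        out.append((traj, windows))
    return out


def sessions_to_features(recordings, threshold: float = ds.DEFAULT_THRESHOLD
                         ) -> ds.SessionStore:
    """Feature-extract every recording into a session store."""
    store = ds.SessionStore()
    for i, (traj, windows) in enumerate(recordings):
        frames = preprocess.extract_features(windows, traj.t, traj.states)
        store.append(ds.Session(
            session_id=f"s{i:02d}_{traj.template.movement_id.value}",
            movement=traj.template.movement_id, frames=frames))
    return store


def train_decoder(store: ds.SessionStore, cfg: RunConfig) -> TrainedDecoder:
    """Label, split, normalize, train and conformally calibrate.

    The chronological 80% head of every recording trains the classifier;
    the 20% tail is halved into a calibration segment (conformal quantile)
    and a holdout segment (reported accuracy), keeping calibration data
    disjoint from training as split conformal prediction requires.
    """
    class_map = ds.default_class_map(
        [s.movement for s in store.sessions if s.movement != simulate.Movement.REST])
    labeled = store.labeled(class_map, cfg.threshold)
    train, test = ds.split_sessions(labeled, cfg.train_fraction)
    X_tr, y_tr = ds.as_arrays(train)
    X_te, y_te = ds.as_arrays(test)
    stats = ds.fit_normalizer(X_tr)
    Z_tr = ds.apply_normalizer(stats, X_tr)
    Z_te = ds.apply_normalizer(stats, X_te)
    model = decode.train_classifier(Z_tr, y_tr, cfg.classifier)
    half = len(y_te) // 2
    cal = decode.calibrate_raps(model, Z_te[:half], y_te[:half],
                                alpha=cfg.alpha, lam=cfg.lam, k_reg=cfg.k_reg)
    holdout = float(np.mean(model.predict(Z_te[half:]) == y_te[half:])) \
        if half < len(y_te) else float("nan")
    return TrainedDecoder(model=model, normalizer=stats, calibrator=cal,
                          class_map=class_map, holdout_accuracy=holdout,
                          n_train=len(y_tr), n_test=len(y_te))


def validate_decoder(dec: TrainedDecoder, cfg: RunConfig,
                     reps: int = 6, span_s: float = 45.0,
                     involuntary_rate_hz: float | None = None
                     ) -> evaluate.EvalReport:
    """Score a fresh simulated validation replay under both schemes.

    Per movement the guide performs ``reps`` cycles in ``span_s`` seconds;
    the ground-truth class per feature frame comes from the same 50%
    activation threshold used for labeling.  An involuntary burst rate
    can override the training condition to probe stability.
    """
    movements = [simulate.Movement(m) for m in cfg.movements]
    unknown = [m for m in movements if m not in dec.class_map]
    if unknown:
        raise ValueError(f"model has no classes for movements {unknown}")
    schedule = evaluate.validation_protocol(movements, reps=reps, span_s=span_s,
                                            hold_time_s=cfg.trajectory.hold_time_s)
    truth_all, naive_all, conf_all, sets_all = [], [], [], []
    solver = decode.SolverState(history_len=cfg.history)
    for j, (mov, vcfg) in enumerate(schedule):
        cuff = cfg.cuff(seed_offset=1000 + j)
        if involuntary_rate_hz is not None:
            cuff = replace(cuff, involuntary_rate_hz=involuntary_rate_hz)
        traj = simulate.generate_trajectory(simulate.template_for(mov), vcfg)
        windows = simulate.synthesize_emg(traj, cuff)
        frames = preprocess.extract_features(windows, traj.t, traj.states)
        template = simulate.template_for(mov)
        truth = [
            dec.class_map[mov] if ds.activation_of(f.label_state, template)
            >= cfg.threshold else ds.REST_CLASS
            for f in frames
        ]
        Z = ds.apply_normalizer(dec.normalizer,
                                np.stack([f.rms for f in frames]))
        naive, conf, sets = decode.predict_stream(dec.model, dec.calibrator,
                                                  solver, Z)
        truth_all.extend(truth)
        naive_all.extend(naive.tolist())
        conf_all.extend(conf.tolist())
        sets_all.extend(sets)
    return evaluate.score_replay(np.array(truth_all), np.array(naive_all),
                                 np.array(conf_all),
                                 class_names=dec.class_names, sets=sets_all)


def run_experiment(cfg: RunConfig, reps: int = 6, span_s: float = 45.0
                   ) -> tuple[TrainedDecoder, evaluate.EvalReport]:
    """The whole pipeline: simulate, featurize, train, calibrate, validate."""
    recordings = simulate_training_sessions(cfg)
    store = sessions_to_features(recordings, cfg.threshold)
    dec = train_decoder(store, cfg)
    report = validate_decoder(dec, cfg, reps=reps, span_s=span_s)
    return dec, report
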