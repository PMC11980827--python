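"""Synthetic guide-hand trajectories and bracelet EMG streams.

The decoder downstream assumes a 32-channel dry-electrode cuff looped
around the forearm (16 rows x 2 columns), sampled at 2000 Hz and streamed
as non-overlapping 18-sample windows (about 111 windows per second), with
a 9-dimensional guide-hand state streamed alongside at 60 Hz.  This module
generates both streams with the statistical structure that matters to the
pipeline: gesture-dependent spatial activation over the grid, amplifier
characteristics (gain, 16-bit quantization, 10-500 Hz band), dead
channels with no skin contact, and optional involuntary motor-unit bursts
that corrupt the rest state.

The EMG carrier is band-limited Gaussian noise amplitude-modulated by the
movement activation: interference-pattern surface EMG is well approximated
by modulated colored noise, which exercises an RMS-based feature pipeline
exactly as a recording would.
"""

from __future__ import annotations

import enum
import time
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np
from scipy import signal as sps

N_CHANNELS = 32
GRID_ROWS = 16
GRID_COLS = 2
SAMPLING_RATE_HZ = 2000
WINDOW_LEN = 18
GUIDE_RATE_HZ = 60
HAND_STATE_DIM = 9

#: Index meaning of the 9D hand-state vector, in order.
HAND_STATE_FIELDS = (
    "thumb_flex",
    "thumb_abduction",
    "index_flex",
    "middle_flex",
    "ring_flex",
    "pinky_flex",
    "wrist_flex",
    "wrist_adduction",
    "wrist_pronation",
)


class Movement(str, enum.Enum):
    """The preset movement vocabulary (rest plus eight hand movements)."""

    REST = "rest"
    THUMB = "thumb"
    INDEX = "index"
    MIDDLE = "middle"
    RING = "ring"
    PINKY = "pinky"
    GRASP = "grasp"
    PINCH2 = "pinch2"
    PINCH3 = "pinch3"


def _state(**kw: float) -> np.ndarray:
    v = np.zeros(HAND_STATE_DIM)
    for name, val in kw.items():
        v[HAND_STATE_FIELDS.index(name)] = val
    return v


#: Fully-executed 9D pose per movement.  Rest is the all-zero vector.
TARGET_STATES: Mapping[Movement, np.ndarray] = {
    Movement.REST: np.zeros(HAND_STATE_DIM),
    Movement.THUMB: _state(thumb_flex=1.0),
    Movement.INDEX: _state(index_flex=1.0),
    Movement.MIDDLE: _state(middle_flex=1.0),
    Movement.RING: _state(ring_flex=1.0),
    Movement.PINKY: _state(pinky_flex=1.0),
    Movement.GRASP: _state(
        thumb_flex=1.0, index_flex=1.0, middle_flex=1.0, ring_flex=1.0, pinky_flex=1.0
    ),
    Movement.PINCH2: _state(thumb_flex=1.0, thumb_abduction=0.5, index_flex=1.0),
    Movement.PINCH3: _state(
        thumb_flex=1.0, thumb_abduction=0.5, index_flex=1.0, middle_flex=1.0
    ),
}


@dataclass(frozen=True)
class MovementTemplate:
    """A movement with its fully-executed pose and an optional display pose.

    ``display_state`` supports remapping an executed movement to a different
    rendered one without touching labels; it defaults to ``target_state``.
    """

    movement_id: Movement
    target_state: np.ndarray
    display_state: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.target_state, dtype=float)
        if t.shape != (HAND_STATE_DIM,):
            raise ValueError(f"target_state must be 9D, got shape {t.shape}")
        if np.any(t < 0) or np.any(t > 1):
            raise ValueError("target_state components must lie in [0, 1]")
        if self.movement_id == Movement.REST and np.any(t != 0):
            raise ValueError("rest template must be the all-zero vector")
        object.__setattr__(self, "target_state", t)
        if self.display_state is None:
            object.__setattr__(self, "display_state", t)

    @property
    def driven_components(self) -> np.ndarray:
        """Indices of the hand-state components this movement drives."""
        return np.flatnonzero(self.target_state > 0)


def template_for(movement: Movement | str) -> MovementTemplate:
    m = Movement(movement)
    return MovementTemplate(m, TARGET_STATES[m])


@dataclass(frozen=True)
class TrajectoryConfig:
    """Timing of the sinusoidal guide movement.

    One cycle is rest-hold -> raised-cosine rise -> flexed-hold ->
    raised-cosine fall; each ramp lasts (cycle_period - 2*hold_time)/2, so
    the activation spends exactly half of each cycle at or above 50%.
    """

    hold_time_s: float = 1.5
    cycle_period_s: float = 7.5
    duration_s: float = 30.0
    sample_rate_hz: float = GUIDE_RATE_HZ

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.cycle_period_s <= 2 * self.hold_time_s:
            raise ValueError("cycle_period_s must exceed twice hold_time_s")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")


@dataclass(frozen=True)
class Trajectory:
    """A sampled guide trajectory: times, activation scalar and 9D states."""

    t: np.ndarray
    activation: np.ndarray
    states: np.ndarray
    template: MovementTemplate
    sample_rate_hz: float

    def __len__(self) -> int:
        return self.t.size


def _cycle_activation(phase: np.ndarray, hold: float, cycle: float) -> np.ndarray:
    """Raised-cosine activation profile over one cycle period."""
    ramp = (cycle - 2.0 * hold) / 2.0
    a = np.zeros_like(phase)
    rising = (phase >= hold) & (phase < hold + ramp)
    a[rising] = 0.5 * (1.0 - np.cos(np.pi * (phase[rising] - hold) / ramp))
    top = (phase >= hold + ramp) & (phase < 2.0 * hold + ramp)
    a[top] = 1.0
    falling = phase >= 2.0 * hold + ramp
    a[falling] = 0.5 * (1.0 + np.cos(np.pi * (phase[falling] - 2.0 * hold - ramp) / ramp))
    return a


def generate_trajectory(template: MovementTemplate, cfg: TrajectoryConfig) -> Trajectory:
    """Sample the guide-hand trajectory for one movement recording.

    The activation rises 0 -> 1 and back each cycle with holds at both
    extrema; the hand state is ``activation * target_state`` (so the rest
    template yields the zero state throughout).
    """
    n = int(round(cfg.duration_s * cfg.sample_rate_hz))
    t = np.arange(n) / cfg.sample_rate_hz
    phase = np.mod(t, cfg.cycle_period_s)
    a = _cycle_activation(phase, cfg.hold_time_s, cfg.cycle_period_s)
    if template.movement_id == Movement.REST:
        a = np.zeros_like(a)
    states = a[:, None] * template.target_state[None, :]
    return Trajectory(t=t, activation=a, states=states, template=template,
                      sample_rate_hz=cfg.sample_rate_hz)


# ---------------------------------------------------------------------------
# Cuff / EMG synthesis
# ---------------------------------------------------------------------------

def default_activation_maps(
    rows: int = GRID_ROWS, cols: int = GRID_COLS
) -> dict[Movement, np.ndarray]:
    """Distinct non-negative spatial gain maps, one per movement.

    Each non-rest movement activates a circular-Gaussian bump of muscle
    territory centred on a different row of the looped cuff, with a mild
    column asymmetry so neighbouring movements stay separable after the
    3x3 spatial smoothing downstream.
    """
    maps: dict[Movement, np.ndarray] = {Movement.REST: np.zeros((rows, cols))}
    active = [m for m in Movement if m != Movement.REST]
    r = np.arange(rows)
    for k, mov in enumerate(active):
        centre = (k * rows) / len(active)
        d = np.minimum(np.abs(r - centre), rows - np.abs(r - centre))  # circular
        bump = np.exp(-0.5 * (d / 1.5) ** 2)
        col_w = np.array([1.0, 0.6]) if k % 2 == 0 else np.array([0.6, 1.0])
        g = bump[:, None] * col_w[None, :cols]
        maps[mov] = g / g.max()
    return maps


@dataclass(frozen=True)
class CuffModel:
    """Physical and statistical model of the EMG bracelet.

    Amplitudes are in ADC counts after the amplifier (gain 4, 16-bit).
    ``voluntary_scale`` sets the peak RMS of fully-activated voluntary
    EMG to about +-3000 counts, leaving int16 headroom as a gain-4
    amplifier would.  ``involuntary_rate_hz`` is the Poisson rate of
    non-task-modulated motor-unit bursts (0 = clean recording).
    """

    n_rows: int = GRID_ROWS
    n_cols: int = GRID_COLS
    sampling_rate_hz: int = SAMPLING_RATE_HZ
    window_len: int = WINDOW_LEN
    gain: int = 4
    adc_bits: int = 16
    bandpass_hz: tuple[float, float] = (10.0, 500.0)
    activation_maps: Mapping[Movement, np.ndarray] = field(
        default_factory=default_activation_maps
    )
    voluntary_scale: float = 3000.0
    noise_sd: float = 30.0
    dead_channels: frozenset[int] = frozenset()
    involuntary_rate_hz: float = 0.0
    involuntary_duration_s: tuple[float, float] = (0.2, 1.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        bad = [c for c in self.dead_channels if not 0 <= c < self.n_channels]
        if bad:
            raise ValueError(f"dead channel indices out of range: {bad}")
        for mov, g in self.activation_maps.items():
            g = np.asarray(g)
            if g.shape != (self.n_rows, self.n_cols):
                raise ValueError(f"activation map for {mov} has shape {g.shape}")
            if np.any(g < 0):
                raise ValueError(f"activation map for {mov} has negative gains")

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def windows_per_second(self) -> int:
        return self.sampling_rate_hz // self.window_len

    def channel_gains(self, movement: Movement) -> np.ndarray:
        """Spatial gain map flattened to channel order (ch = col*16 + row)."""
        g = np.asarray(self.activation_maps[movement])
        return g.T.reshape(-1)  # column-major: channels 0..15 col 0, 16..31 col 1


def sci_like_cuff(seed: int = 0, **overrides) -> CuffModel:
    """Cuff preset emulating recordings after spinal cord injury.

    Severe spasticity keeps motor units firing when the task demands
    rest, and paresis weakens the voluntary signal.  The preset therefore
    halves the voluntary amplitude and adds Poisson-timed involuntary
    bursts (two event onsets per second, 0.5-2 s long, overlapping into
    near-continuous activity) with compact spatial territories and
    amplitudes comparable to voluntary EMG — the regime in which the
    rest state is genuinely corrupted and uncertainty-aware decoding has
    work to do.
    """
    params = dict(
        voluntary_scale=1500.0,
        involuntary_rate_hz=2.0,
        involuntary_duration_s=(0.5, 2.0),
        rng_seed=seed,
    )
    params.update(overrides)
    return CuffModel(**params)


def _bandpass_sos(lo: float, hi: float, fs: float):
    return sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _colored_carrier(rng: np.random.Generator, shape: tuple[int, int],
                     band: tuple[float, float], fs: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian carrier, one row per channel."""
    x = rng.standard_normal(shape)
    x = sps.sosfiltfilt(_bandpass_sos(*band, fs), x, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def synthesize_emg(trajectory: Trajectory, cuff: CuffModel,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Render a trajectory into a stream of int16 EMG windows.

    Returns an array of shape (n_windows, 32, 18) where
    ``n_windows = floor(duration * fs / window_len)``.  Per channel the
    signal is activation-scaled colored-noise carrier x spatial gain,
    plus white measurement noise, plus optional involuntary bursts that
    are independent of the task activation.  Dead channels carry
    measurement noise only.  Samples are rounded and clipped to the ADC
    range.  Bit-identical under a fixed ``cuff.rng_seed``.
    """
    if len(trajectory) == 0:
        raise ValueError("trajectory is empty")
    if rng is None:
        rng = np.random.default_rng(cuff.rng_seed)
    fs = cuff.sampling_rate_hz
    duration = len(trajectory) / trajectory.sample_rate_hz
    n_windows = int(np.floor(duration * fs)) // cuff.window_len
    if n_windows == 0:
        raise ValueError("trajectory too short for a single EMG window")
    n = n_windows * cuff.window_len
    t = np.arange(n) / fs

    a = np.interp(t, trajectory.t, trajectory.activation)
    gains = cuff.channel_gains(trajectory.template.movement_id)

    carrier = _colored_carrier(rng, (cuff.n_channels, n), cuff.bandpass_hz, fs)
    x = (a[None, :] * gains[:, None]) * cuff.voluntary_scale * carrier
    x += _involuntary_bursts(rng, cuff, n)

    dead = sorted(cuff.dead_channels)
    if dead:
        x[dead, :] = 0.0
    if cuff.noise_sd > 0:
        x += rng.normal(0.0, cuff.noise_sd, size=x.shape)

    lim = 2 ** (cuff.adc_bits - 1)
    q = np.clip(np.rint(x), -lim, lim - 1).astype(np.int16)
    return q.reshape(cuff.n_channels, n_windows, cuff.window_len).transpose(1, 0, 2)


def _involuntary_bursts(rng: np.random.Generator, cuff: CuffModel, n: int) -> np.ndarray:
    """Poisson-timed motor-unit bursts with contiguous spatial territories.

    A spontaneously firing motor unit projects to a compact patch of the
    grid, just like voluntary activity does; each burst therefore gets a
    circular-Gaussian spatial profile around a random row, a Hann
    temporal envelope, and an amplitude comparable to voluntary EMG.
    """
    out = np.zeros((cuff.n_channels, n))
    if cuff.involuntary_rate_hz <= 0:
        return out
    fs = cuff.sampling_rate_hz
    n_events = rng.poisson(cuff.involuntary_rate_hz * n / fs)
    lo, hi = cuff.involuntary_duration_s
    r = np.arange(cuff.n_rows)
    for _ in range(n_events):
        start = int(rng.uniform(0, n))
        dur = int(rng.uniform(lo, hi) * fs)
        stop = min(start + dur, n)
        if stop <= start:
            continue
        centre = rng.uniform(0, cuff.n_rows)
        d = np.minimum(np.abs(r - centre), cuff.n_rows - np.abs(r - centre))
        bump = np.exp(-0.5 * (d / 1.5) ** 2)
        col_w = rng.uniform(0.5, 1.0, size=cuff.n_cols)
        gains = (bump[:, None] * col_w[None, :]).T.reshape(-1)  # channel order
        amp = rng.uniform(0.5, 1.2) * cuff.voluntary_scale
        seg = stop - start
        env = np.hanning(seg) if seg > 2 else np.ones(seg)
        burst = _colored_carrier(rng, (cuff.n_channels, seg), cuff.bandpass_hz, fs) \
            if seg > 30 else rng.standard_normal((cuff.n_channels, seg))
        out[:, start:stop] += amp * gains[:, None] * env * burst
    return out


def stream_replay(windows: np.ndarray | Iterable[np.ndarray],
                  pace: str = "unpaced") -> Iterator[np.ndarray]:
    """Yield EMG windows in order, optionally paced to the bracelet rate.

    ``pace="real_time"`` targets one window per window_len/fs seconds
    (about 9 ms), emulating the live stream; ``"unpaced"`` yields as fast
    as the consumer pulls.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("no windows to replay")
    if pace not in ("real_time", "unpaced"):
        raise ValueError(f"unknown pace {pace!r}")
    if pace == "unpaced":
        yield from windows
        return
    period = WINDOW_LEN / SAMPLING_RATE_HZ
    t0 = time.perf_counter()
    for i, w in enumerate(windows):
        target = t0 + i * period
        delay = target - time.perf_counter()
        if delay > 0:
            time.sleep(delay)
        yield w


def simulate_recording(movement: Movement | str,
                       traj_cfg: TrajectoryConfig | None = None,
                       cuff: CuffModel | None = None,
                       seed: int | None = None) -> tuple[Trajectory, np.ndarray]:
    """Convenience: trajectory plus EMG windows for one movement recording."""
    traj_cfg = traj_cfg or TrajectoryConfig()
    cuff = cuff or CuffModel()
    if seed is not None:
        cuff = replace(cuff, rng_seed=seed)
    traj = generate_trajectory(template_for(movement), traj_cfg)
    windows = synthesize_emg(traj, cuff)
    return traj, windows
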