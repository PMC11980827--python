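"""Streaming feature extraction: window queue, grid filter, RMS.

One streamed window (32 channels x 18 samples, ~9 ms) carries too little
temporal information on its own, so windows are buffered in a sliding
20-window queue (360 samples, ~180 ms).  Each buffered block is reshaped
onto the physical 16-row x 2-column cuff grid, smoothed per time sample
with a fixed 3x3 cross-shaped kernel (circular over rows because the
cuff loops around the arm, zero-padded over columns), and summarised as
one RMS value per channel — 32 features per frame, paired with the mean
guide-hand state over the buffered span.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .simulate import (
    GRID_COLS,
    GRID_ROWS,
    HAND_STATE_DIM,
    N_CHANNELS,
    SAMPLING_RATE_HZ,
    WINDOW_LEN,
)

QUEUE_CAPACITY = 20
BLOCK_SAMPLES = QUEUE_CAPACITY * WINDOW_LEN  # 360

#: 3x3 noise-suppression kernel: each electrode is replaced by the mean of
#: its four cross neighbours with the electrode itself at half weight.
SPATIAL_KERNEL_WEIGHTS = np.array(
    [[0.0, 1.0, 0.0],
     [1.0, 0.5, 1.0],
     [0.0, 1.0, 0.0]]
) / 4.0
SPATIAL_KERNEL_WEIGHTS.setflags(write=False)


@dataclass(frozen=True)
class SpatialKernel:
    """The fixed cross-shaped blur kernel (immutable)."""

    weights: np.ndarray = field(default_factory=lambda: SPATIAL_KERNEL_WEIGHTS)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if w.shape != (3, 3):
            raise ValueError("spatial kernel must be 3x3")


@dataclass(frozen=True)
class GridLayout:
    """Bijection between channel index and (row, col) on the looped cuff.

    Default: channel i sits at row i mod 16, column i div 16, i.e. channels
    0-15 run down one column and 16-31 down the other, so channels 0 and 16
    are row-adjacent across the two columns.
    """

    n_rows: int = GRID_ROWS
    n_cols: int = GRID_COLS

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    def channel_of(self, row: int, col: int) -> int:
        return col * self.n_rows + row

    def position_of(self, channel: int) -> tuple[int, int]:
        return channel % self.n_rows, channel // self.n_rows


DEFAULT_LAYOUT = GridLayout()


def to_grid(channels: np.ndarray, layout: GridLayout = DEFAULT_LAYOUT) -> np.ndarray:
    """Reshape (32,) or (32, T) channel data to the (16, 2[, T]) grid."""
    x = np.asarray(channels)
    if x.shape[0] != layout.n_channels:
        raise ValueError(
            f"expected {layout.n_channels} channels, got {x.shape[0]}"
        )
    # channel = col*n_rows + row  =>  leading axis factors as (col, row)
    g = x.reshape(layout.n_cols, layout.n_rows, *x.shape[1:])
    return np.moveaxis(g, 0, 1)


def from_grid(grid: np.ndarray, layout: GridLayout = DEFAULT_LAYOUT) -> np.ndarray:
    """Inverse of :func:`to_grid`."""
    g = np.asarray(grid)
    if g.shape[:2] != (layout.n_rows, layout.n_cols):
        raise ValueError(f"expected grid {layout.n_rows}x{layout.n_cols}, got {g.shape[:2]}")
    return np.moveaxis(g, 1, 0).reshape(layout.n_channels, *g.shape[2:])


def pad_grid(grid: np.ndarray) -> np.ndarray:
    """Pad a (16, 2[, T]) grid to (18, 4[, T]) for the 3x3 kernel.

    Rows are padded circularly (the cuff loops: the last row is prepended
    above the first and the first appended below the last); one zero
    column is added on each side.
    """
    g = np.asarray(grid)
    rows = np.concatenate([g[-1:], g, g[:1]], axis=0)
    zcol = np.zeros_like(rows[:, :1])
    return np.concatenate([zcol, rows, zcol], axis=1)


def spatial_filter(block: np.ndarray, kernel: SpatialKernel | None = None) -> np.ndarray:
    """Apply the 3x3 blur to each time sample of a (16, 2[, T]) block.

    Output electrode value = (up + down + lateral + 0.5*self) / 4 with
    circular rows and zero virtual columns off the grid.  The kernel is
    symmetric so correlation and convolution coincide.
    """
    g = np.asarray(block, dtype=float)
    default_kernel = kernel is None or np.array_equal(kernel.weights,
                                                      SPATIAL_KERNEL_WEIGHTS)
    if default_kernel and g.shape[1] == 2:
        up = np.roll(g, 1, axis=0)
        down = np.roll(g, -1, axis=0)
        lateral = g[:, ::-1]
        return (up + down + lateral + 0.5 * g) / 4.0
    # general path for a custom 3x3 kernel: pad, correlate, crop
    padded = pad_grid(g)
    w = np.asarray((kernel or SpatialKernel()).weights, dtype=float)
    out = np.zeros_like(g)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            out += w[dr + 1, dc + 1] * padded[1 + dr:1 + dr + g.shape[0],
                                              1 + dc:1 + dc + g.shape[1]]
    return out


def software_bandpass(x: np.ndarray, lo: float = 10.0, hi: float = 500.0,
                      fs: float = SAMPLING_RATE_HZ) -> np.ndarray:
    """Optional zero-phase 4th-order Butterworth bandpass.

    The bracelet amplifier band-limits at source, so this is off by
    default; it is available for replaying unfiltered recordings.
    """
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


class WindowQueue:
    """Sliding buffer of the last 20 EMG windows.

    ``push`` returns nothing until 20 windows are queued; from then on it
    returns one concatenated (32, 360) block per push, the oldest window
    falling off the far end.  The one-window hop gives the full 111 Hz
    frame rate.
    """

    def __init__(self, capacity: int = QUEUE_CAPACITY):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._buf: deque[np.ndarray] = deque(maxlen=capacity)

    def __len__(self) -> int:
        return len(self._buf)

    def push(self, window: np.ndarray) -> np.ndarray | None:
        w = np.asarray(window)
        if w.shape != (N_CHANNELS, WINDOW_LEN):
            raise ValueError(
                f"expected window of shape ({N_CHANNELS}, {WINDOW_LEN}), got {w.shape}"
            )
        self._buf.append(w)
        if len(self._buf) < self.capacity:
            return None
        return np.concatenate(list(self._buf), axis=1)


@dataclass
class FeatureFrame:
    """One decoder input frame: 32 RMS features plus its guide label.

    ``label_state`` is the arithmetic mean of the 9D guide states whose
    timestamps fall within the buffered span; ``stale_label`` marks frames
    whose span contained no guide sample (the last known state is carried).
    """

    rms: np.ndarray
    label_state: np.ndarray
    t_end: float
    stale_label: bool = False

    def __post_init__(self) -> None:
        self.rms = np.asarray(self.rms, dtype=float)
        self.label_state = np.asarray(self.label_state, dtype=float)
        if self.rms.shape != (N_CHANNELS,):
            raise ValueError(f"rms must have length {N_CHANNELS}")
        if np.any(self.rms < 0):
            raise ValueError("rms values must be non-negative")
        if self.label_state.shape != (HAND_STATE_DIM,):
            raise ValueError("label_state must be 9D")


def _mean_label(label_states: np.ndarray | None,
                last_state: np.ndarray | None) -> tuple[np.ndarray, bool]:
    stale = label_states is None or len(label_states) == 0
    if stale:
        if last_state is None:
            raise ValueError("no guide states in span and no last known state")
        warnings.warn("feature block span contained no guide sample; "
                      "carrying last known state", stacklevel=3)
        return np.asarray(last_state, dtype=float), True
    return np.mean(np.asarray(label_states, dtype=float), axis=0), False


def rms_features(filtered_block: np.ndarray,
                 label_states: np.ndarray | None,
                 t_end: float = 0.0,
                 last_state: np.ndarray | None = None) -> FeatureFrame:
    """Collapse a filtered (16, 2, 360) or (32, 360) block to a FeatureFrame."""
    b = np.asarray(filtered_block, dtype=float)
    if b.ndim == 3:
        b = from_grid(b)
    if b.shape[0] != N_CHANNELS:
        raise ValueError(f"expected {N_CHANNELS} channels, got {b.shape[0]}")
    rms = np.sqrt(np.mean(b * b, axis=-1))
    label, stale = _mean_label(label_states, last_state)
    return FeatureFrame(rms=rms, label_state=label, t_end=t_end, stale_label=stale)


def extract_features(windows: np.ndarray,
                     guide_t: np.ndarray | None = None,
                     guide_states: np.ndarray | None = None,
                     layout: GridLayout = DEFAULT_LAYOUT,
                     kernel: SpatialKernel | None = None,
                     apply_bandpass: bool = False,
                     queue_capacity: int = QUEUE_CAPACITY) -> list[FeatureFrame]:
    """Run a whole window stream through the pipeline in one batch.

    Equivalent to pushing each window through :class:`WindowQueue` and
    filtering each emitted block, but vectorised: the spatial filter is
    per-sample, so filtering the concatenated stream once and reading RMS
    off cumulative sums of squares gives identical frames.  For a stream
    of N >= 20 windows exactly N - 19 frames are produced.
    """
    w = np.asarray(windows)
    if w.ndim != 3 or w.shape[1:] != (N_CHANNELS, WINDOW_LEN):
        raise ValueError(f"expected windows of shape (n, {N_CHANNELS}, {WINDOW_LEN})")
    n_windows = w.shape[0]
    block_len = queue_capacity * WINDOW_LEN
    signal = w.transpose(1, 0, 2).reshape(N_CHANNELS, n_windows * WINDOW_LEN)
    signal = signal.astype(float)
    if apply_bandpass:
        signal = software_bandpass(signal)
    filt = from_grid(spatial_filter(to_grid(signal, layout), kernel), layout)

    sq = np.concatenate([np.zeros((N_CHANNELS, 1)), np.cumsum(filt * filt, axis=1)],
                        axis=1)
    frames: list[FeatureFrame] = []
    last_state = None if guide_states is None or len(guide_states) == 0 \
        else np.asarray(guide_states[0], dtype=float)
    for i in range(queue_capacity - 1, n_windows):
        end = (i + 1) * WINDOW_LEN
        start = end - block_len
        rms = np.sqrt((sq[:, end] - sq[:, start]) / block_len)
        t_end = end / SAMPLING_RATE_HZ
        t_start = t_end - block_len / SAMPLING_RATE_HZ
        if guide_t is None or guide_states is None:
            span_states, label, stale = None, np.zeros(HAND_STATE_DIM), False
        else:
            sel = (guide_t > t_start) & (guide_t <= t_end)
            span_states = np.asarray(guide_states)[sel]
            label, stale = _mean_label(span_states, last_state)
        frames.append(FeatureFrame(rms=rms, label_state=label, t_end=t_end,
                                   stale_label=stale))
        if span_states is not None and len(span_states):
            last_state = span_states[-1]
    return frames
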