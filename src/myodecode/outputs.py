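"""Mapping decoded classes to output states.

Decoded classes drive either a 9D virtual-hand state or a 2D cursor.
Hand states are not jumped to abruptly: the output interpolates linearly
from the current pose to the class's display target over a fixed
transition time at the output rate (default 32 Hz, decoupled from the
111 Hz prediction rate by keeping only the latest prediction).  The
display target may be remapped — an executed movement can be rendered as
a different one — without ever touching the class labels used for
training or metrics.
"""

from __future__ import annotations

import struct
import time
from dataclasses import dataclass, field, replace
from math import ceil
from typing import Mapping

import numpy as np

from .simulate import HAND_STATE_DIM, Movement, template_for

OUTPUT_RATE_HZ = 32.0
DEFAULT_TRANSITION_S = 0.25

HAND_MSG_STRUCT = struct.Struct("<9fI")   # 9 float32 state + uint32 counter
CURSOR_MSG_STRUCT = struct.Struct("<2fI")  # x, y + uint32 counter


@dataclass(frozen=True)
class OutputMap:
    """class_id -> display hand state, with optional movement remapping."""

    targets: Mapping[int, np.ndarray]

    def __post_init__(self) -> None:
        for cls, st in self.targets.items():
            st = np.asarray(st, dtype=float)
            if st.shape != (HAND_STATE_DIM,):
                raise ValueError(f"display target for class {cls} must be 9D")

    def target_for(self, class_id: int) -> np.ndarray:
        if class_id not in self.targets:
            raise KeyError(f"no display target for class {class_id}")
        return np.asarray(self.targets[class_id], dtype=float)

    @staticmethod
    def from_class_map(class_map: Mapping[Movement, int],
                       remap: Mapping[Movement, Movement] | None = None
                       ) -> "OutputMap":
        """Display targets from movement templates, honouring a remap table.

        ``remap`` substitutes the *rendered* movement only; class ids and
        labels are untouched.
        """
        remap = remap or {}
        targets = {}
        for mov, cls in class_map.items():
            shown = remap.get(mov, mov)
            targets[cls] = template_for(shown).target_state
        return OutputMap(targets=targets)


class StateInterpolator:
    """Linear stepper from the current pose toward a target pose.

    On each new target the gap is divided into ceil(transition_s * rate)
    equal steps, so the target is reached in a fixed number of updates
    and every component moves monotonically; outputs stay in [0, 1]^9 as
    convex combinations of valid states.
    """

    def __init__(self, initial: np.ndarray | None = None,
                 rate_hz: float = OUTPUT_RATE_HZ,
                 transition_s: float = DEFAULT_TRANSITION_S):
        self.current = np.zeros(HAND_STATE_DIM) if initial is None \
            else np.asarray(initial, dtype=float).copy()
        self.rate_hz = rate_hz
        self.transition_s = transition_s
        self._target = self.current.copy()
        self._step = np.zeros(HAND_STATE_DIM)
        self._remaining = 0

    @property
    def n_steps(self) -> int:
        return ceil(self.transition_s * self.rate_hz)

    def set_target(self, target: np.ndarray) -> None:
        target = np.asarray(target, dtype=float)
        if target.shape != (HAND_STATE_DIM,):
            raise ValueError("target must be 9D")
        if np.array_equal(target, self._target) and self._remaining > 0:
            return  # already interpolating toward it
        self._target = target
        if np.array_equal(target, self.current):
            self._remaining = 0
            self._step = np.zeros(HAND_STATE_DIM)
            return
        self._remaining = self.n_steps
        self._step = (target - self.current) / self._remaining

    def step(self) -> np.ndarray:
        """Advance one output frame toward the target; fixed point at it."""
        if self._remaining > 0:
            self._remaining -= 1
            if self._remaining == 0:
                self.current = self._target.copy()
            else:
                self.current = self.current + self._step
        return self.current.copy()


def interpolate_states(current: np.ndarray, target: np.ndarray,
                       rate_hz: float = OUTPUT_RATE_HZ,
                       transition_s: float = DEFAULT_TRANSITION_S) -> np.ndarray:
    """The full interpolation path current -> target, one row per update."""
    interp = StateInterpolator(current, rate_hz, transition_s)
    interp.set_target(target)
    return np.stack([interp.step() for _ in range(interp.n_steps)]) \
        if interp.n_steps and not np.array_equal(current, target) \
        else np.asarray(target, dtype=float)[None, :]


# ---------------------------------------------------------------------------
# 2D cursor (lower-limb scheme)
# ---------------------------------------------------------------------------

#: Five-class foot scheme: ankle movements steer, rest holds position.
CURSOR_DIRECTIONS: Mapping[str, tuple[float, float]] = {
    "rest": (0.0, 0.0),
    "inversion": (-1.0, 0.0),
    "eversion": (1.0, 0.0),
    "dorsiflexion": (0.0, 1.0),
    "plantarflexion": (0.0, -1.0),
}


@dataclass(frozen=True)
class CursorState:
    """2D cursor position driven by decoded foot movements."""

    position: tuple[float, float] = (0.0, 0.0)


def update_cursor(cursor: CursorState, movement: str, step: float = 1.0) -> CursorState:
    """Displace the cursor one step in the movement's direction; rest holds."""
    if movement not in CURSOR_DIRECTIONS:
        raise ValueError(f"unknown cursor class {movement!r}; "
                         f"expected one of {sorted(CURSOR_DIRECTIONS)}")
    dx, dy = CURSOR_DIRECTIONS[movement]
    x, y = cursor.position
    return replace(cursor, position=(x + step * dx, y + step * dy))


# ---------------------------------------------------------------------------
# Serialization and rate-limited emission
# ---------------------------------------------------------------------------

def pack_hand_state(state: np.ndarray, counter: int) -> bytes:
    """Fixed-layout message: 9 little-endian float32 + uint32 frame counter."""
    state = np.asarray(state, dtype=np.float32)
    if state.shape != (HAND_STATE_DIM,):
        raise ValueError("hand state must be 9D")
    return HAND_MSG_STRUCT.pack(*state.tolist(), counter & 0xFFFFFFFF)


def unpack_hand_state(msg: bytes) -> tuple[np.ndarray, int]:
    if len(msg) != HAND_MSG_STRUCT.size:
        raise ValueError(
            f"hand-state message must be {HAND_MSG_STRUCT.size} bytes, got {len(msg)}")
    *vals, counter = HAND_MSG_STRUCT.unpack(msg)
    return np.array(vals, dtype=np.float32), counter


def pack_cursor(cursor: CursorState, counter: int) -> bytes:
    x, y = cursor.position
    return CURSOR_MSG_STRUCT.pack(x, y, counter & 0xFFFFFFFF)


def unpack_cursor(msg: bytes) -> tuple[CursorState, int]:
    if len(msg) != CURSOR_MSG_STRUCT.size:
        raise ValueError(
            f"cursor message must be {CURSOR_MSG_STRUCT.size} bytes, got {len(msg)}")
    x, y, counter = CURSOR_MSG_STRUCT.unpack(msg)
    return CursorState(position=(x, y)), counter


class StateEmitter:
    """Rate-limited sink for decoded states.

    Predictions arrive at ~111 Hz but the display runs at ~32 Hz: the
    emitter keeps the latest submitted state and emits it whenever a full
    output period has elapsed.  ``sink`` is any object with a
    ``send(bytes)`` or ``write(bytes)`` method (datagram socket, file,
    buffer); a closed sink raises.  The clock is injectable for testing.
    """

    def __init__(self, sink, rate_hz: float = OUTPUT_RATE_HZ, clock=time.monotonic):
        self._send = getattr(sink, "send", None) or getattr(sink, "write", None)
        if self._send is None:
            raise ValueError("sink must expose send() or write()")
        self.sink = sink
        self.rate_hz = rate_hz
        self._clock = clock
        self._next_due: float | None = None
        self.counter = 0

    def submit(self, state: np.ndarray, now: float | None = None) -> bool:
        """Offer the latest state; emit if an output frame is due.

        Returns True when a message was actually written.
        """
        now = self._clock() if now is None else now
        if self._next_due is not None and now < self._next_due:
            return False
        if getattr(self.sink, "closed", False):
            raise ValueError("sink is closed")
        payload = pack_cursor(state, self.counter) \
            if isinstance(state, CursorState) else pack_hand_state(state, self.counter)
        self._send(payload)
        self.counter += 1
        period = 1.0 / self.rate_hz
        self._next_due = now + period if self._next_due is None \
            else max(self._next_due + period, now)
        return True
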