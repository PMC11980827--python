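"""On-disk session container and wire framing for EMG streams.

A recorded or simulated session is stored as two files:

* ``<name>.bin`` — the raw windows as little-endian int16, channel-major
  within each window, windows concatenated in stream order;
* ``<name>.json`` — a sidecar with the schema version, movement id,
  stream geometry, generator configuration, seed, and the 60 Hz guide
  trajectory (times, activation, 9D states).

Stream framing for service-style replay is length-prefixed: a uint32
little-endian byte count followed by the 32x18 int16 payload
(channel-major), 4 + 1152 bytes per frame.
"""

from __future__ import annotations

import json
import struct
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .simulate import (
    CuffModel,
    Movement,
    N_CHANNELS,
    Trajectory,
    TrajectoryConfig,
    WINDOW_LEN,
    template_for,
)

SCHEMA_VERSION = 1
_LEN_PREFIX = struct.Struct("<I")
WINDOW_BYTES = N_CHANNELS * WINDOW_LEN * 2


def save_session(directory: str | Path, name: str, windows: np.ndarray,
                 trajectory: Trajectory, cuff: CuffModel,
                 traj_cfg: TrajectoryConfig, force: bool = False) -> Path:
    """Write one session (windows + sidecar) into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bin_path = directory / f"{name}.bin"
    meta_path = directory / f"{name}.json"
    if not force and (bin_path.exists() or meta_path.exists()):
        raise FileExistsError(f"session {name!r} already exists in {directory}")
    w = np.ascontiguousarray(np.asarray(windows, dtype="<i2"))
    if w.ndim != 3 or w.shape[1:] != (N_CHANNELS, WINDOW_LEN):
        raise ValueError(f"expected (n, {N_CHANNELS}, {WINDOW_LEN}) windows")
    w.tofile(bin_path)
    cuff_meta = asdict(cuff)
    cuff_meta["dead_channels"] = sorted(cuff.dead_channels)
    cuff_meta["activation_maps"] = {
        Movement(m).value: np.asarray(g).tolist()
        for m, g in cuff.activation_maps.items()
    }
    meta = {
        "schema_version": SCHEMA_VERSION,
        "movement_id": trajectory.template.movement_id.value,
        "n_windows": int(w.shape[0]),
        "window_shape": [N_CHANNELS, WINDOW_LEN],
        "dtype": "<i2",
        "cuff": cuff_meta,
        "trajectory_config": asdict(traj_cfg),
        "seed": cuff.rng_seed,
        "guide": {
            "t": trajectory.t.tolist(),
            "activation": trajectory.activation.tolist(),
            "states": trajectory.states.tolist(),
        },
    }
    meta_path.write_text(json.dumps(meta))
    return meta_path


def load_session(directory: str | Path, name: str
                 ) -> tuple[np.ndarray, Trajectory, dict]:
    """Read back a session; returns (windows, guide trajectory, metadata)."""
    directory = Path(directory)
    meta = json.loads((directory / f"{name}.json").read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported session schema {meta.get('schema_version')}")
    n = meta["n_windows"]
    w = np.fromfile(directory / f"{name}.bin", dtype="<i2")
    if w.size != n * N_CHANNELS * WINDOW_LEN:
        raise ValueError("session payload size does not match sidecar")
    windows = w.reshape(n, N_CHANNELS, WINDOW_LEN)
    guide = meta["guide"]
    template = template_for(meta["movement_id"])
    traj = Trajectory(
        t=np.asarray(guide["t"]),
        activation=np.asarray(guide["activation"]),
        states=np.asarray(guide["states"]),
        template=template,
        sample_rate_hz=meta["trajectory_config"]["sample_rate_hz"],
    )
    return windows, traj, meta


def save_features(path: str | Path, rms: np.ndarray, labels: np.ndarray,
                  t_end: np.ndarray, movement: Movement) -> None:
    """Persist extracted feature frames of one session (npz + schema tag)."""
    np.savez(path, schema_version=SCHEMA_VERSION, rms=rms,
             label_states=labels, t_end=t_end, movement=movement.value)


def load_features(path: str | Path) -> dict:
    with np.load(path, allow_pickle=False) as z:
        if int(z["schema_version"]) != SCHEMA_VERSION:
            raise ValueError("unsupported feature schema")
        return {"rms": z["rms"], "label_states": z["label_states"],
                "t_end": z["t_end"], "movement": Movement(str(z["movement"]))}


# ---------------------------------------------------------------------------
# Length-prefixed wire framing
# ---------------------------------------------------------------------------

def pack_window(window: np.ndarray) -> bytes:
    """One wire frame: uint32 LE byte count + 32x18 int16 LE channel-major."""
    w = np.ascontiguousarray(np.asarray(window, dtype="<i2"))
    if w.shape != (N_CHANNELS, WINDOW_LEN):
        raise ValueError(f"expected ({N_CHANNELS}, {WINDOW_LEN}) window")
    payload = w.tobytes()
    return _LEN_PREFIX.pack(len(payload)) + payload


def unpack_window(frame: bytes) -> np.ndarray:
    if len(frame) < _LEN_PREFIX.size:
        raise ValueError("truncated frame")
    (n,) = _LEN_PREFIX.unpack_from(frame)
    if n != WINDOW_BYTES or len(frame) != _LEN_PREFIX.size + n:
        raise ValueError(
            f"bad frame: declared {n} bytes, frame has {len(frame)}")
    return np.frombuffer(frame, dtype="<i2", offset=_LEN_PREFIX.size
                         ).reshape(N_CHANNELS, WINDOW_LEN)


def read_frames(stream) -> list[np.ndarray]:
    """Read consecutive length-prefixed windows from a binary stream."""
    out = []
    while True:
        head = stream.read(_LEN_PREFIX.size)
        if not head:
            break
        if len(head) < _LEN_PREFIX.size:
            raise ValueError("truncated frame header")
        (n,) = _LEN_PREFIX.unpack(head)
        payload = stream.read(n)
        if len(payload) != n:
            raise ValueError("truncated frame payload")
        out.append(unpack_window(head + payload))
    return out
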