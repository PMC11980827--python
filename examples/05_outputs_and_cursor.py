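"""Mapping decoded classes to smooth hand states and a 2D cursor.

Decoded classes jump discretely; the display should not. The
interpolator walks the 9D hand state to each class's target over 0.25 s
at the 32 Hz output rate. The same class stream can instead drive a 2D
cursor with the five-class ankle scheme.
"""

import io

import numpy as np

from myodecode import CursorState, Movement, OutputMap, StateEmitter, \
    StateInterpolator, update_cursor
from myodecode.outputs import unpack_hand_state

# hand-state interpolation: rest -> grasp in 8 equal steps
out_map = OutputMap.from_class_map({Movement.REST: 0, Movement.GRASP: 1})
interp = StateInterpolator(rate_hz=32, transition_s=0.25)
interp.set_target(out_map.target_for(1))
path = [interp.step() for _ in range(interp.n_steps)]
print("grasp onset, thumb-flexion component per output frame:")
print("  " + " ".join(f"{s[0]:.3f}" for s in path))

# rate-limited emission: 1 s of 111 Hz predictions -> ~32 messages
sink = io.BytesIO()
clock = iter(np.arange(0, 1, 1 / 111))
emitter = StateEmitter(sink, rate_hz=32, clock=lambda: next(clock))
sent = sum(emitter.submit(path[-1]) for _ in range(111))
state, counter = unpack_hand_state(sink.getvalue()[:40])
print(f"emitted {sent} messages in 1 s (40 bytes each: 9 float32 + counter)")

# 2D cursor: dorsiflexion climbs, inversion goes left, rest holds
c = CursorState()
for mov in ["dorsiflexion"] * 3 + ["inversion"] * 2 + ["rest"] * 5:
    c = update_cursor(c, mov, step=1.0)
print(f"cursor after 3 up, 2 left, 5 rest: {c.position} (rest never moves it)")
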