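"""Run the spatial-filter + RMS feature pipeline on a stream.

Streams windows through the sliding 20-window queue, applies the 3x3
grid blur (circular rows for the looped cuff, zero columns) and reduces
each 360-sample block to 32 RMS features paired with the mean guide
state over its span.
"""

import numpy as np

from myodecode import CuffModel, TrajectoryConfig, extract_features, \
    generate_trajectory, synthesize_emg, template_for

traj = generate_trajectory(template_for("index"), TrajectoryConfig(duration_s=15))
windows = synthesize_emg(traj, CuffModel(rng_seed=7))
frames = extract_features(windows, traj.t, traj.states)

print(f"{windows.shape[0]} windows -> {len(frames)} feature frames "
      f"(always n - 19: the queue emits once full, sliding by one window)")
f = frames[len(frames) // 2]
print(f"frame at t={f.t_end:.3f}s: 32 RMS features, "
      f"guide index flexion = {f.label_state[2]:.2f}")
active = np.stack([f.rms for f in frames if f.label_state[2] >= 0.5])
rest = np.stack([f.rms for f in frames if f.label_state[2] < 0.5])
print(f"mean RMS while active {active.mean():.0f} vs at rest {rest.mean():.0f} "
      f"counts — the amplitude contrast the classifier will exploit")
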