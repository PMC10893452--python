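"""Simulate a VR head-tracking recording with ground truth and raters.

Generates an instant-condition session (ballistic orienting movements
toward eccentric targets), then prints what the stream contains.
"""

import numpy as np

from headmov import SimConfig, compute_kinematics, simulate_trace

cfg = SimConfig(seed=42, n_trials=5, condition="instant")
sim = simulate_trace(cfg)
kin = compute_kinematics(sim.trace)

print(f"trace: {len(sim.trace)} samples at {cfg.rate:.0f} Hz "
      f"({sim.trace.timestamps[-1]:.1f} s)")
print(f"truth events: {len(sim.truth_events)}  raters: {len(sim.rater_labels)}")
print(f"peak angular speed: {kin.speed.max():.0f} deg/s, "
      f"max head angle: {kin.head_angle.max():.1f} deg")
for e in sim.truth_events[:4]:
    print(f"  {e.onset:6.3f}-{e.offset:6.3f} s  {e.direction:>2s}  "
          f"amp {e.amplitude:5.1f} deg  peak {e.peak_velocity:6.1f} deg/s")
print("Each line is one head movement: when it happened, its compass")
print("direction, net amplitude, and peak angular speed.")
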