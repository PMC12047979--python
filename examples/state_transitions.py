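"""Segment a single trajectory into confined and free episodes.

A molecule can escape a nanodomain mid-trajectory. A running window of
20 steps yields per-window (α, D_app) series, and a two-state
Gaussian HMM decodes the confined/normal state sequence and the
transition point.
"""

import numpy as np

from condensate_spt.trajectory import Trajectory
from condensate_spt.transitions import hmm_segment, running_window_profile

rng = np.random.default_rng(3)
dt = 0.01

# 80 frames confined in a 0.1-um domain, then 80 frames free diffusion
p = np.zeros(2)
confined = np.empty((80, 2))
for i in range(80):
    p = p + rng.normal(0, np.sqrt(2 * 0.2 * dt), 2)
    r = np.linalg.norm(p)
    while r > 0.1:
        p = p / r * (0.2 - r)
        r = np.linalg.norm(p)
    confined[i] = p
free = confined[-1] + np.cumsum(
    rng.normal(0, np.sqrt(2 * 1.0 * dt), size=(80, 2)), axis=0
)
traj = Trajectory(0, np.arange(160), np.vstack([confined, free]),
                  frame_interval=dt)

series = running_window_profile(traj, window=20)
result = hmm_segment(series, seed=0)

n_conf = int((result.states == 0).sum())
print(f"windows decoded confined: {n_conf}, normal: "
      f"{len(result.states) - n_conf}")
print(f"decoded transition at frame {result.transition_frames[0]} "
      f"(state switch simulated at frame 80)")
print(f"state mean alpha: confined {result.state_means_alpha[0]:.2f}, "
      f"normal {result.state_means_alpha[1]:.2f}")
print()
print("The transition frame marks where the molecule escaped its")
print("nanodomain; localization is limited to about one 20-step window.")
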