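"""Density-map reconstruction and nanodomain spatial statistics.

Pools trajectory localizations (max 10 per trajectory to suppress
oversampling), bins them onto the 117-nm camera grid, segments the
condensate, and quantifies nanodomain clustering with the
edge-corrected pair correlation function G(r) = 1 + A·exp(−r/R) and
the ring-area-normalized radial profile.
"""

import numpy as np

from condensate_spt.maps import (
    circularity, density_map, segment_condensates, subsample_pool,
)
from condensate_spt.simulate import (
    Nanodomain, Scene, SimParams, simulate_trajectories,
)
from condensate_spt.spatial import (
    fit_exponential, nanodomain_centers, pair_correlation, radial_profile,
)

scene = Scene(
    condensate_center=(2.0, 2.0),
    condensate_radius=1.5,
    nanodomains=[
        Nanodomain((1.4, 1.6), 0.12),
        Nanodomain((2.5, 2.4), 0.10),
        Nanodomain((2.0, 2.9), 0.15),
    ],
)
params = SimParams(
    D_free=1.0, D_confined=0.2, p_confined=0.6,
    n_trajectories=1500, mean_length=25, seed=21,
)
sims = simulate_trajectories(scene, params)
trajs = [s.trajectory for s in sims]

pool = subsample_pool(trajs, seed=1)
dmap = density_map(pool)
rois = segment_condensates(dmap)
print(f"pooled localizations: {len(pool)}; qualified condensates: {len(rois)}")

roi = rois[0]
circ, _ = circularity(roi.mask)
print(f"condensate area: {roi.area_um2:.2f} um^2, "
      f"equivalent radius: {roi.equivalent_radius_um:.2f} um, "
      f"circularity: {circ:.2f}")

r0, c0, r1, c1 = roi.bbox
origin = (c0 * dmap.pixel_size, r0 * dmap.pixel_size)
pts = pool.points[["x_um", "y_um"]].to_numpy()
curve = pair_correlation(pts, pts, roi.mask, origin=origin, mode="auto")
fit = fit_exponential(curve)
print(f"G(r) fit: clustering amplitude A = {fit.amplitude:.2f}, "
      f"radius R = {fit.radius * 1000:.0f} nm")

centers = nanodomain_centers(dmap, method="puncta", threshold=3.0)
prof = radial_profile(centers, roi.centroid_um, roi.equivalent_radius_um)
peak_bin = prof.bin_centers[np.argmax(prof.p_norm)]
print(f"nanodomain puncta: {len(centers)}; radial profile peaks at "
      f"r/R = {peak_bin:.2f}")
print()
print("A > 0 means molecules cluster above a random distribution; R is")
print("the nanodomain length scale. A flat radial profile at 1 would mean")
print("nanodomains sit uniformly through the condensate.")
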