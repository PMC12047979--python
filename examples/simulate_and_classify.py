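"""Simulate a labeled three-class mixture and run the diffusion classifier.

Molecules inside a condensate are immobile, confined to nanodomains, or
freely (normally) diffusing. The classifier separates them using the
mean step size (30 nm immobile threshold) and the anomalous exponent α
from a log-log MSD fit (α < 0.7 confined, R² < 0.7 excluded).
"""

import numpy as np

from condensate_spt import classify_trajectories, category_fractions, step_angles
from condensate_spt.simulate import (
    Nanodomain, Scene, SimParams, simulate_trajectories,
)

scene = Scene(
    condensate_center=(5.0, 5.0),
    condensate_radius=5.0,
    nanodomains=[
        Nanodomain((4.2, 4.4), 0.12),
        Nanodomain((5.6, 5.4), 0.10),
        Nanodomain((5.0, 6.2), 0.15),
    ],
)
params = SimParams(
    D_free=1.0, D_confined=0.2, p_immobile=0.2, p_confined=0.4,
    n_trajectories=400, mean_length=30, min_length=20, seed=7,
)
sims = simulate_trajectories(scene, params)
classified = classify_trajectories([s.trajectory for s in sims])

fractions = category_fractions(classified, include_excluded=True)
print("category fractions:", {k: round(v, 3) for k, v in fractions.items()})

mobile = [c for c in classified if c.category in ("confined", "normal")]
alphas = [c.alpha for c in mobile]
angles = np.concatenate(
    [step_angles(c.trajectory) for c in mobile if len(c.trajectory) >= 3]
)
print(f"mean alpha (mobile): {np.mean(alphas):.2f}")
print(f"mean step angle (mobile): {angles.mean():.1f} deg")
print()
print("Confined + immobile fractions report how strongly the condensate")
print("retains molecules; a mean angle above 90 deg signals the")
print("back-and-forth motion of nanodomain-confined diffusion.")
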