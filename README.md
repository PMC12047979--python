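# condensate-spt

Analysis toolkit for **intra-condensate single-particle tracking (SPT)**:
quantifying how individual protein and RNA molecules diffuse inside
biomolecular condensates, where nanometer-scale regions of restricted
diffusion ("nanodomains") retain molecules without any visible density
transition. It is written for biophysicists who image sparse fluorescent
molecules inside reconstituted (or tethered) condensates and want to turn
trajectory tables or raw TIFF videos into diffusion classes, nanodomain
maps, spatial statistics, and rheological constants — with a synthetic-data
generator that provides ground truth for every stage.

## What it computes

**Trajectory classification.** Each trajectory is labeled *immobile*
(mean step < 30 nm, about twice the 16 nm static localization error),
*confined* (anomalous exponent α < 0.7), or *normal* (α ≥ 0.7), with an
R² ≥ 0.7 reliability filter. α comes from the time-averaged MSD on log-log
axes,

    log MSD(τ) = α·log τ + log(2nD),    n = 2,

fit over lags up to half the trajectory length (minimum 4 lag points).
For normal trajectories the apparent diffusion coefficient D and the
localization error σ are extracted from the motion-blur-corrected linear
model

    MSD(τ) = 4Dτ + 4σ² − 8DRΔt,

with blur coefficient R = 1/6 for continuous full-frame exposure. A
state-array spectrum (gamma jump likelihood on a log-spaced D grid +
EM with a weak Dirichlet prior) estimates the population distribution of D.

**Maps and spatial statistics.** Localizations are pooled (≤ 10 per
trajectory, to stop single long trajectories from faking puncta), binned
on the 117-nm camera grid into density maps and step-size heatmaps, and
condensates are segmented (Gaussian σ = 1 px smooth, 10 locations/pixel
threshold, ≥ 200 px area). Nanodomain clustering is quantified by the
edge-corrected pair correlation function

    G(r) = N_interest(r) / (N_ref · ρ_interest · ring area),

with the ring area replaced by the annulus∩condensate area near the
boundary, fit with G(r) = 1 + A·e^(−r/R), and bootstrapped over
condensates. Radial nanodomain profiles are ring-area normalized (flat at
1 for a uniform distribution). Image pairs are compared by a weighted
pixel-wise Pearson correlation (weights = squared localization counts).

**Within-trajectory transitions.** A running window (20 steps) yields
(α, D_app) series; a two-state Gaussian HMM decodes confined/normal
episodes and the transition frames.

**Fusion rheology.** Dual-trap force traces (50 kHz) of droplet fusion
are fit with F(t) = A + B·e^(−t/τ) + C·t after gradient-based event
detection; τ is the characteristic fusion time (viscosity over surface
tension).

## Worked example

```bash
python examples/simulate_and_classify.py
```

```
category fractions: {'immobile': 0.142, 'confined': 0.172, 'normal': 0.335, 'excluded': 0.35}
mean alpha (mobile): 0.81
mean step angle (mobile): 93.7 deg
```

400 simulated molecules (20% immobile, 40% nanodomain-confined, rest
free) were classified from their trajectories alone. Strongly confined
trajectories have nearly flat MSDs whose log-log fits fail the R² filter,
so a large excluded bin accompanies a high confined load — the same
behavior seen in real intra-condensate data. A mean step angle above 90°
reflects the back-and-forth motion of confined molecules.

```bash
python examples/fusion_rheology.py
```

```
fusion onset detected at t = 2.00 s (simulated at 2.00 s)
tau = 50.9 ms (ground truth 51.0 ms), r^2 = 0.940
```

The other examples cover end-to-end video tracking
(`track_video.py`), nanodomain spatial statistics
(`nanodomain_statistics.py`), and HMM state segmentation
(`state_transitions.py`). A thin CLI wraps the same pipeline:
`condensate-spt run-all --scene-config scene.yaml --out-dir results`.

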