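# Methods

This note records the models, estimators, defaults, and numerical choices
behind `condensate_spt`, and what the synthetic-data generator does and
does not emulate.

## Physical picture and units

Molecules diffuse in 2D inside a disk-shaped condensate of radius ~1–5 µm.
Sub-condensate nanodomains — disks of radius ~0.1–0.3 µm — restrict
diffusion without a density transition. All lengths are µm, times s,
diffusion coefficients µm²/s. The camera grid is 117 nm/pixel; pixel
centers sit at integer pixel coordinates, origin top-left, x rightward,
y downward; positions are exported in µm (px × 0.117).

## Synthetic-data generator

`simulate.simulate_trajectories` draws, per molecule, a class
(immobile / confined / normal, optionally a two-state switcher), a start
position, and a track length, then integrates Brownian steps with
per-axis variance 2DΔt_sub:

- **Immobile**: a fixed point observed through localization noise only.
- **Confined**: reflected hard at its nanodomain boundary. The paper-level
  description gives no confinement potential, so hard reflection at a disk
  is the default; an Ornstein–Uhlenbeck ("spring") mode with stiffness
  4D/r² (stationary SD = r/2 per axis) is available for robustness checks.
- **Normal**: free diffusion, reflected at the condensate boundary.
- **Switching**: alternates confined ↔ normal; escape is a per-frame
  Bernoulli event with the domain's `escape_prob`, capture occurs when the
  molecule steps inside a domain (probability `capture_prob`).

Motion blur is emulated by averaging `subframe_steps` sub-positions per
frame (default 100 when blur is on, 1 when off); independent Gaussian
localization noise (default SD 16 nm, the static localization error of
surface-fixed molecules) is added afterwards. Identical seeds give
bit-identical output.

Key defaults and why:

- **Frame interval 10 ms.** The imaging frame rate is a free parameter of
  the emulation. At the dilute-phase D ≈ 10 µm²/s the rms frame step is
  √(4DΔt) ≈ 0.63 µm ≈ 5.4 px, compatible with the 15-px dilute-phase
  linking radius; a 100 ms interval would not be.
- **Track lengths: geometric, mean 20 frames, truncated at ≥ 5
  localizations**, mimicking photobleaching-limited tracks. The real
  length distribution is not published; the sensitivity of downstream
  statistics to this choice is discussed below.
- **D_free = 1 µm²/s** (condensed-phase scale; the dilute-phase regime
  uses 10), **D_confined = 0.2 µm²/s**: confined molecules diffuse slowly
  locally, and at this value the domain-crossing time r²/4D (~15–30 ms
  for r = 0.1–0.15 µm) is resolvable within a track, which is the regime
  in which confinement is experimentally detectable at all. Much faster
  local diffusion plateaus the MSD within one frame and produces tracks
  that the classifier (correctly) excludes as unreliably flat.

The generator does **not** emulate: 3D motion and defocus, photophysics
(blinking), non-Gaussian localization errors, anisotropic illumination
("lensing" stripes), or channel registration errors. Tests passing on
synthetic data therefore validate the estimators' correctness, not
robustness to those instrument effects.

`render_video` draws each localization as an isotropic Gaussian PSF spot
(integrated `photons` per spot) over a constant background with Poisson
photon noise and Gaussian read noise, for end-to-end detection tests.
`simulate_force_trace` produces F(t) = A + B·e^(−(t−t₀)/τ) + C·t after a
configurable onset t₀, continuous with the pre-onset baseline A + B + C·t.

## Detection and linking

Band-pass filtering is a per-frame difference of Gaussians (σ = 1 and
3 px, in-focus vs slightly defocused molecule). Detection is
Laplacian-of-Gaussian at the scale implied by a 5-px object diameter
(σ = d/(2√2)); **quality** is defined as the scale-normalized LoG
response at the local maximum (the upstream tool leaves its quality
metric undefined; only its threshold, 5, is printed). Subpixel positions
come from separable 3×3 quadratic peak interpolation, offsets clipped to
±0.5 px. `auto_quality_threshold` finds the first substantive valley
(valley < half of both flanking peaks of the smoothed histogram) above
the dominant low-quality mode, falling back to the fixed threshold 5
when the histogram is not bimodal.

Linking is frame-to-frame optimal bipartite assignment on squared
distance with a hard gate (5 px intra-condensate, 15 px dilute phase),
using the augmented birth/death matrix (alternative cost 1.05 × gate²)
so any feasible link beats a termination; no gap closing — a missed
frame always terminates a track. A greedy nearest-pair mode is provided
for speed. Ties are resolved deterministically by the assignment solver.

## Diffusion profiling

The MSD is time-averaged over all overlapping pairs; lags run to half
the trajectory length, never fewer than 4 points (capped at n−1).
α is the unweighted least-squares slope of log MSD vs log τ;
non-positive MSD points are dropped. Classification order: immobile
(mean step < 30 nm) → excluded (fit failed or R² < 0.7) → confined
(α < 0.7) → normal; α exactly 0.7 is normal. Pair counts per lag are
recorded but the fits are unweighted, matching the plain least-squares
formulas of the printed procedure.

Two known statistical properties matter when interpreting outputs:

- **The α estimator is biased low by ≈ 0.05** on Brownian motion (mean
  ≈ 0.94–0.95) irrespective of track length: the largest lags of a
  time-averaged MSD always contain ~2 independent increments, and the
  log transform of that noisy tail biases the slope down (Jensen).
- **Single-track α has SD ≈ 0.2–0.3** for tracks of tens of steps, so
  ~18–22% of genuinely Brownian tracks fall below the 0.7 threshold
  (after the R² filter). This false-confinement rate is exactly what the
  random-walk control measures, and it caps per-class recall of the
  three-way classifier near 80% for the normal class. It is insensitive
  to D, Δt, and the length distribution (the α distribution is
  dimensionless); mean lengths 10–30 move it by only ±3 points.

D and σ for normal tracks come from the blur-corrected linear model
MSD(τ) = 4Dτ + 4σ² − 8DRΔt with R = 1/6 for continuous exposure (the
per-axis form is the standard 2Dτ + 2σ² − 4DRΔt). D and σ² are clipped
at 0 with flags. Recovering R ≈ 1/6 from continuously-exposed simulated
motion via the intercept is an acceptance check of this model. Note the
σ² intercept is a small difference of large numbers: at D = 1 µm²/s and
Δt = 10 ms it is ~2% of MSD(1), so pooled fits need ~10⁵–10⁶
displacements to pin σ to 10%.

The state-array spectrum treats each trajectory's summed squared 2D
displacements as Gamma(shape = n_steps, scale = 4(DΔt + σ² − 2DRΔt))
under state D, on a 64-point log grid over 0.01–100 µm²/s, and estimates
occupations by EM with a symmetric Dirichlet(1.01) prior (tolerance
1e−8 on the log-likelihood, ≤ 500 iterations). It is a grid-likelihood
re-implementation of the state-array idea, not a port of the original
variational scheme; correlations between successive displacements from
shared localization noise are neglected.

Step angles are folded to [0°, 180°] regardless of turn direction;
zero-length steps are skipped. An isotropic walk averages 90°; confined
motion trends above.

## Maps and condensate qualification

The localization pool samples at most 10 localizations (uniformly,
without replacement, seeded) from any trajectory longer than 10 steps;
shorter trajectories pass whole. Density maps are half-open 2D
histograms on the camera grid (edge points go to the higher bin).
Step-size heatmaps assign each step's length to the pixel containing the
step's midpoint (the literal "center of step"); empty pixels are NaN and
per-pixel step counts are kept as weights. Segmentation: smooth the
whole-field density map (Gaussian σ = 1 px), threshold at 10 locations
per pixel, connected components, discard < 200 px, crop with 3-px
padding; re-segmenting a cropped map reproduces the mask.

The weighted Pearson correlation uses weighted means and weighted
central moments (the statistically standard weighted PCC); weights are
squared localization counts, by default the two channels' summed counts
squared (the printed definition does not name a channel; per-channel
modes are provided). NaN pixels are excluded, not zero-filled.
Circularity is 4πA/P² from the marching-squares contour smoothed with a
3-sample circular moving average (the raw contour staircases along the
pixel grid and inflates P by ~6% for a disk); masks touching the crop
border are flagged. An intensity-second-moment anisotropy score is
exported to assist manual review of stripe-like ("lensing") artifacts;
no automatic rejection is performed.

## Pair correlation and radial statistics

G(r) uses sliding bins [r, r+dr), dr = 0.1 µm, step 0.02 µm, r from 0 to
1 µm. The estimator is the ratio of summed pair counts to summed
expected counts, G(r) = Σ_ref N(r) / (ρ Σ_ref area(r)), with the annulus
area computed exactly as π((r+dr)² − r²) when the annulus lies fully
inside the condensate (checked against the mask's Euclidean distance
transform with a one-pixel guard band) and otherwise as the
annulus∩mask area counted on a subdivided pixel grid (default 4×4
subpixels; the `ring_area_in_mask` primitive defaults to 8×8). The
linearized ring area 2πr·dr is *not* used: it is biased by dr/2r (50% in
the first bin) and would break the complete-spatial-randomness
normalization G ≈ 1. Auto-correlation excludes self-pairs;
ρ = N_interest / condensate area. Reference points whose annulus lies
fully outside the mask contribute zero to both sums.

Overlapping bins produce correlated G samples; the exponential fit
G(r) = 1 + A·e^(−r/R) (initialized A₀ = G(0) − 1, R₀ = 0.2 µm, R bounded
positive) treats them as independent, as the printed procedure implies,
and honest uncertainty comes instead from bootstrap over condensates:
curves are resampled with replacement (5,000 rounds by default), the
weighted mean curve refit each round, and percentile intervals reported.
The per-condensate weight is its particle count. Resampling curves with
replacement is non-parametric; the source procedure calls it "parametric
bootstrapping", a nomenclature mismatch noted here.

Nanodomain centers come either from LoG blob detection on the density
map ("puncta") or from centroids of confined-classified trajectories;
both agree to ~2 px on strong-trap simulations. Radial profiles
normalize each point's distance to the condensate center by the
equivalent radius (from area, circle assumption), bin at 0.05 in
normalized radius over [0, 1.2], and divide each bin's probability by
its uniform-disk share (b² − a²), so uniformity is flat at 1. Points
beyond 1.2 R are flagged and dropped. The radial bootstrap resamples
per-condensate profiles with replacement.

## Transitions

The running window is 20 steps, stride 1; each window is fit with the
same MSD → α and MSD → D estimators (blur R = 0 within windows by
default). The two-state HMM has Gaussian emissions on (α, log₁₀ D_app)
— both features by default, single-feature modes available since the
source does not state which was used — diagonal covariances, k-means
initialization, 10 seeded restarts with best-likelihood selection,
sticky initial transitions (0.98 self), and 1e−4 log-likelihood
tolerance. States are canonically labeled by mean α (lower = confined).
Because adjacent windows share all but one step, the feature series is
autocorrelated on the window scale; decoded dwells shorter than half a
window are merged into their neighbors, and transitions are localized
to about one window length (the transition point is reported as the
first frame of the first window in the new state). A constant series
returns one state and no transitions.

## Fusion rheology

Events are found by block-mean downsampling 50 kHz → 5 Hz, taking the
gradient, and selecting the largest absolute peak; a trace whose peak is
below 5× the median absolute gradient (e.g. flat or pure linear drift)
is reported as event-free rather than force-fit. Because τ (~50 ms) is
much shorter than a 0.2 s coarse block, the onset is refined by
repeating the gradient search at 1 kHz within ±1 coarse block. The model
F = A + B·e^(−t/τ) + C·t is fit by nonlinear least squares on full-rate
data over a 1 s window from the onset (window length is not specified by
the source; it is config-exposed), τ initialized from the 1/e point of
the block-averaged decay and bounded positive. A is the measurement
background, C the trap-interference drift; τ is invariant to both.
Non-fusing or degenerate traces are flagged, never silently dropped —
replacing the source's manual inspection with an explicit flag system.
Otsu thresholding of a confocal frame gives the condensate area (largest
connected component × pixel area), with a flag when the intensity
histogram shows no usable bimodality.

## Pipeline

`pipeline.run_intra_condensate` composes simulate/load → classify →
pool/density map → segment → per-condensate statistics → pooled
bootstrap, with per-condensate failures recorded in the report rather
than aborting the run. All randomness derives from one root seed through
per-stage SHA-256 streams (< 2³¹). The config (minus the output
directory) is hashed; every output file carries the hash, and re-running
the same config reproduces a byte-identical report body.
`run_dilute` switches to the 15-px linking radius and skips condensate
segmentation. Problem sizes in the test suite (hundreds to a few
thousand trajectories, single condensates) are chosen to give each
statistic enough power for its stated tolerance while keeping the full
suite fast on one CPU.

## Known limitations

- The classifier's false-confinement rate on pure Brownian motion
  (~18% at the standard conditions) is a property of short-track α
  fitting, not a bug; population confined fractions should be read
  against this baseline.
- The state array assumes a single frame interval across trajectories
  and neglects noise-induced displacement correlations.
- Edge-corrected G(r) assumes the condensate mask is accurate; mask
  errors of a pixel translate into percent-level area errors near the
  boundary.
- No 3D corrections anywhere: axial motion out of the HILO sheet appears
  as track termination.
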