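"""Spatial statistics of nanodomains inside condensates.

The pair correlation function G(r) measures how much more (or less)
likely a particle of interest is found at distance r from a reference
particle than under complete spatial randomness; G > 1 indicates
clustering. Inside a finite condensate the annulus around a reference
point may extend past the boundary, where no particle can be found, so
the normalizing ring area is replaced by the annulus∩mask area (edge
correction). Clustering strength is summarized by fitting

    G(r) = 1 + A·exp(−r / R)

with amplitude A and characteristic cluster radius R, and uncertainty
comes from bootstrap resampling of per-condensate curves. Nanodomain
positions relative to the condensate center are summarized by a
ring-area-normalized radial profile that is flat at 1 for a uniform
distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from scipy.optimize import curve_fit
from skimage.feature import blob_log

from .trajectory import DEFAULT_PIXEL_SIZE_UM
from .maps import DensityMap, CondensateROI

__all__ = [
    "PairCorrelationCurve",
    "ExponentialFit",
    "RadialProfile",
    "BootstrapFitResult",
    "ring_area_in_mask",
    "pair_correlation",
    "fit_exponential",
    "aggregate_and_bootstrap",
    "nanodomain_centers",
    "radial_profile",
    "bootstrap_radial",
]

PCF_DR_UM = 0.10
PCF_STEP_UM = 0.02
PCF_R_MAX_UM = 1.0
RADIAL_BIN_WIDTH = 0.05
RADIAL_R_MAX = 1.2
N_BOOTSTRAP = 5000


@dataclass
class PairCorrelationCurve:
    """G(r) samples on the sliding-bin grid.

    ``r`` holds the left edge of each bin [r, r+dr); adjacent bins
    overlap (dr = 0.1 µm, step 0.02 µm), so samples are correlated.
    """

    r: np.ndarray
    g: np.ndarray
    dr: float
    n_ref: int
    n_interest: int
    roi_id: int | str | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class ExponentialFit:
    """Fit of G(r) = 1 + A·exp(−r/R)."""

    amplitude: float
    radius: float
    covariance: np.ndarray | None = None
    success: bool = True
    message: str = ""


@dataclass
class RadialProfile:
    """Ring-area-normalized radial distribution on normalized radius."""

    bin_edges: np.ndarray  # in r / R_condensate
    p_norm: np.ndarray
    n_points: int
    flags: list[str] = field(default_factory=list)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class BootstrapFitResult:
    """Pooled curve fit with bootstrap uncertainty."""

    pooled_r: np.ndarray
    pooled_g: np.ndarray
    fit: ExponentialFit
    a_samples: np.ndarray
    r_samples: np.ndarray
    a_ci: tuple[float, float]
    r_ci: tuple[float, float]
    a_mean: float
    r_mean: float


def _mask_subpixels(
    mask: np.ndarray,
    pixel_size: float,
    origin: tuple[float, float],
    subdivide: int,
) -> np.ndarray:
    """µm coordinates of subpixel centers of all foreground pixels."""
    ys, xs = np.nonzero(mask)
    sub = (np.arange(subdivide) + 0.5) / subdivide
    ox, oy = np.meshgrid(sub, sub)
    x = (xs[:, None] + ox.ravel()[None, :]) * pixel_size + origin[0]
    y = (ys[:, None] + oy.ravel()[None, :]) * pixel_size + origin[1]
    return np.stack([x.ravel(), y.ravel()], axis=1)


def ring_area_in_mask(
    center: Sequence[float],
    r: float,
    dr: float,
    mask: np.ndarray,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    origin: tuple[float, float] = (0.0, 0.0),
    subdivide: int = 8,
) -> float:
    """Area (µm²) of the annulus [r, r+dr) around ``center`` within the mask.

    Computed by counting subpixel centers of the mask falling in the
    annulus; equals the analytic annulus area π((r+dr)² − r²) when the
    annulus lies fully inside the mask.
    """
    if r < 0:
        raise ValueError("r must be >= 0")
    pts = _mask_subpixels(np.asarray(mask, bool), pixel_size, origin, subdivide)
    d = np.linalg.norm(pts - np.asarray(center, float)[None, :], axis=1)
    n_in = int(np.count_nonzero((d >= r) & (d < r + dr)))
    return n_in * (pixel_size / subdivide) ** 2


def _annulus_area(r: np.ndarray, dr: float) -> np.ndarray:
    return math.pi * ((r + dr) ** 2 - r**2)


def pair_correlation(
    ref_points: np.ndarray,
    interest_points: np.ndarray,
    mask: np.ndarray,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    origin: tuple[float, float] = (0.0, 0.0),
    mode: Literal["auto", "cross"] = "auto",
    dr: float = PCF_DR_UM,
    step: float = PCF_STEP_UM,
    r_max: float = PCF_R_MAX_UM,
    edge_correction: bool = True,
    subdivide: int = 4,
    roi_id: int | str | None = None,
) -> PairCorrelationCurve:
    """Edge-corrected auto- or cross-pair correlation within a mask.

    For each sliding bin [r, r+dr), G(r) is the ratio of observed pair
    counts to the count expected at the interest-particle density over
    the (edge-corrected) annulus areas summed over reference points:

        G(r) = Σ_ref N_ref(r) / (ρ_interest · Σ_ref area_ref(r))

    Reference points whose annulus lies fully inside the mask use the
    analytic area; near the boundary the annulus∩mask area is computed
    on a subdivided pixel grid. In auto mode (ref set == interest set)
    self-pairs are excluded.
    """
    ref_points = np.atleast_2d(np.asarray(ref_points, float))
    interest_points = np.atleast_2d(np.asarray(interest_points, float))
    mask = np.asarray(mask, bool)
    flags: list[str] = []
    if len(ref_points) < 2:
        raise ValueError("need at least 2 reference points")
    r_grid = np.round(np.arange(0.0, r_max + step / 2, step), 10)
    if interest_points.size == 0:
        return PairCorrelationCurve(
            r_grid, np.full_like(r_grid, np.nan), dr, len(ref_points), 0,
            roi_id=roi_id, flags=["empty_interest_set"],
        )
    area_roi = float(mask.sum()) * pixel_size**2
    rho = len(interest_points) / area_roi
    # distance of each reference point to the mask boundary (µm)
    edt = distance_transform_edt(mask) * pixel_size
    ix = np.clip(
        np.floor((ref_points[:, 0] - origin[0]) / pixel_size).astype(int),
        0, mask.shape[1] - 1,
    )
    iy = np.clip(
        np.floor((ref_points[:, 1] - origin[1]) / pixel_size).astype(int),
        0, mask.shape[0] - 1,
    )
    dist_boundary = edt[iy, ix]
    subpix = None
    counts = np.zeros_like(r_grid)
    areas = np.zeros_like(r_grid)
    interior_margin = pixel_size  # guard band for the analytic shortcut
    # sliding bins are integer multiples of `step`; counting on a fine grid
    # of width `step` and summing k adjacent cells gives every [r, r+dr) bin
    k = int(round(dr / step))
    use_fine = abs(k * step - dr) < 1e-9
    fine_edges = np.concatenate([r_grid, r_grid[-1] + step * np.arange(1, k + 1)])

    def _bin_counts(d: np.ndarray) -> np.ndarray:
        if use_fine:
            h, _ = np.histogram(d, bins=fine_edges)
            c = np.cumsum(np.concatenate([[0], h]))
            return (c[k:] - c[:-k]).astype(float)
        d = np.sort(d)
        return (
            np.searchsorted(d, r_grid + dr, side="left")
            - np.searchsorted(d, r_grid, side="left")
        ).astype(float)

    for i, p in enumerate(ref_points):
        d = np.linalg.norm(interest_points - p[None, :], axis=1)
        if mode == "auto":
            d = d[d > 0]
        counts += _bin_counts(d)
        if not edge_correction or dist_boundary[i] >= r_max + dr + interior_margin:
            areas += _annulus_area(r_grid, dr)
        else:
            if subpix is None:
                subpix = _mask_subpixels(mask, pixel_size, origin, subdivide)
            dm = np.linalg.norm(subpix - p[None, :], axis=1)
            areas += _bin_counts(dm) * (pixel_size / subdivide) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(areas > 0, counts / (rho * np.maximum(areas, 1e-300)), np.nan)
    return PairCorrelationCurve(
        r_grid, g, dr, len(ref_points), len(interest_points),
        roi_id=roi_id, flags=flags,
    )


def _exp_model(r, a, R):
    return 1.0 + a * np.exp(-r / R)


def fit_exponential(
    curve: PairCorrelationCurve | tuple[np.ndarray, np.ndarray],
    r0_init: float = 0.2,
) -> ExponentialFit:
    """Nonlinear least squares for G(r) = 1 + A·exp(−r/R).

    Initialized at A₀ = G(first valid bin) − 1 and R₀ = 0.2 µm; failures
    are flagged on the returned object, never silently dropped.
    """
    if isinstance(curve, PairCorrelationCurve):
        r, g = curve.r, curve.g
    else:
        r, g = curve
    keep = np.isfinite(g)
    if keep.sum() < 5:
        return ExponentialFit(np.nan, np.nan, success=False,
                              message="fewer than 5 valid bins")
    r, g = np.asarray(r, float)[keep], np.asarray(g, float)[keep]
    a0 = float(g[0] - 1.0)
    try:
        popt, pcov = curve_fit(
            _exp_model, r, g, p0=[a0, r0_init],
            bounds=([-np.inf, 1e-6], [np.inf, np.inf]), maxfev=10000,
        )
    except RuntimeError as err:
        return ExponentialFit(np.nan, np.nan, success=False, message=str(err))
    return ExponentialFit(float(popt[0]), float(popt[1]), covariance=pcov)


def _weighted_mean_curve(
    curves: Sequence[PairCorrelationCurve], weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    r = curves[0].r
    G = np.stack([c.g for c in curves])
    W = np.repeat(np.asarray(weights, float)[:, None], G.shape[1], axis=1)
    W = np.where(np.isfinite(G), W, 0.0)
    G = np.where(np.isfinite(G), G, 0.0)
    denom = W.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = np.where(denom > 0, (W * G).sum(axis=0) / np.maximum(denom, 1e-300),
                          np.nan)
    return r, pooled


def aggregate_and_bootstrap(
    curves: Sequence[PairCorrelationCurve],
    weights: Sequence[float] | None = None,
    n_boot: int = N_BOOTSTRAP,
    seed: int = 0,
) -> BootstrapFitResult:
    """Weighted pooled G(r) with bootstrap (A, R) confidence intervals.

    The pooled curve is the weighted mean of per-condensate curves, the
    weight being each condensate's particle count by default. The
    bootstrap resamples whole condensate curves with replacement,
    refitting (A, R) each round; identical input curves legitimately
    yield a zero-width interval.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 condensate curves")
    if weights is None:
        weights = np.array([c.n_interest for c in curves], float)
    else:
        weights = np.asarray(weights, float)
    r, pooled = _weighted_mean_curve(curves, weights)
    fit = fit_exponential((r, pooled))
    rng = np.random.default_rng(seed)
    a_s = np.empty(n_boot)
    r_s = np.empty(n_boot)
    idx_all = np.arange(len(curves))
    for b in range(n_boot):
        idx = rng.choice(idx_all, size=len(curves), replace=True)
        _, gb = _weighted_mean_curve([curves[i] for i in idx], weights[idx])
        fb = fit_exponential((r, gb))
        a_s[b] = fb.amplitude
        r_s[b] = fb.radius
    ok = np.isfinite(a_s) & np.isfinite(r_s)
    a_ok, r_ok = a_s[ok], r_s[ok]
    return BootstrapFitResult(
        pooled_r=r, pooled_g=pooled, fit=fit,
        a_samples=a_s, r_samples=r_s,
        a_ci=(float(np.percentile(a_ok, 2.5)), float(np.percentile(a_ok, 97.5))),
        r_ci=(float(np.percentile(r_ok, 2.5)), float(np.percentile(r_ok, 97.5))),
        a_mean=float(a_ok.mean()), r_mean=float(r_ok.mean()),
    )


def nanodomain_centers(
    dmap: DensityMap | None = None,
    classified=None,
    method: Literal["puncta", "confined-centroid"] = "puncta",
    min_sigma_px: float = 1.0,
    max_sigma_px: float = 4.0,
    threshold: float = 2.0,
) -> np.ndarray:
    """Nanodomain center estimates, µm, shape (m, 2); may be empty.

    ``puncta``: Laplacian-of-Gaussian blob detection on the density map.
    ``confined-centroid``: centroid of each confined-classified
    trajectory (pass the output of ``classify_trajectories``).
    """
    if method == "puncta":
        if dmap is None:
            raise ValueError("puncta method needs a density map")
        img = dmap.counts.astype(float)
        blobs = blob_log(
            img, min_sigma=min_sigma_px, max_sigma=max_sigma_px,
            num_sigma=8, threshold=threshold,
        )
        if len(blobs) == 0:
            return np.empty((0, 2))
        xy = np.stack(
            [
                dmap.origin[0] + (blobs[:, 1] + 0.5) * dmap.pixel_size,
                dmap.origin[1] + (blobs[:, 0] + 0.5) * dmap.pixel_size,
            ],
            axis=1,
        )
        return xy
    if method == "confined-centroid":
        if classified is None:
            raise ValueError("confined-centroid method needs classified trajectories")
        pts = [
            ct.trajectory.xy.mean(axis=0)
            for ct in classified
            if ct.category == "confined"
        ]
        return np.array(pts) if pts else np.empty((0, 2))
    raise ValueError(f"unknown method {method!r}")


def radial_profile(
    points: np.ndarray,
    center: Sequence[float],
    condensate_radius: float,
    bin_width: float = RADIAL_BIN_WIDTH,
    r_max: float = RADIAL_R_MAX,
) -> RadialProfile:
    """Ring-area-normalized radial distribution of points in a condensate.

    Distances to the condensate center are normalized by the condensate
    radius (from its area, assuming a circle), binned, and each bin's
    probability divided by its expected share under uniformity over the
    unit disk (the annulus area fraction b² − a²), so uniform points give
    a flat profile at 1. Points beyond ``r_max`` × radius are flagged and
    dropped.
    """
    points = np.atleast_2d(np.asarray(points, float))
    if points.size == 0:
        raise ValueError("need at least one point")
    d = np.linalg.norm(points - np.asarray(center, float)[None, :], axis=1)
    u = d / condensate_radius
    flags: list[str] = []
    if np.any(u > r_max):
        flags.append("points_outside_range")
    edges = np.round(np.arange(0.0, r_max + bin_width / 2, bin_width), 10)
    counts, _ = np.histogram(u, bins=edges)
    p = counts / len(u)
    expected = edges[1:] ** 2 - edges[:-1] ** 2  # uniform-disk share per bin
    p_norm = p / expected
    return RadialProfile(edges, p_norm, n_points=len(u), flags=flags)


def bootstrap_radial(
    profiles: Sequence[RadialProfile],
    n_boot: int = N_BOOTSTRAP,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bootstrap mean and 95% band over per-condensate radial profiles.

    Returns (mean, lower, upper) per bin from ``n_boot`` resamples of the
    profile pool with replacement.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    P = np.stack([p.p_norm for p in profiles])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(profiles), size=(n_boot, len(profiles)))
    means = P[idx].mean(axis=1)
    return (
        means.mean(axis=0),
        np.percentile(means, 2.5, axis=0),
        np.percentile(means, 97.5, axis=0),
    )


def curves_to_frame(curves: Sequence[PairCorrelationCurve]) -> pd.DataFrame:
    """Tidy export of G(r) curves (roi_id, r, value, n)."""
    rows = []
    for c in curves:
        rows.append(
            pd.DataFrame(
                {"roi_id": c.roi_id, "r_um": c.r, "g": c.g, "n": c.n_interest}
            )
        )
    return pd.concat(rows, ignore_index=True)
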