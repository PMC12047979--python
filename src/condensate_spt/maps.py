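"""Localization-density maps, step-size heatmaps, and condensate ROIs.

Trajectory localizations are pooled — with at most 10 points sampled per
trajectory so that a single long trajectory cannot masquerade as a
high-density punctum — and binned back onto the camera's 117-nm pixel
grid. The resulting density map is the super-resolved picture of where
molecules spent time: nanodomains appear as bright puncta. Condensates
are segmented from the whole-field map (Gaussian smooth, fixed count
threshold, minimum area), and per-condensate image pairs are compared by
a weighted pixel-wise Pearson correlation whose weights reflect how many
localizations support each pixel.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter
from skimage.measure import find_contours, label as sk_label, regionprops

from .trajectory import Trajectory, DEFAULT_PIXEL_SIZE_UM

__all__ = [
    "LocalizationPool",
    "DensityMap",
    "StepSizeHeatmap",
    "CondensateROI",
    "subsample_pool",
    "density_map",
    "stepsize_heatmap",
    "segment_condensates",
    "weighted_pcc",
    "pcc_weights",
    "circularity",
    "anisotropy_score",
]

MAX_POINTS_PER_TRAJECTORY = 10
SEGMENT_SMOOTH_SIGMA = 1.0
SEGMENT_THRESHOLD = 10.0
SEGMENT_MIN_AREA_PX = 200
SEGMENT_PADDING_PX = 3


@dataclass
class LocalizationPool:
    """Subsampled localizations (µm) with their source trajectory ids."""

    points: pd.DataFrame  # columns: x_um, y_um, trajectory_id
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class DensityMap:
    """Per-pixel localization counts on the camera grid.

    ``origin`` is the µm coordinate of the (0, 0) pixel's lower corner;
    pixel bins are half-open: [i·px, (i+1)·px).
    """

    counts: np.ndarray  # (ny, nx), int
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    origin: tuple[float, float] = (0.0, 0.0)


@dataclass
class StepSizeHeatmap:
    """Per-pixel mean step length (µm); NaN where no step midpoint fell."""

    mean_step: np.ndarray
    n_steps: np.ndarray  # per-pixel step counts, usable as weights
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    origin: tuple[float, float] = (0.0, 0.0)


@dataclass
class CondensateROI:
    """One qualified condensate from whole-field segmentation."""

    mask: np.ndarray  # cropped boolean mask
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1) incl. padding
    area_px: int
    centroid_um: tuple[float, float]  # (x, y) in FOV coordinates
    equivalent_radius_um: float  # radius of a circle with the same area
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    label: int = 0

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size**2


def subsample_pool(
    trajectories: Sequence[Trajectory],
    seed: int = 0,
    max_points: int = MAX_POINTS_PER_TRAJECTORY,
) -> LocalizationPool:
    """Pool localizations, capping long trajectories' contributions.

    Trajectories longer than ``max_points`` steps contribute exactly
    ``max_points`` localizations, sampled uniformly without replacement;
    shorter trajectories pass all their localizations along. This
    suppresses oversampling, so puncta in the density map reflect
    confinement rather than single long trajectories.
    """
    rng = np.random.default_rng(seed)
    xs, ys, ids = [], [], []
    for t in trajectories:
        if t.n_steps > max_points:
            idx = np.sort(rng.choice(len(t), size=max_points, replace=False))
        else:
            idx = np.arange(len(t))
        xs.append(t.xy[idx, 0])
        ys.append(t.xy[idx, 1])
        ids.append(np.full(len(idx), t.id, dtype=object))
    if not xs:
        df = pd.DataFrame(columns=["x_um", "y_um", "trajectory_id"])
    else:
        df = pd.DataFrame(
            {
                "x_um": np.concatenate(xs),
                "y_um": np.concatenate(ys),
                "trajectory_id": np.concatenate(ids),
            }
        )
    return LocalizationPool(points=df, seed=seed)


def _grid_shape(x, y, pixel_size, origin, shape):
    if shape is not None:
        return shape
    nx = int(np.floor((x.max() - origin[0]) / pixel_size)) + 1 if len(x) else 1
    ny = int(np.floor((y.max() - origin[1]) / pixel_size)) + 1 if len(y) else 1
    return (ny, nx)


def density_map(
    pool: LocalizationPool,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    origin: tuple[float, float] = (0.0, 0.0),
    shape: tuple[int, int] | None = None,
) -> DensityMap:
    """Bin pooled localizations onto the pixel grid (2D histogram).

    Half-open bins: a point exactly on a bin edge belongs to the higher
    bin. Total counts equal the pool size for points inside the grid.
    """
    if len(pool) == 0:
        raise ValueError("empty localization pool")
    x = pool.points["x_um"].to_numpy()
    y = pool.points["y_um"].to_numpy()
    ny, nx = _grid_shape(x, y, pixel_size, origin, shape)
    ix = np.floor((x - origin[0]) / pixel_size).astype(int)
    iy = np.floor((y - origin[1]) / pixel_size).astype(int)
    ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    counts = np.zeros((ny, nx), dtype=np.int64)
    np.add.at(counts, (iy[ok], ix[ok]), 1)
    return DensityMap(counts, pixel_size=pixel_size, origin=origin)


def stepsize_heatmap(
    trajectories: Sequence[Trajectory],
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    origin: tuple[float, float] = (0.0, 0.0),
    shape: tuple[int, int] | None = None,
    max_steps_per_trajectory: int | None = None,
    seed: int = 0,
) -> StepSizeHeatmap:
    """Per-pixel mean step length, each step assigned to its midpoint pixel.

    The "center of step" is the midpoint of the two endpoint positions.
    Pixels with no steps are NaN; per-pixel step counts are retained as
    weights for downstream correlation analysis. Set
    ``max_steps_per_trajectory`` to cap long trajectories' contributions
    the same way the localization pool does.
    """
    rng = np.random.default_rng(seed)
    mids_x, mids_y, lens = [], [], []
    for t in trajectories:
        if t.n_steps == 0:
            continue
        steps = t.steps()
        mid = 0.5 * (t.xy[1:] + t.xy[:-1])
        ln = np.linalg.norm(steps, axis=1)
        if max_steps_per_trajectory is not None and len(ln) > max_steps_per_trajectory:
            idx = np.sort(
                rng.choice(len(ln), size=max_steps_per_trajectory, replace=False)
            )
            mid, ln = mid[idx], ln[idx]
        mids_x.append(mid[:, 0])
        mids_y.append(mid[:, 1])
        lens.append(ln)
    if not lens:
        raise ValueError("no steps in input")
    x = np.concatenate(mids_x)
    y = np.concatenate(mids_y)
    ln = np.concatenate(lens)
    ny, nx = _grid_shape(x, y, pixel_size, origin, shape)
    ix = np.floor((x - origin[0]) / pixel_size).astype(int)
    iy = np.floor((y - origin[1]) / pixel_size).astype(int)
    ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    total = np.zeros((ny, nx))
    count = np.zeros((ny, nx), dtype=np.int64)
    np.add.at(total, (iy[ok], ix[ok]), ln[ok])
    np.add.at(count, (iy[ok], ix[ok]), 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return StepSizeHeatmap(mean, count, pixel_size=pixel_size, origin=origin)


def segment_condensates(
    dmap: DensityMap,
    smooth_sigma: float = SEGMENT_SMOOTH_SIGMA,
    threshold: float = SEGMENT_THRESHOLD,
    min_area_px: int = SEGMENT_MIN_AREA_PX,
    padding_px: int = SEGMENT_PADDING_PX,
) -> list[CondensateROI]:
    """Segment qualified condensates from a whole-field density map.

    Pipeline: Gaussian smooth (σ = 1 px) → threshold at 10 locations per
    pixel → connected components → discard components smaller than
    200 px → crop each survivor with 3-px padding. The equivalent radius
    assumes a circular condensate of the same area.
    """
    smoothed = gaussian_filter(dmap.counts.astype(float), smooth_sigma)
    fg = smoothed >= threshold
    labels = sk_label(fg, connectivity=2)
    rois: list[CondensateROI] = []
    ny, nx = labels.shape
    for rp in regionprops(labels):
        if rp.area < min_area_px:
            continue
        r0, c0, r1, c1 = rp.bbox
        r0p, c0p = max(r0 - padding_px, 0), max(c0 - padding_px, 0)
        r1p, c1p = min(r1 + padding_px, ny), min(c1 + padding_px, nx)
        mask = labels[r0p:r1p, c0p:c1p] == rp.label
        cy, cx = rp.centroid
        rois.append(
            CondensateROI(
                mask=mask,
                bbox=(r0p, c0p, r1p, c1p),
                area_px=int(rp.area),
                centroid_um=(
                    dmap.origin[0] + (cx + 0.5) * dmap.pixel_size,
                    dmap.origin[1] + (cy + 0.5) * dmap.pixel_size,
                ),
                equivalent_radius_um=math.sqrt(rp.area / math.pi) * dmap.pixel_size,
                pixel_size=dmap.pixel_size,
                label=int(rp.label),
            )
        )
    return rois


def pcc_weights(
    counts_x: np.ndarray,
    counts_y: np.ndarray | None = None,
    mode: str = "joint",
) -> np.ndarray:
    """Reliability weights for the weighted PCC: squared location counts.

    ``joint`` (default) squares the summed counts of both channels;
    ``x`` / ``y`` square a single channel's counts.
    """
    if mode == "joint":
        total = counts_x if counts_y is None else counts_x + counts_y
        return total.astype(float) ** 2
    if mode == "x" or counts_y is None:
        return counts_x.astype(float) ** 2
    if mode == "y":
        return counts_y.astype(float) ** 2
    raise ValueError(f"unknown weight mode {mode!r}")


def weighted_pcc(
    image_x: np.ndarray,
    image_y: np.ndarray,
    weights: np.ndarray,
) -> float:
    """Weighted pixel-wise Pearson correlation coefficient.

    Uses weighted means and weighted central moments; pixels with NaN in
    either image (missing data, e.g. step-free heatmap pixels) are
    excluded rather than zero-filled. Symmetric in the two images and
    invariant to affine rescaling of either.
    """
    x = np.asarray(image_x, float).ravel()
    y = np.asarray(image_y, float).ravel()
    w = np.asarray(weights, float).ravel()
    if not (x.shape == y.shape == w.shape):
        raise ValueError("images and weights must have the same shape")
    keep = np.isfinite(x) & np.isfinite(y) & (w > 0)
    if keep.sum() < 2:
        raise ValueError("need at least 2 pixels with positive weight")
    x, y, w = x[keep], y[keep], w[keep]
    wsum = w.sum()
    xm = np.sum(w * x) / wsum
    ym = np.sum(w * y) / wsum
    cov = np.sum(w * (x - xm) * (y - ym))
    vx = np.sum(w * (x - xm) ** 2)
    vy = np.sum(w * (y - ym) ** 2)
    if vx == 0 or vy == 0:
        raise ValueError("zero variance in a weighted image")
    return float(cov / math.sqrt(vx * vy))


def circularity(mask: np.ndarray) -> tuple[float, list[str]]:
    """Shape circularity 4π·A/P² of a connected binary mask.

    Area and perimeter come from the subpixel marching-squares contour
    (level 0.5), so an ideal disk approaches 1 in the continuum limit.
    A mask touching its crop border is flagged (its contour is clipped).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    flags: list[str] = []
    if (
        mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any()
    ):
        flags.append("touches_border")
    padded = np.pad(mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    contour = max(contours, key=len)
    # the raw marching-squares polyline staircases along the pixel grid,
    # inflating the perimeter ~6% for a disk; a short circular moving
    # average recovers the subpixel boundary
    if len(contour) >= 8:
        k = 3  # short window: removes stairs, barely rounds true corners
        ext = np.vstack([contour[-k:], contour, contour[:k]])
        kernel = np.ones(k) / k
        sm = np.stack(
            [np.convolve(ext[:, i], kernel, mode="same") for i in (0, 1)], axis=1
        )
        contour = sm[k:-k]
    d = np.diff(contour, axis=0)
    perimeter = float(np.sqrt((d**2).sum(axis=1)).sum())
    yc, xc = contour[:, 0], contour[:, 1]
    area = 0.5 * abs(float(np.dot(xc, np.roll(yc, -1)) - np.dot(yc, np.roll(xc, -1))))
    if perimeter == 0:
        raise ValueError("degenerate contour")
    return 4.0 * math.pi * area / perimeter**2, flags


def anisotropy_score(dmap_or_counts: DensityMap | np.ndarray) -> float:
    """Elongation score in [0, 1) from intensity-weighted second moments.

    0 for an isotropic pattern; values near 1 indicate the strip-like
    appearance of condensates distorted by the lensing effect, exported
    to assist manual review (no automatic rejection is performed).
    """
    counts = (
        dmap_or_counts.counts
        if isinstance(dmap_or_counts, DensityMap)
        else np.asarray(dmap_or_counts)
    ).astype(float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty map")
    ys, xs = np.mgrid[: counts.shape[0], : counts.shape[1]]
    ym = (counts * ys).sum() / total
    xm = (counts * xs).sum() / total
    cyy = (counts * (ys - ym) ** 2).sum() / total
    cxx = (counts * (xs - xm) ** 2).sum() / total
    cxy = (counts * (ys - ym) * (xs - xm)).sum() / total
    evals = np.linalg.eigvalsh([[cyy, cxy], [cxy, cxx]])
    lo, hi = float(evals[0]), float(evals[1])
    if hi <= 0:
        return 0.0
    return 1.0 - max(lo, 0.0) / hi


# ---------------------------------------------------------------------------
# writers

def write_density_tiff(dmap: DensityMap, path: str | Path) -> None:
    tifffile.imwrite(path, dmap.counts.astype(np.float32))


def write_heatmap_tiff(hm: StepSizeHeatmap, path: str | Path) -> None:
    tifffile.imwrite(path, hm.mean_step.astype(np.float32))


def write_roi_labels_tiff(
    rois: Sequence[CondensateROI], shape: tuple[int, int], path: str | Path
) -> None:
    lab = np.zeros(shape, dtype=np.int32)
    for roi in rois:
        r0, c0, r1, c1 = roi.bbox
        lab[r0:r1, c0:c1][roi.mask] = roi.label
    tifffile.imwrite(path, lab)


def write_pcc_json(pccs: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(pccs, indent=2))
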