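"""End-to-end pipeline orchestration with reproducibility metadata.

Composes the analysis stages in their natural order — (simulate |
track | load) → classify → pool/density map → segment condensates →
per-condensate spatial statistics → report — under a single declarative
:class:`RunConfig`. Every threshold carries the pipeline's standard
default, all randomness derives from one root seed, the config is
serialized next to the outputs, and each output embeds the config hash
so any number in a report is traceable to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import diffusion, maps, spatial, tracking
from .trajectory import Trajectory, read_trajectories_csv, write_trajectories_csv
from .simulate import Scene, SimParams, simulate_trajectories, load_scene_config

__all__ = ["RunConfig", "RunReport", "run_intra_condensate", "run_dilute"]

log = logging.getLogger("condensate_spt.pipeline")


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run.

    Exactly one input source is used: ``input_trajectories`` (CSV),
    ``input_video`` (TIFF, tracked with the configured linking radius),
    or ``scene_config`` / inline defaults (simulation). All thresholds
    default to the pipeline's standard values.
    """

    input_trajectories: str | None = None
    input_video: str | None = None
    scene_config: str | None = None
    simulate_n_trajectories: int = 500
    pixel_size: float = 0.117
    frame_interval: float = 0.01
    max_link_px: float = tracking.INTRA_CONDENSATE_LINK_PX
    quality_threshold: float = tracking.DEFAULT_QUALITY_THRESHOLD
    immobile_threshold_um: float = diffusion.IMMOBILE_THRESHOLD_UM
    alpha_threshold: float = diffusion.ALPHA_THRESHOLD
    r2_min: float = diffusion.R2_MIN
    blur_R: float = diffusion.MOTION_BLUR_R_CONTINUOUS
    segment_threshold: float = maps.SEGMENT_THRESHOLD
    segment_min_area_px: int = maps.SEGMENT_MIN_AREA_PX
    n_boot: int = 200
    seed: int = 0
    output_dir: str = "results"

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration.

        The output directory is execution metadata, not analysis
        configuration, and is excluded so re-runs into different
        directories produce identical reports.
        """
        doc = asdict(self)
        doc.pop("output_dir")
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class RunReport:
    """Structured result of a pipeline run; serializable to JSON."""

    config_hash: str
    version: str
    fractions: dict[str, float]
    n_trajectories: int
    condensates: list[dict] = field(default_factory=list)
    pooled_pcf: dict | None = None
    spectrum: dict | None = None
    errors: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=_jsonable)


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(type(o))


def _seed_stream(root: int, stage: str) -> int:
    """Derived per-stage seed below 2^31, stable across runs."""
    h = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _load_trajectories(config: RunConfig) -> list[Trajectory]:
    if config.input_trajectories:
        return read_trajectories_csv(
            config.input_trajectories, frame_interval=config.frame_interval
        )
    if config.input_video:
        stack = tracking.read_tiff(
            config.input_video,
            pixel_size=config.pixel_size,
            frame_interval=config.frame_interval,
        )
        filtered = tracking.dog_filter(stack)
        dets = tracking.detect_spots(
            filtered, quality_threshold=config.quality_threshold
        )
        return tracking.link_trajectories(
            dets,
            max_link_px=config.max_link_px,
            pixel_size=config.pixel_size,
            frame_interval=config.frame_interval,
        )
    if config.scene_config:
        scene, params = load_scene_config(config.scene_config)
    else:
        scene = Scene(
            condensate_center=(2.0, 2.0),
            condensate_radius=1.5,
            nanodomains=[],
        )
        params = SimParams(
            frame_interval=config.frame_interval,
            n_trajectories=config.simulate_n_trajectories,
            seed=_seed_stream(config.seed, "simulate"),
        )
    sims = simulate_trajectories(scene, params)
    return [s.trajectory for s in sims]


def _classify(config: RunConfig, trajs):
    return diffusion.classify_trajectories(
        trajs,
        immobile_threshold_um=config.immobile_threshold_um,
        alpha_threshold=config.alpha_threshold,
        r2_min=config.r2_min,
        blur_R=config.blur_R,
    )


def run_intra_condensate(config: RunConfig) -> RunReport:
    """Run the full intra-condensate analysis and write a report.

    Stages: input → classification → localization pool / density map →
    condensate segmentation → per-condensate nanodomain statistics
    (pair correlation, exponential fit, radial profile, circularity,
    density-vs-step-size weighted PCC) → pooled bootstrap. Per-condensate
    failures are recorded in the report, not fatal; the run is
    idempotent for a fixed config.
    """
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    (out / f"config_{chash}.yaml").write_text(yaml.safe_dump(asdict(config)))

    trajs = _load_trajectories(config)
    log.info("stage=input n_trajectories=%d t=%.2fs", len(trajs), time.time() - t0)
    classified = _classify(config, trajs)
    fractions = diffusion.category_fractions(classified, include_excluded=True)

    report = RunReport(
        config_hash=chash, version=_version(), fractions=fractions,
        n_trajectories=len(trajs),
    )

    if trajs:
        write_trajectories_csv(trajs, out / f"trajectories_{chash}.csv",
                               seed=config.seed)
        diffusion.classification_table(classified).to_csv(
            out / f"classification_{chash}.csv", index=False
        )
        pool = maps.subsample_pool(trajs, seed=_seed_stream(config.seed, "pool"))
        dmap = maps.density_map(pool, pixel_size=config.pixel_size)
        rois = maps.segment_condensates(
            dmap,
            threshold=config.segment_threshold,
            min_area_px=config.segment_min_area_px,
        )
        log.info("stage=segment n_rois=%d t=%.2fs", len(rois), time.time() - t0)
        hm = maps.stepsize_heatmap(
            trajs, pixel_size=config.pixel_size, shape=dmap.counts.shape
        )
        curves = []
        for roi in rois:
            try:
                entry = _analyze_roi(config, roi, dmap, hm, pool, classified)
                report.condensates.append(entry)
                if entry.get("pcf") is not None:
                    curves.append(entry.pop("_curve"))
            except Exception as err:  # recorded, not fatal
                report.errors.append(f"roi {roi.label}: {err}")
        if len(curves) >= 2:
            boot = spatial.aggregate_and_bootstrap(
                curves, n_boot=config.n_boot,
                seed=_seed_stream(config.seed, "bootstrap"),
            )
            report.pooled_pcf = {
                "amplitude": boot.fit.amplitude, "radius_um": boot.fit.radius,
                "amplitude_ci": boot.a_ci, "radius_ci": boot.r_ci,
            }
        mobile = [
            c.trajectory for c in classified if c.category in ("confined", "normal")
        ]
        if len(mobile) >= 2:
            spec = diffusion.state_array_spectrum(mobile, blur_R=config.blur_R)
            report.spectrum = {
                "d_grid": spec.d_grid, "occupations": spec.occupations,
                "mode": spec.mode,
            }
            (out / f"spectrum_{chash}.json").write_text(
                json.dumps(
                    {"d_grid": spec.d_grid.tolist(),
                     "occupations": spec.occupations.tolist()},
                    indent=2,
                )
            )
    (out / f"report_{chash}.json").write_text(report.to_json())
    log.info("stage=done t=%.2fs", time.time() - t0)
    return report


def _analyze_roi(config, roi, dmap, hm, pool, classified) -> dict:
    r0, c0, r1, c1 = roi.bbox
    origin = (
        dmap.origin[0] + c0 * dmap.pixel_size,
        dmap.origin[1] + r0 * dmap.pixel_size,
    )
    px = dmap.pixel_size
    pts = pool.points[["x_um", "y_um"]].to_numpy()
    ix = np.floor((pts[:, 0] - origin[0]) / px).astype(int)
    iy = np.floor((pts[:, 1] - origin[1]) / px).astype(int)
    inside = (
        (ix >= 0) & (ix < roi.mask.shape[1]) & (iy >= 0) & (iy < roi.mask.shape[0])
    )
    inside[inside] &= roi.mask[iy[inside], ix[inside]]
    roi_pts = pts[inside]
    entry: dict = {
        "roi_id": roi.label,
        "area_um2": roi.area_um2,
        "equivalent_radius_um": roi.equivalent_radius_um,
        "n_localizations": int(inside.sum()),
    }
    circ, cflags = maps.circularity(roi.mask)
    entry["circularity"] = circ
    entry["circularity_flags"] = cflags
    entry["anisotropy"] = maps.anisotropy_score(
        dmap.counts[r0:r1, c0:c1] * roi.mask
    )
    # density map vs step-size heatmap of the same channel
    sub_counts = dmap.counts[r0:r1, c0:c1].astype(float)
    sub_hm = hm.mean_step[r0:r1, c0:c1]
    try:
        w = maps.pcc_weights(dmap.counts[r0:r1, c0:c1])
        entry["pcc_density_vs_stepsize"] = maps.weighted_pcc(sub_counts, sub_hm, w)
    except ValueError:
        entry["pcc_density_vs_stepsize"] = None
    if len(roi_pts) >= 10:
        curve = spatial.pair_correlation(
            roi_pts, roi_pts, roi.mask, pixel_size=px, origin=origin,
            mode="auto", roi_id=roi.label,
        )
        fit = spatial.fit_exponential(curve)
        entry["pcf"] = {
            "amplitude": fit.amplitude, "radius_um": fit.radius,
            "success": fit.success,
        }
        entry["_curve"] = curve
        centers = spatial.nanodomain_centers(
            maps.DensityMap(dmap.counts[r0:r1, c0:c1], px, origin),
            method="puncta",
        )
        if len(centers) > 0:
            prof = spatial.radial_profile(
                centers, roi.centroid_um, roi.equivalent_radius_um
            )
            entry["radial_profile"] = {
                "bin_centers": prof.bin_centers, "p_norm": prof.p_norm,
                "n_points": prof.n_points,
            }
    else:
        entry["pcf"] = None
    return entry


def run_dilute(config: RunConfig) -> RunReport:
    """Dilute-phase variant: 15-px linking radius, no segmentation.

    Produces the classification fractions and the state-array D spectrum
    only; condensate-level statistics do not apply outside condensates.
    """
    cfg = RunConfig(**{**asdict(config), "max_link_px": tracking.DILUTE_PHASE_LINK_PX})
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    (out / f"config_{chash}.yaml").write_text(yaml.safe_dump(asdict(cfg)))
    trajs = _load_trajectories(cfg)
    classified = _classify(cfg, trajs)
    fractions = diffusion.category_fractions(classified, include_excluded=True)
    report = RunReport(
        config_hash=chash, version=_version(), fractions=fractions,
        n_trajectories=len(trajs),
    )
    mobile = [
        c.trajectory for c in classified if c.category in ("confined", "normal")
    ]
    if len(mobile) >= 2:
        spec = diffusion.state_array_spectrum(mobile, blur_R=cfg.blur_R)
        report.spectrum = {
            "d_grid": spec.d_grid, "occupations": spec.occupations,
            "mode": spec.mode,
        }
    if trajs:
        diffusion.classification_table(classified).to_csv(
            out / f"classification_{chash}.csv", index=False
        )
    (out / f"report_{chash}.json").write_text(report.to_json())
    return report


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("condensate-spt")
    except Exception:
        return "unknown"
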