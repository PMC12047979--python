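"""Synthetic single-molecule data with known ground truth.

Emulates the statistical structure of intra-condensate single-particle
tracking experiments: 2D diffusion of molecules inside a disk-shaped
condensate containing nanometer-scale trapping regions ("nanodomains"),
observed through a camera with localization error and optional motion
blur. Three elementary motion classes are generated — immobile (position
fixed, observed through localization noise only), confined (Brownian
motion reflected at a nanodomain boundary), and normal (free Brownian
motion inside the condensate) — plus an optional two-state switching
class that alternates between nanodomain capture and free diffusion.

The module also renders point-spread-function videos of the simulated
molecules (for end-to-end detection/linking tests) and generates
exponential-relaxation force traces mimicking dual-trap droplet fusion
experiments.

Units: lengths in µm, times in s, diffusion coefficients in µm²/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml

from .trajectory import Trajectory
from .fusion import ForceTrace

__all__ = [
    "Nanodomain",
    "Scene",
    "SimParams",
    "SimulatedTrajectory",
    "simulate_trajectories",
    "render_video",
    "simulate_force_trace",
    "save_scene_config",
    "load_scene_config",
]


@dataclass
class Nanodomain:
    """A disk-shaped trapping region inside a condensate.

    ``escape_prob`` is the per-frame probability that a molecule captured
    by this domain (switching mode) is released; it must lie in [0, 1].
    """

    center: tuple[float, float]
    radius: float
    escape_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("nanodomain radius must be positive")
        if not 0.0 <= self.escape_prob <= 1.0:
            raise ValueError("escape_prob must lie in [0, 1]")


@dataclass
class Scene:
    """Geometry of one condensate with its nanodomains.

    Every nanodomain disk must lie fully inside the condensate disk.
    """

    condensate_center: tuple[float, float] = (2.0, 2.0)
    condensate_radius: float = 1.5
    nanodomains: list[Nanodomain] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.condensate_radius <= 0:
            raise ValueError("condensate radius must be positive")
        c = np.asarray(self.condensate_center, float)
        for nd in self.nanodomains:
            d = float(np.linalg.norm(np.asarray(nd.center, float) - c))
            if d + nd.radius > self.condensate_radius + 1e-12:
                raise ValueError(
                    f"nanodomain at {nd.center} (r={nd.radius}) extends "
                    "outside the condensate disk"
                )


@dataclass
class SimParams:
    """Simulation parameters.

    Defaults describe the imaging regime the analysis assumes: 16 nm
    static localization error, a frame interval of 10 ms (at the
    dilute-phase D ≈ 10 µm²/s this keeps the rms frame step ≈ 0.63 µm,
    compatible with a 15-pixel dilute-phase linking radius), and
    photobleaching-limited trajectory lengths drawn from a geometric
    distribution with mean 20 frames truncated at ≥ 5 localizations.
    """

    frame_interval: float = 0.01
    n_frames: int = 1000
    n_trajectories: int = 100
    D_free: float = 1.0
    D_confined: float = 0.2
    loc_error_sd: float = 0.016
    p_immobile: float = 0.0
    p_confined: float = 0.0
    p_switching: float = 0.0
    switching: bool = False
    mean_length: float = 20.0
    min_length: int = 5
    subframe_steps: int = 1
    confinement_mode: Literal["reflect", "spring"] = "reflect"
    capture_prob: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_immobile", "p_confined", "p_switching"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.p_immobile + self.p_confined + self.p_switching > 1.0 + 1e-12:
            raise ValueError("class fractions must sum to <= 1")
        if self.D_free < 0 or self.D_confined < 0:
            raise ValueError("diffusion coefficients must be >= 0")
        if self.loc_error_sd < 0:
            raise ValueError("loc_error_sd must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.subframe_steps < 1:
            raise ValueError("subframe_steps must be >= 1")
        if self.min_length < 2:
            raise ValueError("min_length must be >= 2")


@dataclass
class SimulatedTrajectory:
    """One simulated trajectory with its ground truth.

    ``trajectory.xy`` holds the observed positions (motion-blur averaged,
    localization noise added); ``true_xy`` the noiseless frame-sampled
    positions; ``states`` the per-frame true state; ``label`` the
    per-trajectory class (immobile | confined | normal | switching).
    """

    trajectory: Trajectory
    label: str
    true_xy: np.ndarray
    states: np.ndarray
    domain: int | None = None


def _uniform_in_disk(rng: np.random.Generator, center, radius: float, n: int = 1):
    r = radius * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0, 2 * math.pi, size=n)
    pts = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
    return pts + np.asarray(center, float)


def _reflect_into_disk(p: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Reflect a point back into a disk across its boundary circle."""
    for _ in range(16):
        v = p - center
        d = float(np.linalg.norm(v))
        if d <= radius or d == 0.0:
            return p
        p = center + v / d * (2.0 * radius - d)
    # pathological large step: clamp to boundary
    v = p - center
    return center + v / np.linalg.norm(v) * radius


def _sample_length(rng: np.random.Generator, mean: float, minimum: int) -> int:
    """Geometric trajectory length (localizations), conditioned >= minimum."""
    p = 1.0 / max(mean, 1.0)
    while True:
        n = int(rng.geometric(p))
        if n >= minimum:
            return n


def simulate_trajectories(
    scene: Scene, params: SimParams
) -> list[SimulatedTrajectory]:
    """Simulate labeled 2D trajectories inside a condensate.

    Brownian steps have per-axis variance 2·D·Δt_sub at the subframe time
    step; mobile molecules reflect at the condensate boundary, confined
    molecules additionally at their nanodomain boundary. The recorded
    position of a frame is the mean of its ``subframe_steps`` sub-positions
    (motion blur); independent Gaussian localization noise is then added
    per frame. Bit-identical output for identical seed.
    """
    rng = np.random.default_rng(params.seed)
    dt_sub = params.frame_interval / params.subframe_steps
    center = np.asarray(scene.condensate_center, float)
    needs_domains = params.p_confined > 0 or (
        params.switching and params.p_switching > 0
    )
    if needs_domains and not scene.nanodomains:
        raise ValueError("scene has no nanodomains but confined/switching requested")

    out: list[SimulatedTrajectory] = []
    for i in range(params.n_trajectories):
        n_loc = _sample_length(rng, params.mean_length, params.min_length)
        start = int(rng.integers(0, max(params.n_frames - n_loc, 0) + 1))
        u = rng.uniform()
        if u < params.p_immobile:
            label = "immobile"
        elif u < params.p_immobile + params.p_confined:
            label = "confined"
        elif params.switching and u < (
            params.p_immobile + params.p_confined + params.p_switching
        ):
            label = "switching"
        else:
            label = "normal"

        domain_idx: int | None = None
        if label in ("confined", "switching") and scene.nanodomains:
            domain_idx = int(rng.integers(len(scene.nanodomains)))

        true_xy = np.empty((n_loc, 2))
        states = np.empty(n_loc, dtype=object)

        if label == "immobile":
            p0 = _uniform_in_disk(rng, center, scene.condensate_radius)[0]
            true_xy[:] = p0
            states[:] = "immobile"
        else:
            if label == "confined":
                nd = scene.nanodomains[domain_idx]
                p = _uniform_in_disk(rng, nd.center, nd.radius)[0]
            elif label == "switching":
                nd = scene.nanodomains[domain_idx]
                p = _uniform_in_disk(rng, nd.center, nd.radius)[0]
            else:
                p = _uniform_in_disk(rng, center, scene.condensate_radius)[0]
            state = "confined" if label in ("confined", "switching") else "normal"
            cur_domain = domain_idx
            for k in range(n_loc):
                sub = np.empty((params.subframe_steps, 2))
                for j in range(params.subframe_steps):
                    if state == "confined":
                        nd = scene.nanodomains[cur_domain]
                        ndc = np.asarray(nd.center, float)
                        if params.confinement_mode == "spring":
                            kappa = 4.0 * params.D_confined / nd.radius**2
                            p = p - kappa * (p - ndc) * dt_sub
                            p = p + rng.normal(
                                0, math.sqrt(2 * params.D_confined * dt_sub), 2
                            )
                        else:
                            p = p + rng.normal(
                                0, math.sqrt(2 * params.D_confined * dt_sub), 2
                            )
                            p = _reflect_into_disk(p, ndc, nd.radius)
                    else:
                        p = p + rng.normal(
                            0, math.sqrt(2 * params.D_free * dt_sub), 2
                        )
                        p = _reflect_into_disk(p, center, scene.condensate_radius)
                    sub[j] = p
                true_xy[k] = sub.mean(axis=0) if params.subframe_steps > 1 else p
                states[k] = state
                # per-frame state switching (evaluated once per frame)
                if label == "switching":
                    if state == "confined":
                        nd = scene.nanodomains[cur_domain]
                        if rng.uniform() < nd.escape_prob:
                            state = "normal"
                    else:
                        for di, nd in enumerate(scene.nanodomains):
                            if (
                                np.linalg.norm(p - np.asarray(nd.center)) <= nd.radius
                                and rng.uniform() < params.capture_prob
                            ):
                                state = "confined"
                                cur_domain = di
                                break

        obs = true_xy + rng.normal(0, params.loc_error_sd, size=true_xy.shape)
        traj = Trajectory(
            id=i,
            frames=np.arange(start, start + n_loc),
            xy=obs,
            frame_interval=params.frame_interval,
            true_state=states.astype(str),
        )
        out.append(
            SimulatedTrajectory(
                trajectory=traj,
                label=label,
                true_xy=true_xy,
                states=states.astype(str),
                domain=domain_idx,
            )
        )
    return out


def simulate_brownian_control(
    n_trajectories: int = 1000,
    D: float = 10.0,
    frame_interval: float = 0.01,
    loc_error_sd: float = 0.016,
    mean_length: float = 20.0,
    min_length: int = 5,
    seed: int = 0,
    arena_radius: float = 200.0,
) -> list[SimulatedTrajectory]:
    """Pure random-walk (dilute-phase) control trajectories.

    Free 2D Brownian motion with localization noise and the standard
    photobleaching-limited length distribution, in an arena large enough
    that the reflecting boundary is never felt. This is the null dataset
    against which the classifier's confined fraction is calibrated.
    """
    scene = Scene(
        condensate_center=(0.0, 0.0), condensate_radius=arena_radius,
        nanodomains=[],
    )
    params = SimParams(
        frame_interval=frame_interval,
        n_frames=10000,
        n_trajectories=n_trajectories,
        D_free=D,
        loc_error_sd=loc_error_sd,
        mean_length=mean_length,
        min_length=min_length,
        seed=seed,
    )
    return simulate_trajectories(scene, params)


def render_video(
    trajectories: Sequence[Trajectory],
    shape: tuple[int, int],
    n_frames: int | None = None,
    psf_sd_px: float = 1.2,
    photons: float = 500.0,
    background: float = 10.0,
    camera_noise_sd: float = 2.0,
    pixel_size: float = 0.117,
    seed: int = 0,
    noise: bool = True,
) -> np.ndarray:
    """Render trajectories into a 16-bit camera image stack.

    Each localization becomes an isotropic Gaussian spot of integrated
    intensity ``photons`` centred at its position (µm coordinates divided
    by ``pixel_size``; pixel centers at integer coordinates). Poisson
    photon noise and Gaussian read noise are applied when ``noise``.
    """
    if photons <= 0:
        raise ValueError("photons must be positive")
    H, W = shape
    if n_frames is None:
        n_frames = int(max(t.frames.max() for t in trajectories)) + 1 if trajectories else 1
    stack = np.full((n_frames, H, W), float(background))
    win = int(math.ceil(4 * psf_sd_px))
    for t in trajectories:
        px = t.xy / pixel_size
        for f, (x, y) in zip(t.frames, px):
            if not (0 <= f < n_frames):
                continue
            xi, yi = int(round(x)), int(round(y))
            x0, x1 = max(xi - win, 0), min(xi + win + 1, W)
            y0, y1 = max(yi - win, 0), min(yi + win + 1, H)
            if x0 >= x1 or y0 >= y1:
                continue
            ys, xs = np.mgrid[y0:y1, x0:x1]
            g = np.exp(-((xs - x) ** 2 + (ys - y) ** 2) / (2 * psf_sd_px**2))
            stack[f, y0:y1, x0:x1] += photons * g / (2 * math.pi * psf_sd_px**2)
    if noise:
        rng = np.random.default_rng(seed)
        stack = rng.poisson(stack).astype(float)
        stack += rng.normal(0, camera_noise_sd, size=stack.shape)
    return np.clip(np.round(stack), 0, 65535).astype(np.uint16)


def simulate_force_trace(
    tau: float,
    a: float = 10.0,
    b: float = 30.0,
    c: float = 2.0,
    noise_sd: float = 0.5,
    rate_hz: float = 50000.0,
    duration_s: float = 5.0,
    onset_s: float = 2.0,
    seed: int = 0,
) -> ForceTrace:
    """Generate a dual-trap fusion force trace.

    Before the fusion onset the force sits at the contact baseline
    ``a + b`` plus the linear trap-interference drift ``c·t``; from the
    onset it relaxes as ``a + b·exp(−(t−onset)/τ) + c·t``, continuous at
    the onset. Gaussian measurement noise of ``noise_sd`` pN is added.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    f = np.where(
        t < onset_s,
        a + b + c * t,
        a + b * np.exp(-(np.maximum(t - onset_s, 0.0)) / tau) + c * t,
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0, noise_sd, size=n)
    return ForceTrace(time=t, force=f, rate_hz=rate_hz)


def save_scene_config(
    path: str | Path, scene: Scene, params: SimParams
) -> None:
    """Serialize scene + parameters (seed included) as YAML."""
    doc = {"scene": asdict(scene), "params": asdict(params)}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_scene_config(path: str | Path) -> tuple[Scene, SimParams]:
    doc = yaml.safe_load(Path(path).read_text())
    sc = doc["scene"]
    scene = Scene(
        condensate_center=tuple(sc["condensate_center"]),
        condensate_radius=sc["condensate_radius"],
        nanodomains=[
            Nanodomain(tuple(d["center"]), d["radius"], d.get("escape_prob", 0.0))
            for d in sc.get("nanodomains", [])
        ],
    )
    return scene, SimParams(**doc["params"])
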