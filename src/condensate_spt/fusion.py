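"""Droplet-fusion rheology from dual-trap force traces.

When two optically trapped condensate droplets touch, surface tension
pulls them into one while viscosity resists; the force measured on the
trap relaxes exponentially with a characteristic fusion time τ that
reports the viscosity-to-surface-tension ratio of the material. The
recorded trace is modeled as

    F(t) = A + B·exp(−t/τ) + C·t

where A is the measurement background, B the fusion amplitude, and C a
linear drift from trap–trap interference as the probing trap approaches
at constant speed. Traces are sampled at 50 kHz by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label

__all__ = [
    "ForceTrace",
    "FusionFit",
    "read_force_csv",
    "write_force_csv",
    "detect_fusion_onset",
    "fit_fusion",
    "otsu_area",
]


@dataclass
class ForceTrace:
    """Uniformly sampled force record (time in s, force in pN)."""

    time: np.ndarray
    force: np.ndarray
    rate_hz: float = 50000.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.force = np.asarray(self.force, float)
        if self.rate_hz <= 0:
            raise ValueError("sample rate must be positive")
        if self.time.shape != self.force.shape:
            raise ValueError("time and force length mismatch")

    @property
    def duration(self) -> float:
        return len(self.time) / self.rate_hz


@dataclass
class FusionFit:
    """Result of fitting the fusion relaxation model."""

    tau: float
    a: float
    b: float
    c: float
    onset_index: int
    window_s: float
    r_squared: float
    covariance: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags and self.tau > 0


def read_force_csv(path: str | Path, rate_hz: float | None = None) -> ForceTrace:
    """Read a force trace CSV with columns ``time_s, force_pN``."""
    df = pd.read_csv(path, comment="#")
    t = df["time_s"].to_numpy(float)
    if rate_hz is None:
        rate_hz = 1.0 / float(np.median(np.diff(t)))
    return ForceTrace(time=t, force=df["force_pN"].to_numpy(float), rate_hz=rate_hz)


def write_force_csv(trace: ForceTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time, "force_pN": trace.force}).to_csv(
        path, index=False
    )


def read_force_binary(path: str | Path) -> ForceTrace:  # pragma: no cover
    """Adapter stub for instrument-native binary force logs."""
    raise NotImplementedError(
        "binary force-log import is instrument specific; export CSV instead"
    )


def _block_downsample(x: np.ndarray, factor: int) -> np.ndarray:
    n = (len(x) // factor) * factor
    return x[:n].reshape(-1, factor).mean(axis=1)


def detect_fusion_onset(
    trace: ForceTrace,
    target_rate_hz: float = 5.0,
    threshold_factor: float = 5.0,
    refine_rate_hz: float = 1000.0,
) -> int | None:
    """Locate the fusion event by the largest force-gradient peak.

    The trace is block-averaged down to ``target_rate_hz``, the discrete
    gradient taken, and the largest absolute gradient peak found. Returns
    None (no event) when the peak does not exceed ``threshold_factor`` ×
    the median absolute gradient — e.g. for a flat trace or pure linear
    drift. The coarse peak (resolution 1/``target_rate_hz``) is then
    refined by repeating the gradient search at ``refine_rate_hz`` in a
    ±1-block neighborhood, since typical fusion times are much shorter
    than a coarse block.
    """
    if trace.duration < 2.0:
        raise ValueError("trace shorter than 2 s")
    factor = max(int(round(trace.rate_hz / target_rate_hz)), 1)
    low = _block_downsample(trace.force, factor)
    if len(low) < 3:
        raise ValueError("trace too short after downsampling")
    grad = np.gradient(low)
    mag = np.abs(grad)
    k = int(np.argmax(mag))
    med = float(np.median(mag))
    if med == 0.0:
        if mag[k] == 0.0:
            return None
    elif mag[k] < threshold_factor * med:
        return None
    # refine within the coarse peak's neighborhood at a finer time base
    lo = max((k - 1) * factor, 0)
    hi = min((k + 2) * factor, len(trace.force))
    fine_factor = max(int(round(trace.rate_hz / refine_rate_hz)), 1)
    seg = _block_downsample(trace.force[lo:hi], fine_factor)
    if len(seg) >= 3:
        fine_k = int(np.argmax(np.abs(np.gradient(seg))))
        return int(lo + fine_k * fine_factor + fine_factor // 2)
    return int(k * factor + factor // 2)


def _model(t, a, b, c, tau):
    return a + b * np.exp(-t / tau) + c * t


def fit_fusion(
    trace: ForceTrace,
    onset: int,
    window_s: float = 1.0,
) -> FusionFit:
    """Fit F = A + B·e^(−t/τ) + C·t on full-rate data from the onset.

    Time is measured from the onset; the fit spans ``window_s`` seconds
    (or to the end of the trace). τ is initialized from the 1/e decay
    time of the block-downsampled relaxation. Non-convergence and
    degenerate windows are flagged, never silently dropped.
    """
    n_win = int(round(window_s * trace.rate_hz))
    seg = trace.force[onset : onset + n_win]
    t = np.arange(len(seg)) / trace.rate_hz
    flags: list[str] = []
    if len(seg) < 10:
        return FusionFit(np.nan, np.nan, np.nan, np.nan, onset, window_s, np.nan,
                         flags=["window_too_short"])
    if np.ptp(seg) == 0.0:
        return FusionFit(np.nan, float(seg[0]), 0.0, 0.0, onset, window_s, np.nan,
                         flags=["degenerate_flat"])
    # crude initialization from a 100-point smoothed decay
    factor = max(len(seg) // 100, 1)
    low = _block_downsample(seg, factor)
    b0 = float(low[0] - low[-1])
    a0 = float(low[-1])
    target = a0 + b0 / np.e
    idx = np.nonzero(low <= target if b0 > 0 else low >= target)[0]
    tau0 = (idx[0] + 0.5) * factor / trace.rate_hz if len(idx) else t[-1] / 3
    tau0 = float(np.clip(tau0, 1.0 / trace.rate_hz, t[-1]))
    try:
        popt, pcov = curve_fit(
            _model, t, seg,
            p0=[a0, b0, 0.0, tau0],
            bounds=([-np.inf, -np.inf, -np.inf, 1e-9], [np.inf] * 4),
            maxfev=20000,
        )
    except RuntimeError as err:
        return FusionFit(np.nan, np.nan, np.nan, np.nan, onset, window_s, np.nan,
                         flags=[f"no_convergence: {err}"])
    resid = seg - _model(t, *popt)
    ss_tot = float(np.sum((seg - seg.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    a, b, c, tau = popt
    if abs(b) < 10 * np.finfo(float).eps:
        flags.append("degenerate_no_decay")
    return FusionFit(float(tau), float(a), float(b), float(c), onset, window_s,
                     r2, covariance=pcov, flags=flags)


def otsu_area(
    frame: np.ndarray, pixel_size: float
) -> tuple[float, list[str]]:
    """Condensate area (µm²) by Otsu thresholding of a confocal frame.

    Area counts the largest connected foreground component only. Returns
    (area, flags); a blank / unimodal frame yields area 0 with a
    ``no_bimodality`` flag.
    """
    frame = np.asarray(frame, float)
    flags: list[str] = []
    if np.ptp(frame) == 0.0:
        return 0.0, ["no_bimodality"]
    thr = threshold_otsu(frame)
    fg = frame > thr
    if not fg.any() or fg.all():
        return 0.0, ["no_bimodality"]
    lab = sk_label(fg)
    counts = np.bincount(lab.ravel())[1:]
    # weak-separation heuristic: foreground barely brighter than background
    if frame[fg].mean() - frame[~fg].mean() < frame.std():
        flags.append("weak_bimodality")
    return float(counts.max()) * pixel_size**2, flags


def write_fusion_json(fit: FusionFit, path: str | Path) -> None:
    doc = {
        "tau_s": fit.tau, "a": fit.a, "b": fit.b, "c": fit.c,
        "onset_index": fit.onset_index, "window_s": fit.window_s,
        "r_squared": fit.r_squared, "flags": fit.flags,
    }
    Path(path).write_text(json.dumps(doc, indent=2))
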