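"""Within-trajectory diffusion-state segmentation.

A single molecule can alternate between nanodomain-confined and free
episodes. A running window (default 20 steps, stride 1) slides along the
trajectory, and each window's MSD is fit with the same estimators as the
whole-trajectory classifier, yielding per-window series of the anomalous
exponent α and the apparent diffusion coefficient D_app. A two-state
Gaussian-emission hidden Markov model on (α, log D_app) then decodes the
most likely state sequence; states are canonically labeled by mean α
(the lower-α state is "confined"), so the labeling never depends on the
HMM's arbitrary state indexing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM

from .trajectory import Trajectory
from .diffusion import compute_msd, fit_alpha, fit_d_sigma, MSDCurve

__all__ = [
    "WindowedSeries",
    "SegmentationResult",
    "running_window_profile",
    "hmm_segment",
    "segmentation_table",
]

WINDOW_STEPS = 20
STATE_CONFINED = 0
STATE_NORMAL = 1


@dataclass
class WindowedSeries:
    """Per-window diffusion features along one trajectory.

    Window i spans steps i..i+window−1 (localizations i..i+window);
    ``start_frames``/``center_frames`` give the first and central frame
    of each window. Features are NaN where a window's fit failed.
    """

    start_frames: np.ndarray
    center_frames: np.ndarray
    alpha: np.ndarray
    d_app: np.ndarray
    window: int = WINDOW_STEPS


@dataclass
class SegmentationResult:
    """Decoded two-state sequence with transition frames."""

    states: np.ndarray  # per window, 0 = confined, 1 = normal
    transition_frames: list[int]  # first frame of first window in new state
    transitions: list[tuple[int, int, int]]  # (frame, from_state, to_state)
    log_likelihood: float
    state_means_alpha: tuple[float, float]
    n_states_effective: int


def running_window_profile(
    traj: Trajectory,
    window: int = WINDOW_STEPS,
    blur_R: float = 0.0,
) -> WindowedSeries:
    """Sliding-window (α, D_app) profile of one trajectory.

    Each window of ``window`` steps is treated as a short trajectory and
    run through the standard MSD → α (log-log fit) and MSD → D (linear
    blurred fit) estimators.
    """
    n = len(traj)
    if n < window + 1:
        raise ValueError(
            f"trajectory has {n} localizations; need at least window+1 = {window + 1}"
        )
    n_win = n - window
    alpha = np.full(n_win, np.nan)
    dapp = np.full(n_win, np.nan)
    starts = np.empty(n_win, dtype=np.int64)
    centers = np.empty(n_win, dtype=np.int64)
    for i in range(n_win):
        sub = Trajectory(
            id=f"{traj.id}:w{i}",
            frames=traj.frames[i : i + window + 1],
            xy=traj.xy[i : i + window + 1],
            frame_interval=traj.frame_interval,
        )
        starts[i] = traj.frames[i]
        centers[i] = traj.frames[i + window // 2]
        msd = compute_msd(sub)
        fit = fit_alpha(msd)
        if fit is not None:
            alpha[i] = fit[0]
        d, _, flags = fit_d_sigma(msd, traj.frame_interval, R=blur_R)
        dapp[i] = d if "d_clipped" not in flags else np.nan
    return WindowedSeries(starts, centers, alpha, dapp, window=window)


def _feature_matrix(
    series: WindowedSeries, features: str
) -> tuple[np.ndarray, np.ndarray]:
    cols = []
    if features in ("both", "alpha"):
        cols.append(series.alpha)
    if features in ("both", "d_app"):
        with np.errstate(divide="ignore", invalid="ignore"):
            cols.append(np.log10(np.where(series.d_app > 0, series.d_app, np.nan)))
    X = np.stack(cols, axis=1)
    valid = np.all(np.isfinite(X), axis=1)
    return X, valid


def _merge_short_runs(states: np.ndarray, min_run: int) -> np.ndarray:
    """Absorb state runs shorter than ``min_run`` into their neighbors.

    Adjacent windows share all but one step, so the feature series is
    autocorrelated on the window scale; dwells much shorter than a
    window are below the method's resolution and treated as decoding
    flicker.
    """
    states = states.copy()
    changed = True
    while changed:
        changed = False
        runs = []
        start = 0
        for i in range(1, len(states) + 1):
            if i == len(states) or states[i] != states[start]:
                runs.append((start, i))
                start = i
        if len(runs) <= 1:
            break
        lengths = [b - a for a, b in runs]
        k = int(np.argmin(lengths))
        if lengths[k] < min_run:
            a, b = runs[k]
            neighbor = states[a - 1] if a > 0 else states[b]
            states[a:b] = neighbor
            changed = True
    return states


def hmm_segment(
    series: WindowedSeries,
    features: Literal["both", "alpha", "d_app"] = "both",
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-4,
    n_iter: int = 200,
    min_run: int | None = None,
) -> SegmentationResult:
    """Two-state HMM segmentation of a windowed feature series.

    A Gaussian-emission HMM (diagonal covariance, k-means-style
    initialization, ``n_restarts`` seeded restarts with best-likelihood
    selection) is fit to the per-window features, and the most likely
    state path decoded by Viterbi. Decoded dwells shorter than
    ``min_run`` windows (default: half the window size) are merged into
    their neighbors — overlapping windows cannot resolve faster
    switching. A degenerate (near-constant) series returns a single
    state with no transitions. The transition "point" is reported as
    the first frame of the first window assigned to the new state.
    """
    X, valid = _feature_matrix(series, features)
    Xv = X[valid]
    if len(Xv) < 2:
        raise ValueError("need at least 2 valid windows")
    spread = Xv.std(axis=0)
    if np.all(spread < 1e-9):  # constant series: one state, no transitions
        states = np.zeros(len(series.alpha), dtype=int)
        mean_a = float(np.nanmean(series.alpha))
        return SegmentationResult(states, [], [], 0.0, (mean_a, mean_a), 1)
    best = None
    for k in range(n_restarts):
        model = GaussianHMM(
            n_components=2, covariance_type="diag",
            n_iter=n_iter, tol=tol, random_state=seed * 1000 + k,
            min_covar=1e-6, init_params="mc",
        )
        # sticky start: windows overlap by window-1 steps, so true state
        # dwell times are long; a weak transition prior suppresses flicker
        model.startprob_ = np.array([0.5, 0.5])
        model.transmat_ = np.array([[0.98, 0.02], [0.02, 0.98]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model.fit(Xv)
                score = model.score(Xv)
            except (ValueError, np.linalg.LinAlgError):
                continue
        if best is None or score > best[1]:
            best = (model, score)
    if best is None:
        raise RuntimeError("HMM fitting failed for all restarts")
    model, score = best
    raw = model.predict(Xv)
    # canonicalize: state 0 = lower mean alpha (confined)
    alpha_col = 0 if features in ("both", "alpha") else None
    if alpha_col is not None:
        m0 = Xv[raw == 0, alpha_col].mean() if np.any(raw == 0) else np.inf
        m1 = Xv[raw == 1, alpha_col].mean() if np.any(raw == 1) else np.inf
    else:  # d_app-only: lower D means confined
        m0 = Xv[raw == 0, 0].mean() if np.any(raw == 0) else np.inf
        m1 = Xv[raw == 1, 0].mean() if np.any(raw == 1) else np.inf
    if m1 < m0:
        raw = 1 - raw
        m0, m1 = m1, m0
    if min_run is None:
        min_run = max(series.window // 2, 2)
    raw = _merge_short_runs(raw, min_run)
    states = np.full(len(valid), -1, dtype=int)
    states[valid] = raw
    # fill invalid windows with the nearest decoded state
    for i in range(len(states)):
        if states[i] == -1:
            j = np.nonzero(states >= 0)[0]
            states[i] = states[j[np.argmin(np.abs(j - i))]]
    transitions: list[tuple[int, int, int]] = []
    frames: list[int] = []
    for i in range(1, len(states)):
        if states[i] != states[i - 1]:
            f = int(series.start_frames[i])
            transitions.append((f, int(states[i - 1]), int(states[i])))
            frames.append(f)
    return SegmentationResult(
        states, frames, transitions, float(score),
        (float(m0), float(m1)), int(len(np.unique(raw))),
    )


def segmentation_table(
    series: WindowedSeries, result: SegmentationResult
) -> pd.DataFrame:
    """Per-window export: frame, window features, decoded state."""
    return pd.DataFrame(
        {
            "frame": series.center_frames,
            "window_alpha": series.alpha,
            "window_dapp": series.d_app,
            "state": np.where(result.states == STATE_CONFINED, "confined", "normal"),
        }
    )
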