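"""Core trajectory container and table I/O.

A :class:`Trajectory` is the atom of every downstream analysis: a
time-ordered sequence of 2D localizations (in µm) with an integer frame
index and a fixed frame interval. Trajectory sets are exchanged as tidy
CSV tables with columns ``trajectory_id, frame, x_um, y_um`` (plus
optional extras such as ``quality`` or ``true_state``), and an import
adapter is provided for the column layout exported by common Fiji
tracking plugins (``TRACK_ID, FRAME, POSITION_X, POSITION_Y``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "trajectories_to_frame",
    "frame_to_trajectories",
    "write_trajectories_csv",
    "read_trajectories_csv",
    "read_fiji_table",
    "DEFAULT_PIXEL_SIZE_UM",
]

#: camera pixel size of the imaging system, µm
DEFAULT_PIXEL_SIZE_UM = 0.117


@dataclass
class Trajectory:
    """One linked single-molecule trajectory.

    Parameters
    ----------
    id : int or str
        Trajectory identifier, unique within a set.
    frames : ndarray of int, shape (n,)
        Strictly increasing frame indices. With gap closing disabled the
        indices are consecutive, but the container does not require it.
    xy : ndarray of float, shape (n, 2)
        Localizations in µm, image convention (x rightward, y downward).
    frame_interval : float
        Time between consecutive frames, seconds.
    quality : ndarray or None
        Optional per-localization detection quality.
    true_state : ndarray or None
        Optional per-frame ground-truth state label (synthetic data only).
    """

    id: int | str
    frames: np.ndarray
    xy: np.ndarray
    frame_interval: float = 0.01
    quality: np.ndarray | None = None
    true_state: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=np.float64)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must have shape (n, 2)")
        if self.frames.shape[0] != self.xy.shape[0]:
            raise ValueError("frames and xy length mismatch")
        if self.frames.size > 1 and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def n_steps(self) -> int:
        return max(len(self) - 1, 0)

    def steps(self) -> np.ndarray:
        """Frame-to-frame displacement vectors, shape (n-1, 2), µm."""
        return np.diff(self.xy, axis=0)

    def step_lengths(self) -> np.ndarray:
        """Euclidean frame-to-frame step lengths, µm."""
        return np.linalg.norm(self.steps(), axis=1)

    def times(self) -> np.ndarray:
        """Absolute times of the localizations, seconds."""
        return self.frames * self.frame_interval


def trajectories_to_frame(trajectories: Iterable[Trajectory]) -> pd.DataFrame:
    """Flatten a trajectory set into a tidy table."""
    rows = []
    for t in trajectories:
        d = {
            "trajectory_id": t.id,
            "frame": t.frames,
            "x_um": t.xy[:, 0],
            "y_um": t.xy[:, 1],
        }
        if t.quality is not None:
            d["quality"] = t.quality
        if t.true_state is not None:
            d["true_state"] = t.true_state
        rows.append(pd.DataFrame(d))
    if not rows:
        return pd.DataFrame(columns=["trajectory_id", "frame", "x_um", "y_um"])
    return pd.concat(rows, ignore_index=True)


def frame_to_trajectories(
    df: pd.DataFrame, frame_interval: float = 0.01
) -> list[Trajectory]:
    """Rebuild :class:`Trajectory` objects from a tidy table."""
    out: list[Trajectory] = []
    for tid, grp in df.groupby("trajectory_id", sort=True):
        grp = grp.sort_values("frame")
        out.append(
            Trajectory(
                id=tid,
                frames=grp["frame"].to_numpy(),
                xy=grp[["x_um", "y_um"]].to_numpy(),
                frame_interval=frame_interval,
                quality=grp["quality"].to_numpy() if "quality" in grp else None,
                true_state=(
                    grp["true_state"].to_numpy() if "true_state" in grp else None
                ),
            )
        )
    return out


def write_trajectories_csv(
    trajectories: Sequence[Trajectory],
    path: str | Path,
    seed: int | None = None,
) -> None:
    """Write a trajectory set as CSV; the generator seed (if any) is
    embedded as a comment header for provenance."""
    df = trajectories_to_frame(trajectories)
    path = Path(path)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        df.to_csv(fh, index=False)


def read_trajectories_csv(
    path: str | Path, frame_interval: float = 0.01
) -> list[Trajectory]:
    df = pd.read_csv(path, comment="#")
    return frame_to_trajectories(df, frame_interval=frame_interval)


def read_fiji_table(
    path: str | Path,
    frame_interval: float = 0.01,
    position_unit_um: float = 1.0,
) -> list[Trajectory]:
    """Import trajectories from a Fiji/TrackMate-style spot table.

    Expects columns ``TRACK_ID, FRAME, POSITION_X, POSITION_Y``; positions
    are multiplied by ``position_unit_um`` (1.0 if the table is already in
    µm, the pixel size if it is in pixels). Non-numeric header repeat rows
    (as exported by some plugin versions) are dropped.
    """
    df = pd.read_csv(path)
    df = df[pd.to_numeric(df["FRAME"], errors="coerce").notna()]
    df = df.astype(
        {"TRACK_ID": float, "FRAME": float, "POSITION_X": float, "POSITION_Y": float}
    )
    tidy = pd.DataFrame(
        {
            "trajectory_id": df["TRACK_ID"].astype(int),
            "frame": df["FRAME"].astype(int),
            "x_um": df["POSITION_X"] * position_unit_um,
            "y_um": df["POSITION_Y"] * position_unit_um,
        }
    )
    return frame_to_trajectories(tidy, frame_interval=frame_interval)
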