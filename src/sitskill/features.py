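"""Kinematic features of a tracked instrument-tip trajectory.

From the per-frame pixel positions the module derives the field's standard
smoothness signals — frame-to-frame displacement, speed, acceleration and
motion jerk (magnitude of the third time-derivative of position) — plus
summary statistics: path length, mean speed/acceleration/jerk, duration,
and the trajectory mean-square error S, the mean squared distance of the
points from their centroid (a dispersion index of exploratory motion).

All derivatives are forward finite differences on the uniform frame grid;
speeds and jerks are vector magnitudes (non-negative), while acceleration
is the scalar rate of change of speed, dv/dt.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "MotionSeries",
    "MotionSummary",
    "displacement_series",
    "velocity_series",
    "acceleration_series",
    "jerk_series",
    "path_length",
    "trajectory_mse",
    "build_motion_series",
    "summarize",
]

_T_TOL = 1e-9  # uniform-spacing tolerance, seconds


@dataclass
class Trajectory:
    """Uniformly sampled 2-D pixel track: t in seconds, x/y in pixels."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fps: float = 30.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must share length")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("t must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.fps)) > _T_TOL:
                raise ValueError("t must be uniformly spaced at 1/fps")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return 1.0 / self.fps

    def to_csv(self, path: str | Path) -> None:
        """Write `frame,t,x,y` with six-decimal floats."""
        df = pd.DataFrame({"frame": np.arange(len(self)),
                           "t": self.t, "x": self.x, "y": self.y})
        df.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path: str | Path, fps: Optional[float] = None) -> "Trajectory":
        """Read a `frame,t,x,y` CSV.

        The stored time stamps carry six decimals, so the uniform grid is
        reconstructed from the frame rate (given, or estimated from the
        stamp span and rounded to 1e-3 Hz).
        """
        df = pd.read_csv(path, float_precision="round_trip")
        t = df["t"].to_numpy(dtype=float)
        n = len(t)
        if fps is None:
            fps = (n - 1) / (t[-1] - t[0]) if n >= 2 else 30.0
            fps = float(round(fps, 3))
        t = t[0] + np.arange(n) / fps if n else t
        return cls(t=t, x=df["x"].to_numpy(float), y=df["y"].to_numpy(float),
                   fps=fps)


def _require(traj: Trajectory, n_min: int, what: str) -> None:
    if len(traj) < n_min:
        raise ValueError(f"{what} needs at least {n_min} samples, "
                         f"got {len(traj)}")


def displacement_series(traj: Trajectory) -> np.ndarray:
    """Euclidean distance moved between consecutive frames (length n-1)."""
    _require(traj, 2, "displacement")
    return np.hypot(np.diff(traj.x), np.diff(traj.y))


def velocity_series(traj: Trajectory) -> np.ndarray:
    """Speed |d(x,y)/dt| from first forward differences, px/s (length n-1)."""
    _require(traj, 2, "velocity")
    return displacement_series(traj) / traj.dt


def acceleration_series(traj: Trajectory) -> np.ndarray:
    """Rate of change of speed dv/dt, px/s^2 (length n-2, signed)."""
    _require(traj, 3, "acceleration")
    return np.diff(velocity_series(traj)) / traj.dt


def jerk_series(traj: Trajectory) -> np.ndarray:
    """Motion jerk: magnitude of the third position derivative, px/s^3.

    Third forward differences of x and y divided by dt^3, combined as a
    vector norm; length n-3.
    """
    _require(traj, 4, "jerk")
    d3x = np.diff(traj.x, n=3) / traj.dt ** 3
    d3y = np.diff(traj.y, n=3) / traj.dt ** 3
    return np.hypot(d3x, d3y)


def path_length(traj: Trajectory) -> float:
    """Total distance travelled: the sum of frame-to-frame displacements."""
    return float(displacement_series(traj).sum())


def trajectory_mse(traj: Trajectory) -> float:
    """Mean squared distance of the points from the trajectory centroid.

    S = (1/n) * sum[(x_i - xbar)^2 + (y_i - ybar)^2]; larger S means more
    exploratory or ineffective movement around the working area.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    return float(np.mean((traj.x - traj.x.mean()) ** 2
                         + (traj.y - traj.y.mean()) ** 2))


@dataclass
class MotionSeries:
    """Six aligned channels [x, y, t, v, a, MJ] for one trial.

    All channels are truncated from the front to the valid range of the
    third difference, so one rectangular array feeds the classifier. The
    acceleration channel enters as |dv/dt| so every derived channel is a
    non-negative magnitude.
    """

    data: np.ndarray  # (length, 6) columns x, y, t, v, a, MJ
    label: Optional[int] = None

    CHANNELS = ("x", "y", "t", "v", "a", "MJ")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 6:
            raise ValueError("MotionSeries data must be (length, 6)")

    def __len__(self) -> int:
        return self.data.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, self.CHANNELS.index(name)]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.data[:, [2, 0, 1, 3, 4, 5]],
                          columns=["t", "x", "y", "v", "a", "MJ"])
        if self.label is not None:
            df["label"] = self.label
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MotionSeries":
        df = pd.read_csv(path, float_precision="round_trip")
        data = df[["x", "y", "t", "v", "a", "MJ"]].to_numpy(float)
        label = int(df["label"].iloc[0]) if "label" in df.columns else None
        return cls(data=data, label=label)


@dataclass
class MotionSummary:
    """Per-trial scalar summary of the motion signals."""

    path_length: float   # px
    mean_v: float        # px/s
    mean_a: float        # px/s^2 (mean |dv/dt|)
    mean_mj: float       # px/s^3
    s: float             # px^2, trajectory mean-square error
    duration: float      # s

    def to_dict(self) -> dict:
        return {"path_length": self.path_length, "mean_v": self.mean_v,
                "mean_a": self.mean_a, "mean_MJ": self.mean_mj,
                "S": self.s, "duration": self.duration}


def build_motion_series(traj: Trajectory,
                        label: Optional[int] = None) -> MotionSeries:
    """Assemble the [x, y, t, v, a, MJ] multivariate time series.

    The jerk channel is the shortest (n-3 samples); x, y, t, v, a are
    truncated from the front so all six channels align on its valid range.
    """
    _require(traj, 4, "motion series")
    n = len(traj)
    m = n - 3
    v = velocity_series(traj)
    a = np.abs(acceleration_series(traj))
    mj = jerk_series(traj)
    data = np.column_stack([traj.x[n - m:], traj.y[n - m:], traj.t[n - m:],
                            v[len(v) - m:], a[len(a) - m:], mj])
    return MotionSeries(data=data, label=label)


def summarize(traj: Trajectory) -> MotionSummary:
    """Scalar motion summary: path length, channel means, S and duration."""
    _require(traj, 4, "summary")
    return MotionSummary(
        path_length=path_length(traj),
        mean_v=float(velocity_series(traj).mean()),
        mean_a=float(np.abs(acceleration_series(traj)).mean()),
        mean_mj=float(jerk_series(traj).mean()),
        s=trajectory_mse(traj),
        duration=float(traj.t[-1] - traj.t[0]),
    )
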