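"""Sensor-stream containers: 1-Hz depth and 16-Hz jaw-acceleration series."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class DepthSeries:
    """Per-individual time-depth record on a uniform 1-s grid.

    Depth is in metres, positive downward, surface at ~0; time in seconds
    from trip start.
    """

    individual_id: str
    time: np.ndarray          # seconds, uniform 1-s spacing
    depth: np.ndarray         # metres, positive down

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.time.shape != self.depth.shape:
            raise ValueError("time and depth must have equal length")
        if len(self.time) > 1:
            dt = np.diff(self.time)
            if not np.allclose(dt, 1.0):
                raise ValueError("DepthSeries requires a uniform 1-s grid")
        if not (np.isfinite(self.depth).all() and np.isfinite(self.time).all()):
            raise ValueError("non-finite values in depth series")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "depth_m": self.depth})

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.4f")

    @classmethod
    def read_csv(cls, path: str | Path, individual_id: str = "") -> "DepthSeries":
        df = pd.read_csv(path)
        return cls(individual_id, df["time_s"].to_numpy(), df["depth_m"].to_numpy())


@dataclass
class AccelSeries:
    """Per-individual jaw-sensor record on a uniform grid (16 Hz by default).

    ``ax`` is the horizontal channel used for mouth-opening detection;
    ``ay`` is carried along for completeness. ``sensor_kind`` selects the
    accelerometer pipeline (3-Hz high-pass, 1.5-s variance window) or the
    Hall-sensor variant (no high-pass, 5-s window).
    """

    individual_id: str
    time: np.ndarray
    ax: np.ndarray
    ay: np.ndarray = None
    rate_hz: float = 16.0
    sensor_kind: str = "accelerometer"

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        if self.ay is None:
            self.ay = np.zeros_like(self.ax)
        self.ay = np.asarray(self.ay, dtype=float)
        if len(self.time) > 1:
            dt = np.diff(self.time)
            if not np.allclose(dt, 1.0 / self.rate_hz, atol=1e-9):
                raise ValueError("AccelSeries grid does not match declared rate")
        if not np.isfinite(self.ax).all():
            raise ValueError("non-finite values in acceleration series")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "ax": self.ax, "ay": self.ay})

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.5f")

    @classmethod
    def read_csv(cls, path: str | Path, individual_id: str = "",
                 rate_hz: float = 16.0, sensor_kind: str = "accelerometer") -> "AccelSeries":
        df = pd.read_csv(path)
        return cls(individual_id, df["time_s"].to_numpy(), df["ax"].to_numpy(),
                   df["ay"].to_numpy() if "ay" in df else None,
                   rate_hz=rate_hz, sensor_kind=sensor_kind)
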