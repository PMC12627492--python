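"""Shared in-memory containers: camera frames and keypoint trajectories.

These two types cross every module boundary — the phantom generator emits
them, the tracker consumes and produces them, the gating controller logs
them — so they live here rather than in any one pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRACKED = "tracked"
LOST = "lost"


@dataclass
class ImageFrame:
    """One timestamped grayscale camera frame.

    Parameters
    ----------
    pixels : 2D float array of non-negative intensities (arbitrary units).
    timestamp : acquisition time in seconds.
    frame_index : position in the sequence.
    pixel_pitch_um : physical size of one pixel in micrometres.
    """

    pixels: np.ndarray
    timestamp: float
    frame_index: int
    pixel_pitch_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("frame pixels must be a 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("frame contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class Trajectory:
    """Per-frame keypoint positions with tracking status.

    Positions are in pixels (x = column, y = row, pixel-center based);
    ``status`` is ``"tracked"`` or ``"lost"`` per frame.  Lost frames keep
    the last good (frozen) position so the series stays plottable.
    """

    frame_index: np.ndarray
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    status: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.status is None:
            self.status = np.full(self.frame_index.shape, TRACKED, dtype=object)
        else:
            self.status = np.asarray(self.status, dtype=object)
        n = len(self.frame_index)
        if not all(len(a) == n for a in (self.t, self.x, self.y, self.status)):
            raise ValueError("trajectory columns have unequal lengths")
        if n > 1 and np.any(np.diff(self.frame_index) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        tracked = self.status == TRACKED
        if not np.all(np.isfinite(self.x[tracked])) or not np.all(
            np.isfinite(self.y[tracked])
        ):
            raise ValueError("tracked positions must be finite")

    def __len__(self) -> int:
        return len(self.frame_index)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions."""
        return np.column_stack([self.x, self.y])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame_index,
                "t": self.t,
                "x": self.x,
                "y": self.y,
                "status": self.status,
            }
        )

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        # fixed 6-decimal formatting keeps write -> read -> write byte-identical
        df["t"] = df["t"].map(lambda v: f"{v:.6f}")
        df["x"] = df["x"].map(lambda v: f"{v:.6f}")
        df["y"] = df["y"].map(lambda v: f"{v:.6f}")
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        status = df["status"].to_numpy() if "status" in df else None
        return cls(
            frame_index=df["frame"].to_numpy(),
            t=df["t"].to_numpy(),
            x=df["x"].to_numpy(),
            y=df["y"].to_numpy(),
            status=status,
        )
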