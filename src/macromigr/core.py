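"""Shared domain types: spatial/temporal calibration and cell tracks.

Coordinates follow the image convention used throughout the package:
``x`` is the column index, ``y`` the row index, origin at the top-left
corner, frames 0-based. Distances in pixels are converted to physical
units through a :class:`Calibration`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Calibration", "Track"]


@dataclass(frozen=True)
class Calibration:
    """Pixel and frame calibration of a time-lapse acquisition.

    Parameters
    ----------
    microns_per_pixel : float
        Length scale, µm per pixel. Must be strictly positive.
    minutes_per_frame : float
        Time between consecutive frames in minutes. The default of 10
        minutes matches the overnight acquisitions the analysis was
        designed for (one frame every 10 min for at least 16 h).
    """

    microns_per_pixel: float = 1.0
    minutes_per_frame: float = 10.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.microns_per_pixel) and self.microns_per_pixel > 0):
            raise ValueError("microns_per_pixel must be finite and > 0")
        if not (np.isfinite(self.minutes_per_frame) and self.minutes_per_frame > 0):
            raise ValueError("minutes_per_frame must be finite and > 0")


@dataclass
class Track:
    """Ordered per-frame centroid positions of a single cell.

    Attributes
    ----------
    track_id : int
        Identifier, unique within one movie/linking run.
    frames : ndarray of int
        Strictly increasing 0-based frame indices. Gaps are allowed
        (missed detections bridged by gap closing).
    x, y : ndarray of float
        Sub-pixel centroid coordinates in pixels (x = column, y = row).
    calibration : Calibration
        Converts pixel/frame quantities to µm/min.
    """

    track_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise ValueError("frames, x and y must have equal length")
        if len(self.frames) < 1:
            raise ValueError("a track needs at least 1 point")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("track coordinates must be finite")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration_frames(self) -> int:
        """Number of frames spanned, first to last inclusive."""
        return int(self.frames[-1] - self.frames[0] + 1)

    @property
    def duration_minutes(self) -> float:
        """Elapsed time between first and last frame, minutes."""
        return float(
            (self.frames[-1] - self.frames[0]) * self.calibration.minutes_per_frame
        )

    def positions_um(self) -> np.ndarray:
        """(n, 2) array of positions in µm, columns (x, y)."""
        return np.column_stack([self.x, self.y]) * self.calibration.microns_per_pixel

    def step_lengths_um(self) -> np.ndarray:
        """Euclidean length of each successive segment in µm.

        A segment across a closed gap contributes its straight-line
        (end-to-end) distance, consistent with how linked tracks are
        interpreted downstream.
        """
        p = self.positions_um()
        return np.linalg.norm(np.diff(p, axis=0), axis=1)

    def path_length_um(self) -> float:
        """Accumulated path length in µm."""
        return float(self.step_lengths_um().sum())

    def net_displacement_um(self) -> float:
        """Straight-line distance from first to last position in µm."""
        p = self.positions_um()
        return float(np.linalg.norm(p[-1] - p[0]))
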