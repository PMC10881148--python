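"""Per-track velocity and persistence in the chemotaxis-tool convention.

Velocity (cell speed) is the accumulated path length divided by the
elapsed time, in µm/min. Persistence is the directness ratio d/T: net
start-to-end displacement d divided by accumulated path length T, a
dimensionless number in [0, 1] that equals 1 for perfectly straight
migration. A displacement-rate variant (d divided by elapsed time,
µm/min) is available behind the ``method`` flag for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Track

__all__ = ["TrackMetrics", "track_speed", "track_persistence",
           "track_metrics", "metrics_table"]


@dataclass(frozen=True)
class TrackMetrics:
    track_id: int
    n_points: int
    duration_frames: int
    duration_min: float
    mean_speed_um_min: float
    net_disp_um: float
    path_um: float
    persistence: float  # NaN when path length is zero


def track_speed(track: Track) -> float:
    """Mean speed: path length (µm) over elapsed time (min).

    Gap segments contribute their straight-line distance; elapsed time is
    the full first-to-last frame interval.
    """
    minutes = track.duration_minutes
    if minutes <= 0:
        raise ValueError("track spans no time")
    return track.path_length_um() / minutes


def track_persistence(track: Track, method: str = "directness") -> float:
    """Persistence of a track.

    ``directness`` (default): d/T, net displacement over path length,
    in [0, 1]. ``displacement_rate``: net displacement over elapsed time,
    µm/min. A zero path length leaves directness undefined — NaN is
    returned rather than 0.
    """
    d = track.net_displacement_um()
    if method == "directness":
        path = track.path_length_um()
        if path == 0:
            return float("nan")
        return min(1.0, d / path)
    if method == "displacement_rate":
        return d / track.duration_minutes
    raise ValueError(f"unknown persistence method: {method!r}")


def track_metrics(track: Track) -> TrackMetrics:
    """All motility metrics of one track."""
    path = track.path_length_um()
    d = track.net_displacement_um()
    return TrackMetrics(
        track_id=track.track_id,
        n_points=len(track),
        duration_frames=track.duration_frames,
        duration_min=track.duration_minutes,
        mean_speed_um_min=track_speed(track),
        net_disp_um=d,
        path_um=path,
        persistence=track_persistence(track),
    )


def metrics_table(tracks) -> pd.DataFrame:
    """Tidy per-track metrics table.

    Columns: track_id, n_frames, duration_min, mean_speed_um_min,
    net_disp_um, path_um, persistence.
    """
    rows = [track_metrics(t) for t in tracks]
    return pd.DataFrame(
        {
            "track_id": [m.track_id for m in rows],
            "n_frames": [m.n_points for m in rows],
            "duration_min": [m.duration_min for m in rows],
            "mean_speed_um_min": [m.mean_speed_um_min for m in rows],
            "net_disp_um": [m.net_disp_um for m in rows],
            "path_um": [m.path_um for m in rows],
            "persistence": [m.persistence for m in rows],
        }
    )
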