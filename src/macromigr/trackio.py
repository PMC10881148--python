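"""Spot detection, LAP track linking with gap closing, track filtering
and track-table I/O.

The pipeline mirrors a standard particle-tracking workflow for labeled
cells: Laplacian-of-Gaussian blob detection per frame, frame-to-frame
linking by optimal linear assignment (cost = squared distance, links
forbidden beyond a maximum distance), a second assignment pass that
closes gaps left by missed detections, and a final filter that removes
dead cells and debris by minimum duration, mean speed and net
displacement. Default thresholds: link/gap distance 70.0, max frame gap
10, minimum 20 frames, mean speed >= 2.00 and displacement >= 8.00, all
in calibrated units (with the default 1 µm/px calibration they coincide
numerically with pixel units). All comparisons are inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_laplace
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max

from .core import Calibration, Track

__all__ = [
    "Detection",
    "TrackingConfig",
    "detect_cells",
    "link_tracks",
    "filter_tracks",
    "track_movie",
    "read_tracks",
    "write_tracks",
]

log = logging.getLogger(__name__)

_BIG = 1e12  # forbidden-assignment cost


@dataclass(frozen=True)
class Detection:
    """One spot in one frame: sub-pixel centre and detector response."""

    frame: int
    x: float
    y: float
    quality: float


@dataclass(frozen=True)
class TrackingConfig:
    """Detection, linking and filter settings.

    ``max_link_distance``, ``min_mean_speed`` and ``min_displacement``
    are in calibrated units (µm with a µm/px calibration); speeds are per
    frame interval. The defaults are the settings used for overnight
    macrophage movies.
    """

    spot_diameter: float = 8.0
    quality_threshold: float = 50.0
    max_link_distance: float = 70.0
    max_gap_frames: int = 10
    min_duration_frames: int = 20
    min_mean_speed: float = 2.00
    min_displacement: float = 8.00

    def __post_init__(self) -> None:
        for name in ("spot_diameter", "quality_threshold", "max_link_distance",
                     "min_mean_speed", "min_displacement"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.max_gap_frames < 0 or self.min_duration_frames < 0:
            raise ValueError("frame thresholds must be >= 0")


# ---------------------------------------------------------------------------
# detection

def detect_cells(
    frame_image: np.ndarray, config: TrackingConfig, frame: int = 0
) -> list[Detection]:
    """LoG blob detection with sub-pixel localisation.

    The image background is flattened by subtracting a large-scale
    Gaussian blur, then the scale-normalised negative
    Laplacian-of-Gaussian response is computed at the scale matched to
    ``spot_diameter`` (sigma = d / 2√2). Local maxima above
    ``quality_threshold`` are refined to sub-pixel precision by a
    separable quadratic fit on the 3x3 response neighbourhood.
    """
    img = np.asarray(frame_image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("frame_image must be a non-empty 2-D array")
    if not np.all(np.isfinite(img)):
        raise ValueError("frame_image contains non-finite values")

    sigma = config.spot_diameter / (2.0 * np.sqrt(2.0))
    flat = img - gaussian_filter(img, sigma=4.0 * config.spot_diameter)
    response = -(sigma**2) * gaussian_laplace(flat, sigma=sigma)

    peaks = peak_local_max(
        response,
        min_distance=max(1, int(round(config.spot_diameter / 2))),
        threshold_abs=config.quality_threshold,
        exclude_border=False,
    )
    detections = []
    for r, c in peaks:
        dy = _parabolic_offset(response, r, c, axis=0)
        dx = _parabolic_offset(response, r, c, axis=1)
        detections.append(
            Detection(frame=frame, x=c + dx, y=r + dy, quality=float(response[r, c]))
        )
    detections.sort(key=lambda d: (d.y, d.x))
    return detections


def _parabolic_offset(resp: np.ndarray, r: int, c: int, axis: int) -> float:
    """Sub-pixel offset from a 1-D quadratic fit through three samples."""
    if axis == 0:
        if r == 0 or r == resp.shape[0] - 1:
            return 0.0
        f0, f1, f2 = resp[r - 1, c], resp[r, c], resp[r + 1, c]
    else:
        if c == 0 or c == resp.shape[1] - 1:
            return 0.0
        f0, f1, f2 = resp[r, c - 1], resp[r, c], resp[r, c + 1]
    denom = f0 - 2 * f1 + f2
    if denom == 0:
        return 0.0
    off = 0.5 * (f0 - f2) / denom
    return float(np.clip(off, -0.5, 0.5))


# ---------------------------------------------------------------------------
# linking

def _group_by_frame(detections) -> dict[int, list[Detection]]:
    frames: dict[int, list[Detection]] = {}
    for d in detections:
        frames.setdefault(d.frame, []).append(d)
    return frames


def _solve_augmented_lap(cost: np.ndarray, n1: int, n2: int, b: float):
    """Jaqaman-style augmented assignment.

    ``cost`` is the (n1, n2) link-cost block with np.inf for forbidden
    links. The augmented matrix prices leaving a source or target
    unmatched at ``b``; the lower-right slack block is free. Returns the
    list of (i, j) links chosen.
    """
    full = np.full((n1 + n2, n1 + n2), _BIG)
    finite = np.isfinite(cost)
    full[:n1, :n2][finite] = cost[finite]
    full[:n1, n2:] = np.where(np.eye(n1, dtype=bool), b, _BIG)
    full[n1:, :n2] = np.where(np.eye(n2, dtype=bool), b, _BIG)
    full[n1:, n2:] = 0.0
    rows, cols = linear_sum_assignment(full)
    return [(i, j) for i, j in zip(rows, cols) if i < n1 and j < n2 and finite[i, j]]


def link_tracks(
    detections,
    config: TrackingConfig,
    calibration: Calibration | None = None,
) -> list[Track]:
    """Two-pass LAP linking of per-frame detections into tracks.

    Pass 1 links detections between consecutive frames by minimum total
    squared distance, forbidding links beyond ``max_link_distance``
    (inclusive) and pricing the no-link alternative at that distance
    squared. Pass 2 closes gaps: segment ends are matched to later
    segment starts within the same distance bound and at most
    ``max_gap_frames`` missing frames, again by optimal assignment.
    Unlinked detections remain as single-point tracks (removed later by
    the duration filter).

    ``detections`` may be a flat iterable of :class:`Detection` or a list
    of per-frame lists. Distances are computed in calibrated units.
    """
    cal = calibration or Calibration()
    if detections and isinstance(detections[0], (list, tuple)):
        flat = [d for fr in detections for d in fr]
    else:
        flat = list(detections)
    if not flat:
        return []
    frames = _group_by_frame(flat)
    frame_ids = sorted(frames)
    upp = cal.microns_per_pixel
    d_max = config.max_link_distance
    b = d_max**2

    # pass 1: frame-to-frame
    segments: list[list[Detection]] = []
    open_by_det: dict[int, int] = {}  # id(detection) -> segment index
    for d in frames[frame_ids[0]]:
        segments.append([d])
        open_by_det[id(d)] = len(segments) - 1
    for prev_f, cur_f in zip(frame_ids[:-1], frame_ids[1:]):
        prev, cur = frames[prev_f], frames[cur_f]
        links = []
        if cur_f == prev_f + 1 and prev and cur:
            p = np.array([[d.x, d.y] for d in prev]) * upp
            q = np.array([[d.x, d.y] for d in cur]) * upp
            dist = np.linalg.norm(p[:, None, :] - q[None, :, :], axis=2)
            cost = np.where(dist <= d_max, dist**2, np.inf)
            links = _solve_augmented_lap(cost, len(prev), len(cur), b)
        linked_j = set()
        for i, j in links:
            seg = open_by_det.pop(id(prev[i]))
            segments[seg].append(cur[j])
            open_by_det[id(cur[j])] = seg
            linked_j.add(j)
        for i, d in enumerate(prev):
            open_by_det.pop(id(d), None)
        for j, d in enumerate(cur):
            if j not in linked_j:
                segments.append([d])
                open_by_det[id(d)] = len(segments) - 1

    # pass 2: gap closing (end of one segment -> start of a later one)
    ends = np.array([[s[-1].x * upp, s[-1].y * upp] for s in segments])
    end_f = np.array([s[-1].frame for s in segments])
    starts = np.array([[s[0].x * upp, s[0].y * upp] for s in segments])
    start_f = np.array([s[0].frame for s in segments])
    n = len(segments)
    gap = start_f[None, :] - end_f[:, None] - 1  # missing frames
    dist = np.linalg.norm(ends[:, None, :] - starts[None, :, :], axis=2)
    allowed = (gap >= 1) & (gap <= config.max_gap_frames) & (dist <= d_max)
    cost = np.where(allowed, dist**2, np.inf)
    links = _solve_augmented_lap(cost, n, n, b)

    successor = {}
    has_pred = set()
    for i, j in links:
        successor[i] = j
        has_pred.add(j)

    tracks: list[Track] = []
    next_id = 0
    for i in range(n):
        if i in has_pred:
            continue
        chain = list(segments[i])
        k = i
        while k in successor:
            k = successor[k]
            chain.extend(segments[k])
        tracks.append(
            Track(
                track_id=next_id,
                frames=[d.frame for d in chain],
                x=[d.x for d in chain],
                y=[d.y for d in chain],
                calibration=cal,
            )
        )
        next_id += 1
    log.info("link_tracks: %d detections -> %d segments -> %d tracks",
             len(flat), n, len(tracks))
    return tracks


# ---------------------------------------------------------------------------
# filtering

def filter_tracks(tracks, config: TrackingConfig) -> list[Track]:
    """Keep tracks meeting the duration, mean-speed and displacement
    minima (all inclusive); order is preserved. Idempotent."""
    tracks = list(tracks)
    kept = []
    for t in tracks:
        dur = t.duration_frames
        intervals = t.frames[-1] - t.frames[0]
        speed = t.path_length_um() / intervals if intervals > 0 else 0.0
        disp = t.net_displacement_um()
        if (
            dur >= config.min_duration_frames
            and speed >= config.min_mean_speed
            and disp >= config.min_displacement
        ):
            kept.append(t)
    log.info("filter_tracks: %d -> %d tracks", len(tracks), len(kept))
    return kept


def track_movie(
    stack: np.ndarray,
    config: TrackingConfig | None = None,
    calibration: Calibration | None = None,
    apply_filters: bool = True,
) -> list[Track]:
    """Full detect → link → filter pipeline on a (T, H, W) movie."""
    config = config or TrackingConfig()
    cal = calibration or Calibration()
    detections = [
        detect_cells(stack[f], config, frame=f) for f in range(stack.shape[0])
    ]
    n_det = sum(len(d) for d in detections)
    log.info("track_movie: %d detections over %d frames", n_det, stack.shape[0])
    tracks = link_tracks(detections, config, cal)
    return filter_tracks(tracks, config) if apply_filters else tracks


# ---------------------------------------------------------------------------
# I/O

#: Column aliases accepted on read (TrackMate-dialect exports).
_ALIASES = {
    "track_id": ("track_id", "TRACK_ID"),
    "frame": ("frame", "FRAME"),
    "x": ("x", "POSITION_X"),
    "y": ("y", "POSITION_Y"),
}


def write_tracks(tracks, path) -> None:
    """Write tracks as CSV with columns track_id, frame, x, y."""
    rows = [
        (t.track_id, int(f), x, y)
        for t in tracks
        for f, x, y in zip(t.frames, t.x, t.y)
    ]
    pd.DataFrame(rows, columns=["track_id", "frame", "x", "y"]).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_tracks(path, calibration: Calibration | None = None) -> list[Track]:
    """Read a track CSV (native or TrackMate-dialect).

    Required columns: track_id, frame, x, y (or their TrackMate aliases);
    extra columns are ignored, as are non-numeric repeat-header rows.
    Frames must be strictly increasing within each track.
    """
    cal = calibration or Calibration()
    df = pd.read_csv(path)
    cols = {}
    for key, names in _ALIASES.items():
        found = next((n for n in names if n in df.columns), None)
        if found is None:
            raise ValueError(f"missing required column: {key}")
        cols[key] = found
    df = df[[cols[k] for k in ("track_id", "frame", "x", "y")]]
    df.columns = ["track_id", "frame", "x", "y"]
    # TrackMate CSV exports repeat human-readable header rows; drop any
    # row that does not parse as numeric
    for c in df.columns:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df = df.dropna()
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        frames = grp["frame"].to_numpy(dtype=int)
        order = np.argsort(frames, kind="stable")
        frames = frames[order]
        if np.any(np.diff(frames) <= 0):
            raise ValueError(f"track {tid}: frames are not strictly increasing")
        tracks.append(
            Track(
                track_id=int(tid),
                frames=frames,
                x=grp["x"].to_numpy()[order],
                y=grp["y"].to_numpy()[order],
                calibration=cal,
            )
        )
    return tracks
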