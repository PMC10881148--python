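"""Synthetic migration data with known ground truth.

Real inputs to this analysis are overnight time-lapse movies of
tracker-dye-labeled macrophages (one frame every 10 min for >= 16 h) plus
confocal z-stacks and pre/post-wash adhesion fields. This module emulates
all of them with controllable ground truth so that every downstream
measurement (tracking, motility, shape dynamics, intensity fractions,
adhesion ratios) can be validated against the parameters that generated
the data.

The motility model is a two-mode persistent random walk. Each condition
fixes one :class:`ModeParams`: the heading evolves by Gaussian increments
(``angular_sd``), the step length is ``mean_step_speed`` x the frame
interval, and circularity fluctuates about ``circ_baseline``. "Slingshot"
events — the elongate-then-recoil behaviour seen on laminin — are drawn
as a Bernoulli process per frame interval: the cell's circularity ramps
down over a few frames (each sub-threshold step) as the cell elongates,
then snaps back up by ``slingshot_delta_c`` in a single frame while the
cell body is launched forward by ``slingshot_step``. Exactly one
single-frame shape change >= ``slingshot_delta_c`` is therefore injected
per event. Two presets, :data:`FN_LIKE` (slow, persistent, spread cells,
no slingshots) and :data:`LAM_LIKE` (faster, meandering, rounded cells
with slingshots), reproduce the qualitative fibronectin/laminin contrast;
their numeric values are package defaults, not measured quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import tifffile
import yaml

from .core import Calibration, Track
from .morpho import ShapeSeries

__all__ = [
    "ModeParams",
    "SimParams",
    "GroundTruth",
    "FN_LIKE",
    "LAM_LIKE",
    "simulate_tracks",
    "synthesize_circularity",
    "render_movie",
    "write_movie",
    "simulate_zstack",
    "zstack_cell_mask",
    "simulate_adhesion_field",
    "ground_truth_to_dataframe",
    "write_ground_truth",
    "params_from_yaml",
    "params_to_yaml",
]


@dataclass(frozen=True)
class ModeParams:
    """Parameters of one migration mode (one substrate condition).

    mean_step_speed : µm/min — mean speed along the path.
    angular_sd : rad per frame — sd of the Gaussian heading increment;
        0 gives perfectly straight tracks, large values a diffusive walk.
    circ_baseline : baseline circularity in (0, 1].
    circ_noise_sd : sd of per-frame circularity fluctuations.
    slingshot_rate : events per cell per hour.
    slingshot_step : µm — displacement of the recoil step (one frame).
    slingshot_delta_c : magnitude of the single-frame circularity jump.
    """

    mean_step_speed: float
    angular_sd: float
    circ_baseline: float
    circ_noise_sd: float = 0.02
    slingshot_rate: float = 0.0
    slingshot_step: float = 0.0
    slingshot_delta_c: float = 0.5

    def __post_init__(self) -> None:
        for name in ("mean_step_speed", "angular_sd", "circ_noise_sd",
                     "slingshot_rate", "slingshot_step"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not 0 < self.circ_baseline <= 1:
            raise ValueError("circ_baseline must be in (0, 1]")
        if not 0 <= self.slingshot_delta_c <= 1:
            raise ValueError("slingshot_delta_c must be in [0, 1]")
        if self.slingshot_rate > 0 and self.circ_baseline - self.slingshot_delta_c < 0:
            raise ValueError(
                "circ_baseline - slingshot_delta_c must be >= 0 when slingshots occur"
            )


#: Fibronectin-like mode: slow, persistent, spread (low circularity), no
#: slingshots. Values are package defaults chosen only to reproduce the
#: qualitative substrate contrast.
FN_LIKE = ModeParams(
    mean_step_speed=0.3,
    angular_sd=0.35,
    circ_baseline=0.45,
    circ_noise_sd=0.03,
    slingshot_rate=0.0,
)

#: Laminin-like mode: ~3x faster, meandering, rounded, with slingshots.
LAM_LIKE = ModeParams(
    mean_step_speed=0.9,
    angular_sd=1.2,
    circ_baseline=0.8,
    circ_noise_sd=0.03,
    slingshot_rate=0.6,
    slingshot_step=15.0,
    slingshot_delta_c=0.5,
)


@dataclass(frozen=True)
class SimParams:
    """Full configuration of one simulated movie."""

    n_cells: int = 50
    n_frames: int = 97
    field_size: tuple[int, int] = (1024, 1024)  # (width, height) px
    calibration: Calibration = field(default_factory=Calibration)
    mode: ModeParams = FN_LIKE
    detection_dropout_prob: float = 0.0
    seed: int = 0
    placement: str = "uniform"  # "uniform" or "grid"
    margin_px: float = 40.0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not 0 <= self.detection_dropout_prob < 1:
            raise ValueError("detection_dropout_prob must be in [0, 1)")
        if any(s <= 0 for s in self.field_size):
            raise ValueError("field_size must be positive")
        if self.placement not in ("uniform", "grid"):
            raise ValueError("placement must be 'uniform' or 'grid'")


@dataclass
class GroundTruth:
    """True tracks, shape series and injected slingshot frames.

    ``slingshot_frames[i]`` lists, for cell ``i``, the recoil frame ``f``
    of each injected event; the circularity jump ``|C_f - C_{f-1}|`` is
    at least ``slingshot_delta_c`` by construction.
    """

    tracks: list[Track]
    shapes: list[ShapeSeries]
    slingshot_frames: list[list[int]]
    params: SimParams

    @property
    def elongations(self) -> list[np.ndarray]:
        return [s.elongation for s in self.shapes]


def _ramp_length(delta_c: float) -> int:
    # elongation ramp long enough that each downward step stays well
    # below the 0.4 detection threshold
    return max(2, math.ceil(delta_c / 0.2))


def _draw_event_frames(
    rng: np.random.Generator, n_frames: int, p: float, dead_time: int
) -> list[int]:
    """Bernoulli event frames with a refractory dead time.

    ``p`` is the target per-interval probability; the draw probability is
    inflated to ``p / (1 - p * dead_time)`` so that the stationary event
    rate equals the requested one despite the enforced spacing.
    """
    if p <= 0:
        return []
    if p * dead_time >= 1:
        raise ValueError("slingshot rate too high for the refractory spacing")
    p_adj = p / (1.0 - p * dead_time)
    draws = rng.random(n_frames)
    frames: list[int] = []
    # start in the stationary state of the renewal process: an interval is
    # refractory with probability p * dead_time, uniformly into the spacing
    u = rng.random()
    cooldown = int(rng.integers(1, dead_time + 1)) if (dead_time > 0 and u < p * dead_time) else 0
    for f in range(1, n_frames):
        if cooldown > 0:
            cooldown -= 1
            continue
        if draws[f] < p_adj:
            frames.append(f)
            cooldown = dead_time
    return frames


def synthesize_circularity(
    n_frames: int,
    baseline: float,
    noise_sd: float,
    event_frames: list[int],
    delta_c: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Circularity series with slingshot events injected at given frames.

    The baseline series is ``baseline`` plus Gaussian noise, clipped to
    (0, 1]. For each event (recoil at frame ``f``), circularity ramps
    linearly down over a few frames to ``C_f - delta_c`` and returns to
    ``C_f`` at frame ``f`` — guaranteeing ``|C_f - C_{f-1}| >= delta_c``
    while every ramp step stays below half the detection threshold.
    """
    rng = rng or np.random.default_rng(0)
    circ = baseline + rng.normal(0.0, noise_sd, size=n_frames)
    circ = np.clip(circ, 1e-6, 1.0)
    ramp = _ramp_length(delta_c) if delta_c > 0 else 0
    for f in sorted(event_frames):
        if not 1 <= f < n_frames:
            raise ValueError(f"event frame {f} outside [1, n_frames)")
        high = max(circ[f], delta_c)
        circ[f] = high
        low = high - delta_c
        pre_idx = f - ramp - 1
        pre = circ[pre_idx] if pre_idx >= 0 else baseline
        for j in range(1, ramp + 1):
            idx = f - j
            if idx < 0:
                break
            # linear ramp from `pre` (at f-ramp-1) down to `low` (at f-1)
            frac = (j - 1) / ramp
            circ[idx] = low + frac * (pre - low)
    return circ


def simulate_tracks(params: SimParams) -> GroundTruth:
    """Simulate persistent-random-walk tracks with slingshot events.

    Deterministic: identical ``params`` (including ``seed``) give
    bit-identical output. Positions reflect at the field boundaries.
    """
    rng = np.random.default_rng(params.seed)
    cal = params.calibration
    mode = params.mode
    w, h = params.field_size
    step_px = mode.mean_step_speed * cal.minutes_per_frame / cal.microns_per_pixel
    sling_px = mode.slingshot_step / cal.microns_per_pixel
    p_event = mode.slingshot_rate * cal.minutes_per_frame / 60.0
    dead_time = _ramp_length(mode.slingshot_delta_c) + 1

    starts = _initial_positions(params, rng)

    tracks: list[Track] = []
    shapes: list[ShapeSeries] = []
    events_all: list[list[int]] = []
    for i in range(params.n_cells):
        heading = rng.uniform(0.0, 2.0 * np.pi)
        xs = np.empty(params.n_frames)
        ys = np.empty(params.n_frames)
        xs[0], ys[0] = starts[i]
        events = _draw_event_frames(rng, params.n_frames, p_event, dead_time)
        event_set = set(events)
        for f in range(1, params.n_frames):
            heading += rng.normal(0.0, mode.angular_sd) if mode.angular_sd > 0 else 0.0
            step = sling_px if f in event_set else step_px
            x = xs[f - 1] + step * math.cos(heading)
            y = ys[f - 1] + step * math.sin(heading)
            x, heading = _reflect(x, w - 1, "x", heading)
            y, heading = _reflect(y, h - 1, "y", heading)
            xs[f], ys[f] = x, y
        circ = synthesize_circularity(
            params.n_frames, mode.circ_baseline, mode.circ_noise_sd,
            events, mode.slingshot_delta_c, rng,
        )
        elong = np.clip(1.0 / np.sqrt(np.clip(circ, 0.05, 1.0)), 1.0, 5.0)
        tracks.append(Track(track_id=i, frames=np.arange(params.n_frames),
                            x=xs, y=ys, calibration=cal))
        shapes.append(ShapeSeries(cell_id=i, circularity=circ, elongation=elong))
        events_all.append(events)
    return GroundTruth(tracks=tracks, shapes=shapes,
                       slingshot_frames=events_all, params=params)


def _initial_positions(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    w, h = params.field_size
    m = params.margin_px
    if 2 * m >= min(w, h):
        raise ValueError("margin too large for the field")
    if params.placement == "uniform":
        return np.column_stack(
            [rng.uniform(m, w - m, params.n_cells),
             rng.uniform(m, h - m, params.n_cells)]
        )
    # grid placement: near-square lattice covering the field interior,
    # useful when guaranteed inter-cell spacing is needed
    n = params.n_cells
    cols = math.ceil(math.sqrt(n * (w - 2 * m) / max(h - 2 * m, 1)))
    cols = max(cols, 1)
    rows = math.ceil(n / cols)
    gx = np.linspace(m, w - m, cols)
    gy = np.linspace(m, h - m, rows)
    pts = np.array([(x, y) for y in gy for x in gx])[:n]
    return pts


def _reflect(v: float, vmax: float, axis: str, heading: float):
    """Reflect a coordinate into [0, vmax], mirroring the heading."""
    flipped = False
    while v < 0 or v > vmax:
        v = -v if v < 0 else 2 * vmax - v
        flipped = True
    if flipped:
        heading = math.pi - heading if axis == "x" else -heading
    return v, heading


# ---------------------------------------------------------------------------
# rendering

#: Base Gaussian sigma of a rendered cell spot, px.
SPOT_SIGMA = 2.5
#: Integrated intensity of one rendered cell, arbitrary camera units.
SPOT_INTENSITY = 50_000.0
#: Camera offset and read-noise sd of the rendered background.
BACKGROUND_MEAN = 100.0
BACKGROUND_NOISE_SD = 10.0


def render_movie(
    truth: GroundTruth,
    params: SimParams | None = None,
    spot_sigma: float = SPOT_SIGMA,
    intensity: float = SPOT_INTENSITY,
    background: float = BACKGROUND_MEAN,
    noise_sd: float = BACKGROUND_NOISE_SD,
) -> np.ndarray:
    """Render ground-truth tracks into a 16-bit movie stack (T, H, W).

    Each visible cell is an elliptical Gaussian spot: the axis ratio
    encodes the frame's elongation (area-preserving, so the integrated
    intensity stays constant), the major axis is aligned with the last
    step direction. Cells are omitted independently per frame with
    ``detection_dropout_prob``; Gaussian background noise is added.
    """
    params = params or truth.params
    w, h = params.field_size
    if min(w, h) < 8 * spot_sigma:
        raise ValueError("field too small for the requested spot size")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 7]))
    stack = np.empty((params.n_frames, h, w), dtype=np.uint16)
    # pre-draw dropout so the noise stream is independent of n_cells
    visible = rng.random((params.n_frames, len(truth.tracks))) >= params.detection_dropout_prob
    for f in range(params.n_frames):
        img = np.full((h, w), background, dtype=float)
        for i, tr in enumerate(truth.tracks):
            if not visible[f, i]:
                continue
            e = float(truth.shapes[i].elongation[f]) if truth.shapes[i].elongation is not None else 1.0
            if f > 0:
                theta = math.atan2(tr.y[f] - tr.y[f - 1], tr.x[f] - tr.x[f - 1])
            else:
                theta = 0.0
            _add_spot(img, tr.x[f], tr.y[f], spot_sigma, e, theta, intensity)
        img += rng.normal(0.0, noise_sd, size=img.shape)
        stack[f] = np.clip(img, 0, 65535).astype(np.uint16)
    return stack


def _add_spot(img, x, y, sigma, elong, theta, intensity):
    sa = sigma * math.sqrt(elong)
    sb = sigma / math.sqrt(elong)
    half = int(math.ceil(4 * sa))
    r0, r1 = int(y) - half, int(y) + half + 1
    c0, c1 = int(x) - half, int(x) + half + 1
    r0c, c0c = max(r0, 0), max(c0, 0)
    r1c, c1c = min(r1, img.shape[0]), min(c1, img.shape[1])
    if r0c >= r1c or c0c >= c1c:
        return
    yy, xx = np.mgrid[r0c:r1c, c0c:c1c]
    dx, dy = xx - x, yy - y
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    amp = intensity / (2 * math.pi * sa * sb)
    img[r0c:r1c, c0c:c1c] += amp * np.exp(-0.5 * ((u / sa) ** 2 + (v / sb) ** 2))


def write_movie(stack: np.ndarray, path, calibration: Calibration) -> None:
    """Write a movie/stack as multi-page 16-bit TIFF with calibration
    metadata (ImageJ convention) and a YAML sidecar."""
    res = 1.0 / calibration.microns_per_pixel
    tifffile.imwrite(
        path, stack, imagej=True, resolution=(res, res),
        metadata={
            "unit": "um",
            "finterval": calibration.minutes_per_frame * 60.0,
            "axes": "TYX",
        },
    )
    sidecar = str(path) + ".yaml"
    with open(sidecar, "w") as fh:
        yaml.safe_dump(
            {"microns_per_pixel": calibration.microns_per_pixel,
             "minutes_per_frame": calibration.minutes_per_frame},
            fh,
        )


# ---------------------------------------------------------------------------
# z-stacks

def simulate_zstack(
    n_slices: int,
    ventral_fraction: float,
    total_intensity: float = 1e6,
    noise_sd: float = 5.0,
    shape: tuple[int, int] = (96, 96),
    spot_sigma: float = 8.0,
    background: float = 50.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Confocal z-stack of one cell with a known ventral intensity split.

    Slice 0 (ventral, closest to the coverslip) carries
    ``ventral_fraction x total_intensity``; the remainder is split evenly
    over the other slices. Each slice renders the cell as a centred
    Gaussian spot on a constant background with per-pixel Gaussian noise.

    Returns
    -------
    stack : ndarray (n_slices, H, W), uint16, z ascending from ventral
    true_profile : ndarray (n_slices,) of the generating per-slice
        integrated intensities.
    """
    if n_slices < 2:
        raise ValueError("n_slices must be >= 2")
    if not 0 <= ventral_fraction <= 1:
        raise ValueError("ventral_fraction must be in [0, 1]")
    if total_intensity < 0:
        raise ValueError("total_intensity must be >= 0")
    rng = np.random.default_rng(seed)
    profile = np.full(n_slices, total_intensity * (1 - ventral_fraction) / (n_slices - 1))
    profile[0] = total_intensity * ventral_fraction
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    g = np.exp(-0.5 * (((xx - w / 2) ** 2 + (yy - h / 2) ** 2) / spot_sigma**2))
    g /= g.sum()
    stack = np.empty((n_slices, h, w), dtype=np.uint16)
    for z in range(n_slices):
        img = background + profile[z] * g
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        stack[z] = np.clip(img, 0, 65535).astype(np.uint16)
    return stack, profile


def zstack_cell_mask(
    shape: tuple[int, int] = (96, 96), spot_sigma: float = 8.0
) -> np.ndarray:
    """Circular mask covering the rendered z-stack cell (radius 4 sigma)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - w / 2) ** 2 + (yy - h / 2) ** 2 <= (4 * spot_sigma) ** 2


# ---------------------------------------------------------------------------
# adhesion fields

def simulate_adhesion_field(
    n_pre: int,
    detach_prob: float,
    seed: int = 0,
    field_size: tuple[int, int] = (1024, 1024),
) -> tuple[np.ndarray, np.ndarray]:
    """Pre/post-wash cell positions for the adhesion assay.

    The pre-wash set is uniform over the field; each cell is removed
    independently with ``detach_prob`` to form the post-wash set.
    """
    if not 0 <= detach_prob <= 1:
        raise ValueError("detach_prob must be in [0, 1]")
    if n_pre < 0:
        raise ValueError("n_pre must be >= 0")
    rng = np.random.default_rng(seed)
    w, h = field_size
    pre = np.column_stack([rng.uniform(0, w, n_pre), rng.uniform(0, h, n_pre)])
    keep = rng.random(n_pre) >= detach_prob
    return pre, pre[keep]


# ---------------------------------------------------------------------------
# ground-truth I/O and config

def ground_truth_to_dataframe(truth: GroundTruth):
    """Tidy ground truth table: one row per (track, frame)."""
    import pandas as pd

    rows = []
    for tr, sh, ev in zip(truth.tracks, truth.shapes, truth.slingshot_frames):
        ev_set = set(ev)
        for k, f in enumerate(tr.frames):
            rows.append(
                (tr.track_id, int(f), tr.x[k], tr.y[k],
                 sh.circularity[k],
                 sh.elongation[k] if sh.elongation is not None else np.nan,
                 int(f in ev_set))
            )
    return pd.DataFrame(
        rows,
        columns=["track_id", "frame", "x_px", "y_px",
                 "circularity", "elongation", "is_slingshot"],
    )


def write_ground_truth(truth: GroundTruth, path) -> None:
    ground_truth_to_dataframe(truth).to_csv(path, index=False)


def params_to_yaml(params: SimParams, path) -> None:
    d = asdict(params)
    d["field_size"] = list(params.field_size)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)


def params_from_yaml(path) -> SimParams:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["calibration"] = Calibration(**d.get("calibration", {}))
    d["mode"] = ModeParams(**d.get("mode", {}))
    d["field_size"] = tuple(d.get("field_size", (1024, 1024)))
    return SimParams(**d)
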