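"""Intensity-based quantifications.

Covers the fixed-image measurements of the study: the ventral fraction of
a confocal z-stack (share of a cell's total fluorescence in the lowest,
coverslip-proximal slice — a proxy for myosin II localisation at the
adhesive plane), in-mask intensity statistics, five-position coating
uniformity, blot band densitometry ratios, and the pre/post-wash adhesion
ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .trackio import TrackingConfig, detect_cells

__all__ = [
    "ZProfile",
    "AdhesionResult",
    "BandQuant",
    "IntensityStats",
    "CoatingUniformity",
    "ventral_fraction",
    "mean_intensity_in_mask",
    "coating_uniformity",
    "band_ratio",
    "adhesion_ratio",
    "adhesion_ratio_from_images",
]

log = logging.getLogger(__name__)


@dataclass
class ZProfile:
    """Per-slice integrated intensity of one cell, z=0 = ventral slice."""

    cell_id: int
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1 or len(self.intensities) < 2:
            raise ValueError("a z-profile needs >= 2 slices")
        if np.any(self.intensities < 0):
            raise ValueError("slice intensities must be >= 0")
        if self.intensities.sum() <= 0:
            raise ValueError("total intensity is zero")

    @property
    def fractions(self) -> np.ndarray:
        """Per-slice share of the total; sums to 1."""
        return self.intensities / self.intensities.sum()

    @property
    def ventral_fraction(self) -> float:
        """I_0 / sum(I_z); larger = more signal at the cell bottom."""
        return float(self.fractions[0])


@dataclass(frozen=True)
class AdhesionResult:
    pre_count: int
    post_count: int
    ratio: float


@dataclass(frozen=True)
class BandQuant:
    target_intensity: float
    control_intensity: float
    normalized: float


@dataclass(frozen=True)
class IntensityStats:
    area: int
    mean: float
    min: float
    max: float


@dataclass(frozen=True)
class CoatingUniformity:
    positions: dict  # name -> mean gray value
    mean: float
    cv: float


def ventral_fraction(
    stack: np.ndarray,
    masks: np.ndarray,
    cell_id: int = 0,
    background: str = "border_median",
    border_px: int = 3,
) -> ZProfile:
    """Integrated in-mask intensity per slice and the ventral fraction.

    Slice 0 must be the ventral slice (closest to the coverslip; stack
    acquisition order is the caller's responsibility to declare). Per
    slice, the median of the cell-free image border is subtracted
    (``background="none"`` disables this), negative pixels are clipped to
    zero, and intensity is summed inside the slice's mask.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be (n_slices, H, W) with >= 2 slices")
    masks = np.asarray(masks).astype(bool)
    if masks.ndim == 2:
        masks = np.broadcast_to(masks, stack.shape)
    if masks.shape != stack.shape:
        raise ValueError("masks must match the stack shape")

    intensities = np.empty(stack.shape[0])
    for z in range(stack.shape[0]):
        img = stack[z]
        if background == "border_median":
            border = np.concatenate([
                img[:border_px].ravel(), img[-border_px:].ravel(),
                img[:, :border_px].ravel(), img[:, -border_px:].ravel(),
            ])
            img = np.clip(img - np.median(border), 0, None)
        elif background != "none":
            raise ValueError(f"unknown background mode: {background!r}")
        intensities[z] = img[masks[z]].sum()
    return ZProfile(cell_id=cell_id, intensities=intensities)


def mean_intensity_in_mask(image: np.ndarray, mask: np.ndarray) -> IntensityStats:
    """Area, mean, min and max of raw pixel values inside a mask.

    Display-range settings affect visualisation only; measurements use
    raw values. A warning is logged when the in-mask maximum saturates
    the integer dtype (only unsaturated exposures should be analysed).
    """
    image = np.asarray(image)
    mask = np.asarray(mask).astype(bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("mask is empty")
    vals = image[mask]
    vmax = float(vals.max())
    if np.issubdtype(image.dtype, np.integer) and vmax == np.iinfo(image.dtype).max:
        log.warning("in-mask maximum equals the dtype maximum: possible saturation")
    return IntensityStats(
        area=int(mask.sum()), mean=float(vals.mean()),
        min=float(vals.min()), max=vmax,
    )


_POSITIONS = ("top_left", "top_right", "center", "bottom_left", "bottom_right")


def coating_uniformity(image: np.ndarray, square_size: int) -> CoatingUniformity:
    """Mean gray value of a square at the four corners and the centre.

    Returns the five values plus their mean and coefficient of variation
    (population sd / mean); a perfectly uniform coating gives CV 0.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    s = int(square_size)
    if s <= 0 or s > h or s > w:
        raise ValueError("square does not fit in the image")
    cr, cc = (h - s) // 2, (w - s) // 2
    offsets = {
        "top_left": (0, 0),
        "top_right": (0, w - s),
        "center": (cr, cc),
        "bottom_left": (h - s, 0),
        "bottom_right": (h - s, w - s),
    }
    values = {
        name: float(image[r : r + s, c : c + s].mean())
        for name, (r, c) in offsets.items()
    }
    arr = np.array([values[p] for p in _POSITIONS])
    mean = float(arr.mean())
    cv = float(arr.std() / mean) if mean != 0 else float("nan")
    return CoatingUniformity(positions=values, mean=mean, cv=cv)


def band_ratio(target_box: np.ndarray, control_box: np.ndarray) -> BandQuant:
    """Densitometry ratio: total target intensity over total control
    (loading-control) intensity, from identically sized boxes."""
    target_box = np.asarray(target_box, dtype=float)
    control_box = np.asarray(control_box, dtype=float)
    if target_box.shape != control_box.shape:
        raise ValueError("target and control boxes must be identically sized")
    control = float(control_box.sum())
    if control <= 0:
        raise ValueError("control intensity must be > 0")
    target = float(target_box.sum())
    return BandQuant(target_intensity=target, control_intensity=control,
                     normalized=target / control)


def _as_count(obj) -> int:
    if np.isscalar(obj):
        return int(obj)
    arr = np.asarray(obj)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return len(arr)
    raise ValueError("expected a count or an (n, 2) point set")


def adhesion_ratio(pre, post) -> AdhesionResult:
    """Bound-cell ratio: post-wash count over pre-wash count.

    1 = 100% adherence. Accepts counts or (n, 2) point sets. The ratio is
    not clipped; counting noise can push it above 1, which is logged.
    """
    pre_count, post_count = _as_count(pre), _as_count(post)
    if pre_count <= 0:
        raise ValueError("pre-wash count must be > 0")
    ratio = post_count / pre_count
    if ratio > 1:
        log.warning("adhesion ratio %.3f > 1 (counting noise)", ratio)
    return AdhesionResult(pre_count=pre_count, post_count=post_count, ratio=ratio)


def adhesion_ratio_from_images(
    pre_image: np.ndarray,
    post_image: np.ndarray,
    config: TrackingConfig | None = None,
) -> AdhesionResult:
    """Adhesion ratio from pre/post-wash images via spot detection."""
    config = config or TrackingConfig()
    pre = detect_cells(pre_image, config)
    post = detect_cells(post_image, config)
    return adhesion_ratio(len(pre), len(post))
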