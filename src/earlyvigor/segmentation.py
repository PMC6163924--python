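"""Canopy-cover extraction from quadrat RGB images by HSV thresholding.

A pixel is counted as vegetation when its hue falls inside a green window
and its saturation and value clear minimum thresholds; canopy cover (CC)
is the fraction of vegetation pixels.  This formalizes the manual
"adapt HSV thresholds on a few images, keep them fixed" workflow used with
interactive tools: :func:`calibrate_thresholds` grid-searches the window
against reference masks, and the result is then applied unchanged to the
whole image set of a date.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage.color import rgb2hsv

from ._exceptions import CalibrationError

__all__ = [
    "HsvThresholds",
    "SegmentationResult",
    "DEFAULT_THRESHOLDS",
    "crop_quadrat",
    "rgb_to_hsv",
    "segment_green",
    "calibrate_thresholds",
    "load_image",
    "save_mask",
    "segment_batch",
]


@dataclass(frozen=True)
class HsvThresholds:
    """Vegetation window in HSV space.

    Hue bounds are degrees in [0, 360); a window with ``hue_min > hue_max``
    wraps across 0 degrees.  ``sat_min`` and ``val_min`` are fractions.
    """

    hue_min: float
    hue_max: float
    sat_min: float = 0.15
    val_min: float = 0.0

    def __post_init__(self) -> None:
        for h in (self.hue_min, self.hue_max):
            if not 0.0 <= h < 360.0:
                raise ValueError(f"hue bound {h} outside [0, 360)")
        if self.hue_min == self.hue_max:
            raise ValueError("empty hue window")
        if not 0.0 <= self.sat_min <= 1.0 or not 0.0 <= self.val_min <= 1.0:
            raise ValueError("sat_min and val_min must be fractions")

    def hue_mask(self, hue_deg: np.ndarray) -> np.ndarray:
        if self.hue_min < self.hue_max:
            return (hue_deg >= self.hue_min) & (hue_deg <= self.hue_max)
        return (hue_deg >= self.hue_min) | (hue_deg <= self.hue_max)


#: Defaults covering green plant material generously while excluding brown
#: soil; the value floor only rejects near-black pixels.
DEFAULT_THRESHOLDS = HsvThresholds(60.0, 180.0, sat_min=0.15, val_min=0.05)


@dataclass
class SegmentationResult:
    """Binary vegetation mask and the derived canopy-cover fraction."""

    mask: np.ndarray
    n_vegetation_pixels: int
    n_total_pixels: int

    @property
    def canopy_cover(self) -> float:
        return self.n_vegetation_pixels / self.n_total_pixels


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB array")
    if image.size == 0:
        raise ValueError("empty image")
    if image.dtype != np.uint8:
        raise ValueError("expected 8-bit RGB (uint8)")
    return image


def crop_quadrat(image: np.ndarray, corners: Sequence[Sequence[float]]) -> np.ndarray:
    """Crop to the bounding box of four corner points (x, y).

    The corners must form a convex, non-degenerate quadrilateral inside the
    image.  A perspective warp is deliberately not applied: quadrats are
    photographed near-nadir and the reference workflow cropped rectangles.
    """
    image = _check_image(image)
    pts = np.asarray(corners, dtype=float)
    if pts.shape != (4, 2):
        raise ValueError("corners must be four (x, y) points")
    h, w = image.shape[:2]
    if np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > w - 1) or np.any(
        pts[:, 1] < 0
    ) or np.any(pts[:, 1] > h - 1):
        raise ValueError("corner outside image bounds")
    # strict convexity: all consecutive edge cross products share one sign
    cross = []
    for i in range(4):
        a, b, c = pts[i], pts[(i + 1) % 4], pts[(i + 2) % 4]
        u, v = b - a, c - b
        cross.append(u[0] * v[1] - u[1] * v[0])
    cross = np.asarray(cross)
    if np.any(cross == 0) or not (np.all(cross > 0) or np.all(cross < 0)):
        raise ValueError("corners do not form a convex quadrilateral")
    x0, y0 = np.floor(pts.min(axis=0)).astype(int)
    x1, y1 = np.ceil(pts.max(axis=0)).astype(int)
    return image[y0 : y1 + 1, x0 : x1 + 1]


def rgb_to_hsv(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hexcone HSV transform: (hue degrees, saturation, value) arrays.

    Hue is set to 0 where saturation is 0 (achromatic pixels).
    """
    image = _check_image(image)
    hsv = rgb2hsv(image)
    return hsv[..., 0] * 360.0, hsv[..., 1], hsv[..., 2]


def segment_green(
    image: np.ndarray, thresholds: HsvThresholds = DEFAULT_THRESHOLDS,
    min_component_px: int = 0,
) -> SegmentationResult:
    """Classify pixels as vegetation by the HSV window and count them.

    ``min_component_px`` optionally removes connected vegetation components
    smaller than the given pixel count (off by default; useful on real
    photographs with speckle noise).
    """
    hue, sat, val = rgb_to_hsv(image)
    mask = thresholds.hue_mask(hue) & (sat >= thresholds.sat_min) & (
        val >= thresholds.val_min
    )
    if min_component_px > 0:
        from skimage.morphology import remove_small_objects

        mask = remove_small_objects(mask, min_size=min_component_px)
    return SegmentationResult(
        mask=mask,
        n_vegetation_pixels=int(mask.sum()),
        n_total_pixels=int(mask.size),
    )


def calibrate_thresholds(
    reference_images: Sequence[np.ndarray],
    reference_masks: Sequence[np.ndarray],
    hue_min_grid: Sequence[float] = (30, 40, 50, 60, 70, 80, 90),
    hue_max_grid: Sequence[float] = (140, 150, 160, 170, 180, 190),
    sat_min_grid: Sequence[float] = (0.05, 0.10, 0.15, 0.20, 0.30),
    val_min: float = 0.05,
) -> HsvThresholds:
    """Grid-search HSV thresholds against reference vegetation masks.

    Maximizes the mean pixel-wise Jaccard overlap with the reference masks.
    Ties are resolved toward the more inclusive setting: lower ``sat_min``,
    then the wider hue window, then the lower ``hue_min``.
    """
    if len(reference_images) == 0 or len(reference_images) != len(reference_masks):
        raise CalibrationError("need >= 1 matching image/mask pair")
    masks = [np.asarray(m, dtype=bool) for m in reference_masks]
    if not any(m.any() for m in masks):
        raise CalibrationError("all reference masks are empty")
    hsv = [rgb_to_hsv(img) for img in reference_images]

    best_key, best = None, None
    for sat_min in sat_min_grid:
        for hue_min in hue_min_grid:
            for hue_max in hue_max_grid:
                thr = HsvThresholds(hue_min, hue_max, sat_min, val_min)
                scores = []
                for (hue, sat, val), ref in zip(hsv, masks):
                    pred = thr.hue_mask(hue) & (sat >= sat_min) & (val >= val_min)
                    union = np.logical_or(pred, ref).sum()
                    inter = np.logical_and(pred, ref).sum()
                    scores.append(1.0 if union == 0 else inter / union)
                key = (
                    float(np.mean(scores)),
                    -sat_min,
                    hue_max - hue_min,
                    -hue_min,
                )
                if best_key is None or key > best_key:
                    best_key, best = key, thr
    return best


# ---------------------------------------------------------------------------
# I/O helpers


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG as an (H, W, 3) uint8 RGB array."""
    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"))


def save_mask(mask: np.ndarray, path) -> None:
    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(path)


def segment_batch(
    images: dict,
    thresholds: HsvThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Segment a mapping of image_id -> RGB array into a CC table."""
    rows = []
    for image_id, image in images.items():
        res = segment_green(image, thresholds)
        rows.append(
            {
                "image_id": image_id,
                "canopy_cover": res.canopy_cover,
                "n_veg": res.n_vegetation_pixels,
                "n_total": res.n_total_pixels,
            }
        )
    return pd.DataFrame(rows)
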