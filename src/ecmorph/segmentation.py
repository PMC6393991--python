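"""Sirius-red collagen segmentation and ECM surface measurement.

PicroSirius red stains fibrillar collagen red/magenta against the pale-yellow
counterstained parenchyma.  Collagen pixels are classified by a colour rule —
by default a wrapping hue band in HSV space, optionally a pure-RGB dominance
rule — restricted to the tissue mask.  Connected runs of collagen pixels are
the *collagen islets*; their summed area over the tissue area is the
Sirius-red-stained ECM surface percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv

from .errors import DegenerateInputError, ValidationError
from .imaging import BinaryMask, MaskKind, RGBImage


@dataclass(frozen=True)
class SegmentationConfig:
    """Colour rule for collagen pixels.

    The hue band is given in degrees on the 0–360 colour wheel and may wrap
    through 0° (the default red band [330°, 25°] does).  ``rule="rgb"``
    switches to the dominance rule ``R > G + margin and R > B + margin``.
    """

    hue_low: float = 330.0
    hue_high: float = 25.0
    sat_min: float = 0.25
    val_min: float = 0.20
    min_islet_pixels: int = 0
    rule: str = "hsv"        # "hsv" or "rgb"
    rgb_margin: int = 30     # used only by the "rgb" rule

    def __post_init__(self) -> None:
        if not (0.0 <= self.sat_min <= 1.0 and 0.0 <= self.val_min <= 1.0):
            raise ValidationError("sat_min and val_min must lie in [0, 1]")
        if self.min_islet_pixels < 0:
            raise ValidationError("min_islet_pixels must be >= 0")
        if self.rule not in ("hsv", "rgb"):
            raise ValidationError(f"unknown segmentation rule {self.rule!r}")


@dataclass(frozen=True)
class IsletSet:
    """Connected collagen components after size filtering.

    ``labels`` is an integer raster (0 = background, k = islet k);
    ``areas[k-1]`` is the pixel count of islet k.
    """

    labels: np.ndarray
    areas: np.ndarray

    @property
    def n_islets(self) -> int:
        return int(len(self.areas))

    def total_area(self) -> int:
        return int(self.areas.sum()) if self.n_islets else 0

    def to_mask(self) -> BinaryMask:
        return BinaryMask(grid=self.labels > 0, kind=MaskKind.COLLAGEN)


def _hue_in_band(hue_deg: np.ndarray, low: float, high: float) -> np.ndarray:
    low %= 360.0
    high %= 360.0
    if low <= high:
        return (hue_deg >= low) & (hue_deg <= high)
    return (hue_deg >= low) | (hue_deg <= high)  # band wraps through 0°


def segment_collagen(
    img: RGBImage,
    tissue: BinaryMask,
    config: "SegmentationConfig | None" = None,
) -> BinaryMask:
    """Classify collagen pixels within the tissue mask.

    The returned collagen mask is always a subset of the tissue mask.
    Thresholds are global per run, never adapted per image.
    """
    config = config or SegmentationConfig()
    if tissue.shape != (img.height, img.width):
        raise ValidationError(
            f"tissue mask shape {tissue.shape} does not match image "
            f"{(img.height, img.width)}"
        )
    if config.rule == "rgb":
        px = img.pixels.astype(np.int16)
        m = config.rgb_margin
        colour = (px[:, :, 0] > px[:, :, 1] + m) & (px[:, :, 0] > px[:, :, 2] + m)
    else:
        hsv = rgb2hsv(img.pixels)
        hue_deg = hsv[:, :, 0] * 360.0
        colour = (
            _hue_in_band(hue_deg, config.hue_low, config.hue_high)
            & (hsv[:, :, 1] >= config.sat_min)
            & (hsv[:, :, 2] >= config.val_min)
        )
    return BinaryMask(grid=colour & tissue.grid, kind=MaskKind.COLLAGEN)


_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool),
    8: np.ones((3, 3), bool),
}


def label_islets(
    mask: BinaryMask,
    connectivity: int = 8,
    min_islet_pixels: int = 0,
) -> IsletSet:
    """Label connected collagen components ("islets").

    Components smaller than ``min_islet_pixels`` are dropped from both the
    label raster and the area list; surviving islets are relabelled 1..n.
    """
    if connectivity not in _STRUCTURES:
        raise ValidationError("connectivity must be 4 or 8")
    labels, n = ndimage.label(mask.grid, structure=_STRUCTURES[connectivity])
    if n == 0:
        return IsletSet(labels=labels, areas=np.zeros(0, dtype=np.int64))
    areas = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    keep = areas >= min_islet_pixels
    if not keep.all():
        remap = np.zeros(n + 1, dtype=labels.dtype)
        remap[1:][keep] = np.arange(1, int(keep.sum()) + 1)
        labels = remap[labels]
        areas = areas[keep]
    return IsletSet(labels=labels, areas=areas.astype(np.int64))


def ecm_surface_percent(islets: IsletSet, tissue: BinaryMask) -> float:
    """Summed islet area as a percentage of the tissue surface area."""
    denom = tissue.foreground_count()
    if denom == 0:
        raise DegenerateInputError(
            "tissue mask is empty; ECM surface percentage is undefined"
        )
    return 100.0 * islets.total_area() / denom
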