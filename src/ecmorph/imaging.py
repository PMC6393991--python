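"""Image ingestion, tissue masking and cohort bookkeeping.

A region of interest (ROI) is one digitized brightfield microscope field of a
Sirius-red-stained pancreas section.  Everything downstream works on two
rasters derived here:

* an :class:`RGBImage` — the 8-bit colour field plus case/group metadata, and
* a tissue :class:`BinaryMask` — the pixels that actually contain tissue,
  excluding the near-white glass background and tears/holes introduced by
  specimen handling.

All masks share the image's pixel grid: 0-based, row-major, origin at the
top-left corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import CohortEmptyError, ValidationError

MIN_IMAGE_SIDE = 16


class Group(str, Enum):
    """Histological group of a case."""

    NPA = "nPA"     # natural (normal) pancreatic tissue
    IPA = "iPA"     # inflammatory: chronic pancreatitis
    PDAC = "PDAC"   # pancreatic ductal adenocarcinoma
    OTHER = "other"

    @classmethod
    def parse(cls, value: "str | Group") -> "Group":
        if isinstance(value, Group):
            return value
        for member in cls:
            if member.value.lower() == str(value).strip().lower():
                return member
        raise ValidationError(
            f"unknown group {value!r}; expected one of "
            f"{[m.value for m in cls]}"
        )


class MaskKind(str, Enum):
    TISSUE = "tissue"
    COLLAGEN = "collagen"
    GENERIC = "generic"


@dataclass(frozen=True)
class RGBImage:
    """One digitized ROI: H×W×3 uint8 pixels plus provenance metadata."""

    pixels: np.ndarray
    roi_id: str
    case_id: str
    group: Group
    magnification_label: str = "20x"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(
                f"RGBImage requires an H×W×3 array, got shape {px.shape}"
            )
        if px.shape[0] < MIN_IMAGE_SIDE or px.shape[1] < MIN_IMAGE_SIDE:
            raise ValidationError(
                f"image {px.shape[0]}×{px.shape[1]} smaller than the "
                f"{MIN_IMAGE_SIDE}×{MIN_IMAGE_SIDE} minimum"
            )
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValidationError("pixel intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "group", Group.parse(self.group))

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class BinaryMask:
    """Boolean raster aligned with its source image (origin top-left)."""

    grid: np.ndarray
    kind: MaskKind = MaskKind.GENERIC

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2:
            raise ValidationError(f"mask must be 2-D, got shape {g.shape}")
        object.__setattr__(self, "grid", g.astype(bool))
        object.__setattr__(self, "kind", MaskKind(self.kind))

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.grid.shape)  # type: ignore[return-value]

    def foreground_count(self) -> int:
        return int(self.grid.sum())

    def is_empty(self) -> bool:
        return not bool(self.grid.any())

    def to_png(self, path: "str | Path") -> None:
        """Write as single-channel PNG, foreground = 255."""
        Image.fromarray(self.grid.astype(np.uint8) * 255, mode="L").save(path)


def _read_raster(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path))
    with Image.open(path) as im:
        return np.asarray(im)


def load_rgb_image(
    path: "str | Path",
    roi_id: str,
    case_id: str,
    group: "str | Group",
    magnification_label: str = "20x",
) -> RGBImage:
    """Read a PNG or 8-bit TIFF ROI from disk.

    Grayscale inputs are replicated to three channels; an alpha channel is
    dropped.  Images smaller than 16×16 are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    try:
        arr = _read_raster(path)
    except (UnidentifiedImageError, ValueError, OSError) as exc:
        raise IOError(f"cannot decode image {path}: {exc}") from exc

    if arr.ndim == 2:  # grayscale → replicate
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] >= 4:  # drop alpha
        arr = arr[:, :, :3]
    elif arr.ndim == 3 and arr.shape[2] == 3:
        pass
    else:
        raise IOError(f"unsupported raster layout {arr.shape} in {path}")

    if arr.dtype != np.uint8:
        info = np.iinfo(arr.dtype) if np.issubdtype(arr.dtype, np.integer) else None
        if info is not None and info.max > 255:
            arr = (arr.astype(np.float64) * (255.0 / info.max)).round().astype(np.uint8)
        else:
            arr = np.clip(arr, 0, 255).astype(np.uint8)

    return RGBImage(
        pixels=arr,
        roi_id=roi_id,
        case_id=case_id,
        group=Group.parse(group),
        magnification_label=magnification_label,
    )


def compute_tissue_mask(
    img: RGBImage,
    whiteness_threshold: int = 220,
    min_channel_spread: int = 30,
    close_holes: bool = False,
) -> BinaryMask:
    """Mask the pixels that contain tissue.

    A pixel is background (glass / tissue-free space) when it is near-white:
    ``min(R,G,B) >= whiteness_threshold`` and
    ``max(R,G,B) - min(R,G,B) <= min_channel_spread``.
    Every other pixel is tissue.  Pure function of the pixels and thresholds.

    ``close_holes`` applies one pass of 3×3 morphological closing to the
    tissue mask; off by default.
    """
    px = img.pixels.astype(np.int16)
    lo = px.min(axis=2)
    spread = px.max(axis=2) - lo
    non_tissue = (lo >= whiteness_threshold) & (spread <= min_channel_spread)
    tissue = ~non_tissue
    if close_holes:
        from scipy import ndimage

        tissue = ndimage.binary_closing(tissue, structure=np.ones((3, 3), bool))
    return BinaryMask(grid=tissue, kind=MaskKind.TISSUE)


@dataclass
class CohortManifest:
    """Outcome of streaming a cohort: which records failed and why."""

    n_loaded: int = 0
    failures: list[tuple[str, str]] = field(default_factory=list)  # (path, reason)


def iter_cohort(
    records: Sequence[tuple],
    manifest: "CohortManifest | None" = None,
) -> Iterator[RGBImage]:
    """Yield :class:`RGBImage` for each ``(path, roi_id, case_id, group)``
    record, in input order, skipping unreadable files.

    Pass a :class:`CohortManifest` to collect the failure list.  Raises
    :class:`CohortEmptyError` if no record loads.
    """
    if len(records) == 0:
        raise CohortEmptyError("cohort record list is empty")
    manifest = manifest if manifest is not None else CohortManifest()
    yielded = 0
    for rec in records:
        path, roi_id, case_id, group = rec[:4]
        try:
            img = load_rgb_image(path, roi_id=roi_id, case_id=case_id, group=group)
        except (IOError, ValidationError) as exc:
            manifest.failures.append((str(path), str(exc)))
            continue
        yielded += 1
        manifest.n_loaded = yielded
        yield img
    if yielded == 0:
        raise CohortEmptyError(
            f"no image in the cohort could be loaded "
            f"({len(manifest.failures)} failures)"
        )
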