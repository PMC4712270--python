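"""Reading, writing, grayscale conversion and thresholding of microscopy images.

All math modules operate on :class:`GrayImage` / :class:`BinaryMask`; every
file-format concern is isolated here.  Coordinates are row-major ``(row, col)``,
0-based, origin at the top-left corner, everywhere in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import tifffile
from skimage.filters import threshold_otsu

from .errors import DegenerateInputError, ParameterError, UnsupportedFormatError

logger = logging.getLogger(__name__)

#: ITU-R BT.601 luminance weights used for RGB -> gray conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class GrayImage:
    """A calibrated 8-bit grayscale image.

    Parameters
    ----------
    pixels
        2D array of integer intensities in [0, 255]; stored as ``uint8``.
    um_per_pixel
        Physical calibration in micrometres per pixel (> 0).
    meta
        Free-form tags (group, region, marker, animal id, image id, ...).
    """

    pixels: np.ndarray
    um_per_pixel: float = 1.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ParameterError(f"pixels must be a non-empty 2D array, got shape {px.shape}")
        if px.dtype != np.uint8:
            if not np.issubdtype(px.dtype, np.integer):
                raise ParameterError("pixel intensities must be integers")
            if px.min() < 0 or px.max() > 255:
                raise ParameterError("pixel intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        if not self.um_per_pixel > 0:
            raise ParameterError(f"um_per_pixel must be > 0, got {self.um_per_pixel}")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """A {0,1} mask with the shape and calibration of its source image.

    ``provenance`` records how the mask was produced (e.g. the threshold used).
    """

    pixels: np.ndarray
    um_per_pixel: float = 1.0
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ParameterError(f"mask must be 2D, got shape {px.shape}")
        if px.dtype != bool:
            vals = np.unique(px)
            if not np.isin(vals, [0, 1]).all():
                raise ParameterError("mask values must be 0/1")
            px = px.astype(bool)
        if not self.um_per_pixel > 0:
            raise ParameterError(f"um_per_pixel must be > 0, got {self.um_per_pixel}")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def rgb_to_gray(rgb: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB raster to 8-bit luminance.

    Uses BT.601 weights 0.299/0.587/0.114, rounded to the nearest integer.
    Single-marker fluorescence channels are effectively monochrome, so the
    exact weight choice is immaterial; a fixed documented convention keeps
    conversion reproducible.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise UnsupportedFormatError(f"expected an (H, W, 3) raster, got shape {rgb.shape}")
    gray = np.tensordot(rgb.astype(np.float64), LUMA_WEIGHTS, axes=([2], [0]))
    return np.rint(gray).astype(np.uint8)


def read_image(
    path: str | Path,
    um_per_pixel: float | None = None,
    meta: Mapping[str, Any] | None = None,
) -> GrayImage:
    """Read a TIFF as a calibrated :class:`GrayImage`.

    8-bit images pass through unchanged; 16-bit images are rescaled by the
    fixed factor 255/65535 and rounded; RGB images go through
    :func:`rgb_to_gray`.  If no calibration is given, 1.0 um/pixel is assumed
    and a warning is logged so pure-pixel workflows still run.
    """
    path = Path(path)
    try:
        raw = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc

    if raw.ndim == 3:
        if raw.shape[2] == 3:
            raw = rgb_to_gray(raw)
        else:
            raise UnsupportedFormatError(
                f"{path}: only 2D single-channel or RGB images supported, got shape {raw.shape}"
            )
    elif raw.ndim != 2:
        raise UnsupportedFormatError(f"{path}: unsupported dimensionality {raw.ndim}")

    if raw.dtype == np.uint16:
        raw = np.rint(raw.astype(np.float64) * (255.0 / 65535.0)).astype(np.uint8)
    elif raw.dtype != np.uint8:
        raise UnsupportedFormatError(f"{path}: unsupported dtype {raw.dtype}")

    if um_per_pixel is None:
        logger.warning("%s: no calibration supplied, assuming 1.0 um/pixel", path)
        um_per_pixel = 1.0
    return GrayImage(raw, um_per_pixel=um_per_pixel, meta=dict(meta or {}))


def write_image(img: GrayImage | BinaryMask, path: str | Path) -> None:
    """Write an image or mask as an 8-bit single-page TIFF.

    Masks are written with foreground 255 / background 0 for viewability.
    """
    px = img.pixels
    if px.dtype == bool:
        px = px.astype(np.uint8) * 255
    tifffile.imwrite(Path(path), px)


def threshold_image(
    img: GrayImage,
    method: str = "otsu",
    fixed_value: int | None = None,
) -> BinaryMask:
    """Binarize a grayscale image; pixels strictly above the threshold are 1.

    ``method='otsu'`` picks the threshold by Otsu's criterion; a constant
    image has no two classes to separate and raises
    :class:`DegenerateInputError`.  ``method='fixed'`` uses ``fixed_value``.
    The chosen threshold is recorded in the mask's provenance.
    """
    px = img.pixels
    if method == "otsu":
        if px.min() == px.max():
            raise DegenerateInputError(
                f"Otsu threshold undefined for constant image {img.meta.get('image_id', '')!r}"
                f" (all pixels = {int(px.min())})"
            )
        thr = float(threshold_otsu(px))
    elif method == "fixed":
        if fixed_value is None or not 0 <= fixed_value <= 255:
            raise ParameterError(f"fixed_value must be in [0, 255], got {fixed_value}")
        thr = float(fixed_value)
    else:
        raise ParameterError(f"unknown threshold method {method!r}")
    return BinaryMask(
        px > thr,
        um_per_pixel=img.um_per_pixel,
        provenance={"method": method, "threshold": thr},
    )
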