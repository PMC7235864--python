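"""Fixed-coordinate region-of-interest mask for the third-molar band.

On a reference 1200x2400 panoramic radiograph the four third molars fall
inside rows [300, 900) and columns [490, 2200).  The mask marks that band
for feature detection without cropping: pixels outside are zeroed, image
dimensions are untouched, so keypoint coordinates stay in the frame of
the original radiograph.  For other image sizes the band is rescaled
proportionally from the declared reference dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DimensionError

__all__ = ["RoiSpec", "RoiMask", "make_roi_mask", "apply_mask", "overlay_mask"]


@dataclass(frozen=True)
class RoiSpec:
    """Half-open row/column band of the third-molar region.

    Bounds index the reference image size; ``make_roi_mask`` rescales
    them proportionally for other dimensions.
    """

    row_start: int = 300
    row_end: int = 900
    col_start: int = 490
    col_end: int = 2200
    reference_height: int = 1200
    reference_width: int = 2400

    def validate(self) -> None:
        if not (0 <= self.row_start < self.row_end):
            raise ConfigurationError(
                f"need 0 <= row_start < row_end, got [{self.row_start}, {self.row_end})"
            )
        if not (0 <= self.col_start < self.col_end):
            raise ConfigurationError(
                f"need 0 <= col_start < col_end, got [{self.col_start}, {self.col_end})"
            )
        if self.reference_height <= 0 or self.reference_width <= 0:
            raise ConfigurationError("reference dimensions must be positive")


@dataclass(frozen=True)
class RoiMask:
    """Binary inclusion mask plus its pixel count."""

    mask: np.ndarray

    @property
    def included_pixel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(row_start, row_end, col_start, col_end) of the true region, half-open."""
        rows = np.flatnonzero(self.mask.any(axis=1))
        cols = np.flatnonzero(self.mask.any(axis=0))
        if rows.size == 0:
            return (0, 0, 0, 0)
        return (int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)


def _scale(value: int, size: int, reference: int) -> int:
    # proportional rescale, rounded half-up
    return int(np.floor(value * (size / reference) + 0.5))


def make_roi_mask(height: int, width: int, spec: RoiSpec | None = None) -> RoiMask:
    """Build the ROI mask for an ``height`` x ``width`` image.

    For the reference dimensions the bounds apply unscaled; otherwise
    they are rescaled proportionally (rounded half-up).  An empty
    rescaled band is a configuration error.
    """
    spec = spec or RoiSpec()
    spec.validate()
    if height <= 0 or width <= 0:
        raise DimensionError(f"image dimensions must be positive, got {height}x{width}")

    r0 = _scale(spec.row_start, height, spec.reference_height)
    r1 = _scale(spec.row_end, height, spec.reference_height)
    c0 = _scale(spec.col_start, width, spec.reference_width)
    c1 = _scale(spec.col_end, width, spec.reference_width)
    r1 = min(r1, height)
    c1 = min(c1, width)
    if r0 >= r1 or c0 >= c1:
        raise ConfigurationError(
            f"ROI rescaled to an empty range [{r0},{r1})x[{c0},{c1}) on a "
            f"{height}x{width} image; minimum usable size keeps at least one "
            f"pixel of the band (reference {spec.reference_height}x{spec.reference_width})"
        )
    mask = np.zeros((height, width), dtype=bool)
    mask[r0:r1, c0:c1] = True
    return RoiMask(mask=mask)


def apply_mask(img: np.ndarray, roi: RoiMask) -> np.ndarray:
    """Zero out pixels outside the mask; dimensions unchanged (mask, not crop)."""
    img = np.asarray(img)
    if img.shape != roi.mask.shape:
        raise DimensionError(
            f"image shape {img.shape} does not match mask shape {roi.mask.shape}"
        )
    out = img.copy()
    out[~roi.mask] = 0
    return out


def overlay_mask(img: np.ndarray, roi: RoiMask) -> np.ndarray:
    """RGB visual-audit overlay: masked band highlighted in green."""
    img = np.asarray(img)
    if img.shape != roi.mask.shape:
        raise DimensionError(
            f"image shape {img.shape} does not match mask shape {roi.mask.shape}"
        )
    rgb = np.stack([img, img, img], axis=-1).astype(np.float64)
    rgb[roi.mask, 1] = np.clip(rgb[roi.mask, 1] * 0.5 + 128, 0, 255)
    return np.clip(np.floor(rgb + 0.5), 0, 255).astype(np.uint8)
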