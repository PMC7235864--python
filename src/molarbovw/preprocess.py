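"""Radiograph smoothing and edge-detection chain.

The chain prepares a panoramic radiograph for keypoint detection:

1. 3x3 median filter — suppresses quantum mottle (photon-count speckle);
2. bilateral filter (diameter 9, sigma_color = sigma_space = 75) —
   edge-preserving smoothing of the remaining noise;
3. Sobel X/Y gradients;
4. gradients rectified to 8-bit magnitude and blended into one edge image.

All windowed operators use reflect-101 border padding (the edge pixel is
not duplicated), so a constant image never acquires a dark frame that
would later spawn spurious keypoints.  Every conversion to 8-bit rounds
half-up (``floor(x + 0.5)``) so the operators are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DimensionError, FormatError, ParameterError

__all__ = [
    "FilterParams",
    "to_grayscale",
    "median_filter",
    "bilateral_filter",
    "sobel_gradients",
    "blend_gradients",
    "preprocess_chain",
]

# Sobel cross-correlation kernels (X = horizontal gradient).
SOBEL_KX = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.int64)
SOBEL_KY = SOBEL_KX.T.copy()

#: Rec.601 luma weights used for RGB -> gray conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with ties away from zero-ward .5 going up."""
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


def _as_uint8(x: np.ndarray) -> np.ndarray:
    return np.clip(_round_half_up(x), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class FilterParams:
    """Parameters of the smoothing/edge chain.

    Defaults are the reference operating point: median kernel 3,
    bilateral diameter 9 with sigma_color = sigma_space = 75, and an
    even 0.5/0.5 blend of the two rectified Sobel gradients.
    """

    median_kernel: int = 3
    bilateral_diameter: int = 9
    sigma_color: float = 75.0
    sigma_space: float = 75.0
    blend_wx: float = 0.5
    blend_wy: float = 0.5

    def validate(self) -> None:
        if self.median_kernel < 3 or self.median_kernel % 2 == 0:
            raise ParameterError(
                f"median_kernel must be odd and >= 3, got {self.median_kernel}"
            )
        if self.bilateral_diameter < 3 or self.bilateral_diameter % 2 == 0:
            raise ParameterError(
                f"bilateral_diameter must be odd and >= 3, got {self.bilateral_diameter}"
            )
        if self.sigma_color <= 0 or self.sigma_space <= 0:
            raise ParameterError("sigma_color and sigma_space must be > 0")
        if self.blend_wx < 0 or self.blend_wy < 0:
            raise ParameterError("blend weights must be >= 0")


def _check_image(img: np.ndarray, min_side: int = 3) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise DimensionError(f"expected a single-channel image, got shape {img.shape}")
    if min(img.shape) < min_side:
        raise DimensionError(
            f"image {img.shape} too small; both sides must be >= {min_side}"
        )
    return img


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert a 1- or 3-channel 8-bit image to single-channel grayscale.

    3-channel input is combined with the fixed luma weights
    (0.299, 0.587, 0.114), rounded half-up; grayscale input (including a
    trailing singleton channel) passes through unchanged.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        return image.astype(np.uint8, copy=False)
    if image.ndim == 3 and image.shape[2] == 1:
        return image[:, :, 0].astype(np.uint8, copy=False)
    if image.ndim == 3 and image.shape[2] == 3:
        gray = np.tensordot(image.astype(np.float64), LUMA_WEIGHTS, axes=([2], [0]))
        return _as_uint8(gray)
    if image.ndim == 3 and image.shape[2] == 4:
        # Alpha is irrelevant for radiographs; drop it.
        return to_grayscale(image[:, :, :3])
    raise FormatError(
        f"unsupported channel layout {image.shape}; expected 1 or 3 channels"
    )


def median_filter(img: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Median filter with a ``kernel`` x ``kernel`` window, reflect-101 borders."""
    img = _check_image(img)
    if kernel % 2 == 0:
        raise ParameterError(f"median kernel must be odd, got {kernel}")
    if kernel < 3 or kernel > min(img.shape):
        raise ParameterError(
            f"median kernel must be in [3, {min(img.shape)}], got {kernel}"
        )
    # scipy's 'mirror' mode is reflect-101 padding.
    return ndimage.median_filter(img.astype(np.uint8), size=kernel, mode="mirror")


def bilateral_filter(img: np.ndarray, params: FilterParams | None = None) -> np.ndarray:
    """Edge-preserving bilateral filter over a square diameter x diameter window.

    output(p) = sum_q I(q) w_s(||p-q||) w_c(|I(q)-I(p)|) / sum_q w_s w_c
    with Gaussian spatial and range kernels.  The 8-bit input makes the
    range kernel a 256-entry lookup table, so the double sum reduces to
    one vectorised pass per window offset.
    """
    params = params or FilterParams()
    params.validate()
    img = _check_image(img).astype(np.uint8)
    d = params.bilateral_diameter
    r = d // 2
    h, w = img.shape

    color_lut = np.exp(
        -(np.arange(256, dtype=np.float64) ** 2) / (2.0 * params.sigma_color**2)
    ).astype(np.float32)
    padded_i = np.pad(img, r, mode="reflect").astype(np.int16)  # reflect-101
    padded_f = padded_i.astype(np.float32)
    center = padded_i[r : r + h, r : r + w]
    num = np.zeros((h, w), dtype=np.float32)
    den = np.zeros((h, w), dtype=np.float32)
    for di in range(-r, r + 1):
        for dj in range(-r, r + 1):
            ws = np.float32(
                np.exp(-(di * di + dj * dj) / (2.0 * params.sigma_space**2))
            )
            view_i = padded_i[r + di : r + di + h, r + dj : r + dj + w]
            weight = color_lut[np.abs(view_i - center)]
            weight *= ws
            num += weight * padded_f[r + di : r + di + h, r + dj : r + dj + w]
            den += weight
    return _as_uint8(num / den)


def sobel_gradients(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Signed Sobel X and Y gradients (cross-correlation, reflect-101 borders)."""
    img = _check_image(img)
    src = img.astype(np.int64)
    gx = ndimage.correlate(src, SOBEL_KX, mode="mirror")
    gy = ndimage.correlate(src, SOBEL_KY, mode="mirror")
    return gx, gy


def blend_gradients(
    gx: np.ndarray, gy: np.ndarray, params: FilterParams | None = None
) -> np.ndarray:
    """Rectify both gradients to 8-bit magnitude and blend into one edge image.

    Each gradient is mapped by absolute value, clipped to [0, 255]
    ("converted back to uint8"), then combined as
    ``round(wx*|gx| + wy*|gy|)`` and clipped again.
    """
    params = params or FilterParams()
    params.validate()
    gx = np.asarray(gx)
    gy = np.asarray(gy)
    if gx.shape != gy.shape:
        raise DimensionError(f"gradient shapes differ: {gx.shape} vs {gy.shape}")
    ax = np.clip(np.abs(gx.astype(np.float64)), 0, 255)
    ay = np.clip(np.abs(gy.astype(np.float64)), 0, 255)
    return _as_uint8(params.blend_wx * ax + params.blend_wy * ay)


def preprocess_chain(img: np.ndarray, params: FilterParams | None = None) -> np.ndarray:
    """Full chain: median -> bilateral -> Sobel -> rectified blend."""
    params = params or FilterParams()
    params.validate()
    img = _check_image(to_grayscale(img))
    smoothed = median_filter(img, params.median_kernel)
    smoothed = bilateral_filter(smoothed, params)
    gx, gy = sobel_gradients(smoothed)
    return blend_gradients(gx, gy, params)
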