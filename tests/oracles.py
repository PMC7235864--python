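"""Brute-force reference implementations used only as test oracles.

Every function here evaluates the operator's definition directly
(double loops, exhaustive scans), independent of the vectorised
implementations under test.
"""

from __future__ import annotations

import numpy as np


def reflect101_pad(img: np.ndarray, r: int) -> np.ndarray:
    """Reflect-101 padding (edge pixel not duplicated), built by explicit
    index mirroring."""
    h, w = img.shape
    idx_r = np.abs(np.arange(-r, h + r))
    idx_r = np.where(idx_r >= h, 2 * (h - 1) - idx_r, idx_r)
    idx_c = np.abs(np.arange(-r, w + r))
    idx_c = np.where(idx_c >= w, 2 * (w - 1) - idx_c, idx_c)
    return img[np.ix_(idx_r, idx_c)]


def median_oracle(img: np.ndarray, kernel: int) -> np.ndarray:
    r = kernel // 2
    padded = reflect101_pad(img, r)
    out = np.empty_like(img)
    h, w = img.shape
    for i in range(h):
        for j in range(w):
            window = padded[i : i + kernel, j : j + kernel].ravel()
            out[i, j] = np.sort(window)[window.size // 2]
    return out


def sobel_oracle(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.int64)
    ky = kx.T
    padded = reflect101_pad(img.astype(np.int64), 1)
    h, w = img.shape
    gx = np.zeros((h, w), dtype=np.int64)
    gy = np.zeros((h, w), dtype=np.int64)
    for i in range(h):
        for j in range(w):
            window = padded[i : i + 3, j : j + 3]
            gx[i, j] = int((window * kx).sum())
            gy[i, j] = int((window * ky).sum())
    return gx, gy


def bilateral_oracle(
    img: np.ndarray, diameter: int, sigma_color: float, sigma_space: float
) -> np.ndarray:
    r = diameter // 2
    padded = reflect101_pad(img.astype(np.float64), r)
    h, w = img.shape
    out = np.empty((h, w), dtype=np.uint8)
    for i in range(h):
        for j in range(w):
            center = padded[i + r, j + r]
            num = den = 0.0
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    val = padded[i + r + di, j + r + dj]
                    ws = np.exp(-(di * di + dj * dj) / (2 * sigma_space**2))
                    wc = np.exp(-((val - center) ** 2) / (2 * sigma_color**2))
                    num += val * ws * wc
                    den += ws * wc
            out[i, j] = min(255, max(0, int(np.floor(num / den + 0.5))))
    return out


def nearest_center_oracle(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Exhaustive all-pairs nearest-center assignment, ties to lowest index."""
    labels = np.empty(X.shape[0], dtype=np.int64)
    for i, x in enumerate(X):
        best, best_d = 0, np.inf
        for j, c in enumerate(centers):
            d = float(np.sum((x - c) ** 2))
            if d < best_d:
                best, best_d = j, d
        labels[i] = best
    return labels
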