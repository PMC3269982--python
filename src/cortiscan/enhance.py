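"""Radiograph ROI enhancement: equalization, thresholding, high-pass, binarization.

The stage chain turns a raw 8-bit ROI crop into a clean binary image of the
cortical object: histogram equalization -> between-class-variance threshold
(object mask) -> mask multiply (background removal) -> averaging low-pass
subtraction (high-pass) -> mean-threshold binarization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from cortiscan.errors import (
    DegenerateHistogramError,
    ParameterError,
    RoiBoundsError,
    ShapeMismatchError,
)


@dataclass(frozen=True)
class RoiBox:
    """Rectangular region of interest, 0-based, top-left origin, extent-based.

    ``side`` tags which cortex the box covers ("right" or "left"); the
    canonical crop is 300x300 px over the inferior cortex below the mental
    foramen.
    """

    top_row: int
    left_col: int
    height: int = 300
    width: int = 300
    side: str = "right"

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0:
            raise ParameterError("RoiBox height and width must be positive")
        if self.side not in ("right", "left"):
            raise ParameterError(f"RoiBox side must be 'right' or 'left', got {self.side!r}")


def _as_gray(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ParameterError(f"expected a 2-D grayscale image, got ndim={arr.ndim}")
    if arr.size == 0:
        raise ParameterError("empty image")
    return arr


def crop_roi(image, box: RoiBox) -> np.ndarray:
    """Copy the pixels of ``box`` out of ``image``.

    Raises :class:`RoiBoundsError` naming the offending edge if the box does
    not lie entirely inside the image.
    """
    arr = _as_gray(image)
    n_rows, n_cols = arr.shape
    if box.top_row < 0:
        raise RoiBoundsError("ROI box crosses the top edge (top_row < 0)")
    if box.left_col < 0:
        raise RoiBoundsError("ROI box crosses the left edge (left_col < 0)")
    if box.top_row + box.height > n_rows:
        raise RoiBoundsError(
            f"ROI box crosses the bottom edge ({box.top_row + box.height} > {n_rows} rows)"
        )
    if box.left_col + box.width > n_cols:
        raise RoiBoundsError(
            f"ROI box crosses the right edge ({box.left_col + box.width} > {n_cols} cols)"
        )
    return arr[box.top_row:box.top_row + box.height,
               box.left_col:box.left_col + box.width].copy()


def equalize_histogram(image) -> np.ndarray:
    """Standard cumulative-histogram equalization onto [0, 255].

    Each intensity v maps to round(255 * CDF(v)); the map is monotone
    non-decreasing, so intensity rank order is preserved.
    """
    arr = _as_gray(image)
    flat = np.clip(arr, 0, 255).astype(np.int64)
    counts = np.bincount(flat.ravel(), minlength=256)
    cdf = np.cumsum(counts) / flat.size
    lut = np.rint(cdf * 255.0).astype(np.uint8)
    return lut[flat]


def variance_threshold(image) -> tuple[int, np.ndarray]:
    """Threshold by exhaustive sweep of between-class variance (Otsu's rule).

    All 256 integer levels are candidates; the returned threshold t maximizes
    the between-class variance of the split {v <= t} vs {v > t} (ties go to
    the smallest t). The mask is 1 where intensity > t.
    """
    arr = _as_gray(image)
    flat = np.clip(arr, 0, 255).astype(np.int64)
    counts = np.bincount(flat.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError(
            "cannot threshold a constant image: no separable classes")
    total = flat.size
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(counts)                    # pixels with v <= t
    mu0_sum = np.cumsum(counts * levels)      # intensity mass with v <= t
    w1 = total - w0
    mu_total = mu0_sum[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu0_sum / w0
        mu1 = (mu_total - mu0_sum) / w1
        between = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
    between[(w0 == 0) | (w1 == 0)] = -np.inf
    t = int(np.argmax(between))
    mask = (flat > t).astype(np.uint8)
    return t, mask


def mask_multiply(image, mask) -> np.ndarray:
    """Keep image pixels where mask == 1, zero elsewhere (background removal)."""
    arr = _as_gray(image)
    m = np.asarray(mask)
    if m.shape != arr.shape:
        raise ShapeMismatchError(
            f"image shape {arr.shape} != mask shape {m.shape}")
    return np.where(m != 0, arr, 0)


def highpass(image, kernel_size: int = 75) -> np.ndarray:
    """Subtract a kernel_size x kernel_size moving average from the image.

    The averaging filter acts as a background (low-frequency) estimator;
    borders are handled by edge replication. The output is a signed float
    grid and is deliberately not clipped. ``kernel_size`` must be odd, >= 3,
    and no larger than either image dimension; it should comfortably exceed
    the cortical band's vertical extent so the band interior stays positive
    after subtraction.
    """
    arr = _as_gray(image).astype(np.float64)
    k = int(kernel_size)
    if k % 2 == 0 or k < 3:
        raise ParameterError(f"kernel_size must be odd and >= 3, got {kernel_size}")
    if k > min(arr.shape):
        raise ParameterError(
            f"kernel_size {k} exceeds the smallest image dimension {min(arr.shape)}")
    low = ndimage.uniform_filter(arr, size=k, mode="nearest")
    return arr - low


def binarize_mean(hp) -> np.ndarray:
    """Binarize a signed grid at its global mean: 1 where value > mean.

    Strict comparison, so a constant grid yields an all-zero mask.
    """
    arr = np.asarray(hp, dtype=np.float64)
    if arr.size == 0:
        raise ParameterError("empty grid")
    return (arr > arr.mean()).astype(np.uint8)
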