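"""Shared low-level image helpers (foreground extraction, centroids)."""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = ["foreground_mask", "weighted_centroid", "background_estimate"]


def foreground_mask(
    pixels: np.ndarray,
    *,
    median_size: int = 3,
    min_object_px: int = 50,
    min_dynamic_range: float = 0.1,
) -> np.ndarray:
    """Binary foreground (sample-holder silhouette) of a frame.

    Median-filters, thresholds with Otsu, then drops small speckle objects so
    shot/read noise does not survive into the mask. Frames whose
    median-filtered dynamic range is below ``min_dynamic_range`` (blank or
    noise-only mounts) give an all-False mask.
    """
    px = np.asarray(pixels, dtype=float)
    if float(np.ptp(px)) < 1e-9:
        return np.zeros(px.shape, dtype=bool)
    med = ndimage.median_filter(px, size=median_size)
    if float(np.ptp(med)) < min_dynamic_range:
        return np.zeros(px.shape, dtype=bool)
    thr = threshold_otsu(med)
    mask = med > thr
    if min_object_px > 1 and mask.any():
        lab, n = ndimage.label(mask)
        counts = np.bincount(lab.ravel())
        keep = counts >= min_object_px
        keep[0] = False
        mask = keep[lab]
    return mask


def weighted_centroid(
    pixels: np.ndarray, mask: np.ndarray, *, background: float = 0.0
) -> tuple[float, float]:
    """Intensity-weighted (row, col) centroid of the masked pixels.

    Weights are background-subtracted intensities clipped at zero; if they sum
    to zero the unweighted mask centroid is returned. Invariant under global
    intensity scaling when background=0.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask has no centroid")
    w = np.clip(np.asarray(pixels, float)[rows, cols] - background, 0.0, None)
    total = w.sum()
    if total <= 0:
        return float(rows.mean()), float(cols.mean())
    return float((rows * w).sum() / total), float((cols * w).sum() / total)


def background_estimate(pixels: np.ndarray) -> tuple[float, float]:
    """Global background level and robust noise sigma.

    Background = median of the pixels below the Otsu threshold (the dark,
    lights-off background); sigma = 1.4826 x their MAD. Falls back to the
    global median for (near-)constant frames.
    """
    px = np.asarray(pixels, dtype=float)
    if float(np.ptp(px)) < 1e-9:
        return float(np.median(px)), 0.0
    thr = threshold_otsu(px)
    low = px[px < thr]
    if low.size == 0:
        low = px.ravel()
    med = float(np.median(low))
    sigma = 1.4826 * float(np.median(np.abs(low - med)))
    return med, sigma
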