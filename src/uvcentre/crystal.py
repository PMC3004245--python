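"""Stage-2 centring: segment the fluorescing crystal in UV frames.

Under ~265-285 nm illumination with the hutch lights off, the protein crystal
fluoresces brightly against a dark background while the sample holder is only
weakly visible. Segmentation proceeds by (i) removing the known holder
silhouette from the UV frame (a geometric re-use of the stage-1 loop model:
the measured silhouette, dilated into a boundary band, is replaced by the
background estimate), (ii) Laplacian-of-Gaussian (LoG) zero-crossing edge
detection, and (iii) selecting the largest closed contour whose interior is
brighter than the background — its external edges give the crystal size and
its intensity centre of mass the centring target.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import find_contours, label, regionprops

from ._image import background_estimate, foreground_mask, weighted_centroid
from .errors import NoCrystalError
from .loop import LoopBox
from .scene import Frame

__all__ = [
    "EdgeParams",
    "EdgeMap",
    "CrystalMeasure",
    "LineScanProfile",
    "log_kernel",
    "log_edge_map",
    "holder_mask_from_visible",
    "loop_band",
    "remove_loop_model",
    "segment_crystal",
    "line_scans",
    "contrast_score",
]


# -----------------------------------------------------------------------------
# Laplacian-of-Gaussian edges


@dataclass(frozen=True)
class EdgeParams:
    """LoG scale and zero-crossing gate.

    ``zero_crossing_threshold`` is the minimum absolute LoG response on *both*
    sides of a sign change for it to count as an edge; ``None`` means 1% of
    the frame's dynamic range, evaluated per frame.
    """

    sigma_px: float = 2.0
    zero_crossing_threshold: float | None = None
    truncate: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma_px < 0.5:
            raise ValueError("sigma_px must be >= 0.5")
        if self.zero_crossing_threshold is not None and self.zero_crossing_threshold < 0:
            raise ValueError("zero_crossing_threshold must be >= 0")


def log_kernel(sigma_px: float, truncate: float = 4.0) -> np.ndarray:
    """Discretized zero-mean Laplacian-of-Gaussian kernel.

    Sampled from the analytic LoG, then DC-corrected so the entries sum to
    (numerically) zero: the response to a constant frame is identically zero.
    """
    if sigma_px <= 0:
        raise ValueError("sigma must be positive")
    radius = int(math.ceil(truncate * sigma_px))
    ax = np.arange(-radius, radius + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    r2 = xx**2 + yy**2
    g = np.exp(-r2 / (2.0 * sigma_px**2))
    k = (r2 - 2.0 * sigma_px**2) / sigma_px**4 * g
    k /= g.sum()
    return k - k.mean()


@dataclass(frozen=True)
class EdgeMap:
    response: np.ndarray  # LoG response, congruent with the source frame
    edges: np.ndarray  # bool zero-crossing pixels
    threshold: float
    params: EdgeParams

    def __post_init__(self) -> None:
        if self.response.shape != self.edges.shape:
            raise ValueError("response and edge grids must be congruent")


def log_edge_map(frame: Frame, params: EdgeParams | None = None) -> EdgeMap:
    """LoG response and zero-crossing edge map of a frame.

    The response is the frame convolved with the discretized LoG kernel
    (symmetric/mirror boundary handling). A pixel is an edge pixel when it and
    a 4-neighbour have opposite response signs and both magnitudes reach the
    threshold.
    """
    params = params or EdgeParams()
    k = log_kernel(params.sigma_px, params.truncate)
    if k.shape[0] > frame.shape[0] or k.shape[1] > frame.shape[1]:
        raise ValueError(
            f"LoG kernel {k.shape} larger than frame {frame.shape}; reduce sigma"
        )
    resp = ndimage.convolve(frame.pixels, k, mode="mirror")
    thr = params.zero_crossing_threshold
    if thr is None:
        thr = 0.01 * float(np.ptp(frame.pixels))
    thr = max(thr, 1e-12)

    edges = np.zeros(resp.shape, dtype=bool)
    for axis in (0, 1):
        n = resp.shape[axis]
        a = resp.take(range(n - 1), axis=axis)
        b = resp.take(range(1, n), axis=axis)
        crossing = (a * b < 0) & (np.minimum(np.abs(a), np.abs(b)) >= thr)
        # a response sampled exactly (to within thr) at zero on the crossing
        # line: compare the flanking samples across the zero pixel instead
        lo = resp.take(range(n - 2), axis=axis)
        mid = resp.take(range(1, n - 1), axis=axis)
        hi = resp.take(range(2, n), axis=axis)
        on_zero = (
            (lo * hi < 0)
            & (np.abs(mid) < thr)
            & (np.minimum(np.abs(lo), np.abs(hi)) >= thr)
        )
        if axis == 0:
            edges[:-1, :] |= crossing
            edges[1:, :] |= crossing
            edges[1:-1, :] |= on_zero
        else:
            edges[:, :-1] |= crossing
            edges[:, 1:] |= crossing
            edges[:, 1:-1] |= on_zero
    return EdgeMap(response=resp, edges=edges, threshold=float(thr), params=params)


# -----------------------------------------------------------------------------
# loop removal


def holder_mask_from_visible(visible_frame: Frame) -> np.ndarray:
    """Holder silhouette measured on the paired visible-light frame (the
    stage-1 loop model registered to the same rotation angle)."""
    return foreground_mask(visible_frame.pixels)


def loop_band(mask: np.ndarray, band_width_px: int = 3) -> np.ndarray:
    """The loop-boundary band: the measured silhouette dilated by
    ``band_width_px``. The wire *is* the loop boundary, so the whole silhouette
    plus a safety margin is removed."""
    if band_width_px < 0:
        raise ValueError("band width must be >= 0")
    band = np.asarray(mask, dtype=bool)
    if band_width_px > 0 and band.any():
        band = ndimage.binary_dilation(band, iterations=band_width_px)
    return band


def remove_loop_model(
    uv_frame: Frame,
    loop: np.ndarray | LoopBox | None,
    *,
    band_width_px: int = 3,
    background: float | None = None,
) -> Frame:
    """Replace the holder-boundary band of a UV frame by the background level.

    ``loop`` may be a boolean silhouette mask (preferred; see
    :func:`holder_mask_from_visible`), a stage-1 :class:`LoopBox` (only the box
    perimeter is removed — degraded), or ``None`` (warn and return the frame
    unchanged). Pixels outside the band are passed through bit-exactly.
    """
    if loop is None:
        warnings.warn(
            "no loop geometry supplied; UV frame returned unchanged", stacklevel=2
        )
        return uv_frame
    if isinstance(loop, LoopBox):
        band = np.zeros(uv_frame.shape, dtype=bool)
        band[loop.row_min : loop.row_max + 1, [loop.col_min, loop.col_max]] = True
        band[[loop.row_min, loop.row_max], loop.col_min : loop.col_max + 1] = True
        band = loop_band(band, band_width_px)
    else:
        mask = np.asarray(loop, dtype=bool)
        if mask.shape != uv_frame.shape:
            raise ValueError("loop mask shape does not match the UV frame")
        band = loop_band(mask, band_width_px)
    if background is None:
        background, _ = background_estimate(uv_frame.pixels)
    out = uv_frame.pixels.copy()
    out[band] = max(background, 0.0)
    return Frame(
        pixels=out,
        pixel_size_um=uv_frame.pixel_size_um,
        illumination=uv_frame.illumination,
        omega_deg=uv_frame.omega_deg,
        exposure_ms=uv_frame.exposure_ms,
    )


# -----------------------------------------------------------------------------
# segmentation


@dataclass(frozen=True)
class CrystalMeasure:
    """Segmented crystal: closed contour, external-edge extents, intensity
    centre of mass and interior statistics."""

    contour: np.ndarray  # (N, 2) closed polygon in (row, col)
    centroid_px: tuple[float, float]
    extent_px: tuple[float, float]  # (width_cols, height_rows)
    extent_um: tuple[float, float]
    mean_interior_intensity: float
    region_mask: np.ndarray  # bool, the filled crystal region
    background: float

    def __post_init__(self) -> None:
        w, h = self.extent_px
        if w <= 0 or h <= 0:
            raise ValueError("crystal extents must be positive")
        rows, cols = np.nonzero(self.region_mask)
        r, c = self.centroid_px
        if not (rows.min() - 0.5 <= r <= rows.max() + 0.5
                and cols.min() - 0.5 <= c <= cols.max() + 0.5):
            raise ValueError("centroid outside the contour's bounding box")


def segment_crystal(
    frame: Frame,
    edges: EdgeMap,
    *,
    beam_centre_px: tuple[float, float] | None = None,
    min_area_px: int = 25,
    background: float | None = None,
    noise_sigma: float | None = None,
    close_gaps_px: int = 2,
) -> CrystalMeasure:
    """Delimit the crystal's external edges and compute its centre of mass.

    The zero-crossing rings are closed against small noise-induced gaps
    (dilate by ``close_gaps_px``, fill holes, erode back) and filled; among
    the filled regions at least ``min_area_px`` large whose mean interior
    intensity exceeds the background estimate (plus three noise sigma), the
    largest is the crystal — ties break toward the beam centre. Raises
    :class:`NoCrystalError` when nothing qualifies (distinct from an empty
    mount: the holder was present).
    """
    if background is None or noise_sigma is None:
        bg, sig = background_estimate(frame.pixels)
        background = bg if background is None else background
        noise_sigma = sig if noise_sigma is None else noise_sigma
    if close_gaps_px > 0:
        st = np.ones((3, 3), dtype=bool)
        grown = ndimage.binary_dilation(edges.edges, structure=st, iterations=close_gaps_px)
        filled = ndimage.binary_fill_holes(grown)
        filled = ndimage.binary_erosion(
            filled, structure=st, iterations=close_gaps_px, border_value=1
        )
        filled |= edges.edges
    else:
        filled = ndimage.binary_fill_holes(edges.edges)
    labels = label(filled, connectivity=2)
    if beam_centre_px is None:
        beam_centre_px = ((frame.shape[0] - 1) / 2.0, (frame.shape[1] - 1) / 2.0)

    candidates = []
    for prop in regionprops(labels):
        if prop.area < min_area_px:
            continue
        region = labels == prop.label
        interior = region & ~edges.edges
        sample = interior if interior.any() else region
        mean_int = float(frame.pixels[sample].mean())
        if mean_int <= background + 3.0 * noise_sigma:
            continue
        d_beam = math.hypot(
            prop.centroid[0] - beam_centre_px[0], prop.centroid[1] - beam_centre_px[1]
        )
        candidates.append((prop.area, -d_beam, prop.label, region, mean_int))
    if not candidates:
        raise NoCrystalError("no closed bright contour found in the UV frame")
    candidates.sort(key=lambda c: (c[0], c[1]), reverse=True)
    _, _, _, region, mean_int = candidates[0]

    contours = find_contours(region.astype(float), 0.5)
    contour = max(contours, key=len)
    # external edges: drop the outer (positive-response) half of the LoG ring,
    # whose zero crossing sits on the physical boundary
    tight = region & ~(edges.edges & (edges.response > 0))
    rows, cols = np.nonzero(tight if tight.any() else region)
    width = float(cols.max() - cols.min() + 1)
    height = float(rows.max() - rows.min() + 1)
    centroid = weighted_centroid(frame.pixels, region, background=background)
    return CrystalMeasure(
        contour=contour,
        centroid_px=centroid,
        extent_px=(width, height),
        extent_um=(width * frame.pixel_size_um, height * frame.pixel_size_um),
        mean_interior_intensity=mean_int,
        region_mask=region,
        background=float(background),
    )


# -----------------------------------------------------------------------------
# reporting helpers


@dataclass(frozen=True)
class LineScanProfile:
    """Raw intensity scans through a point, for reporting/plotting: the full
    row (horizontal) and column (vertical) of the frame."""

    point_px: tuple[int, int]
    horizontal: np.ndarray  # intensity vs col, length = n_cols
    vertical: np.ndarray  # intensity vs row, length = n_rows


def line_scans(frame: Frame, point_px: tuple[float, float]) -> LineScanProfile:
    r, c = int(round(point_px[0])), int(round(point_px[1]))
    if not (0 <= r < frame.shape[0] and 0 <= c < frame.shape[1]):
        raise ValueError(f"scan point {point_px} outside frame {frame.shape}")
    return LineScanProfile(
        point_px=(r, c),
        horizontal=frame.pixels[r, :].copy(),
        vertical=frame.pixels[:, c].copy(),
    )


def contrast_score(
    frame: Frame,
    measure: CrystalMeasure,
    *,
    exclude_mask: np.ndarray | None = None,
) -> float:
    """Crystal/background contrast: mean intensity inside the segmented
    contour divided by the mean outside it (and outside ``exclude_mask``,
    typically the loop band). Returns ``inf`` when the background mean is 0.
    """
    region = measure.region_mask
    if region.shape != frame.shape:
        raise ValueError("measure does not belong to a frame of this shape")
    bg_mask = ~region
    if exclude_mask is not None:
        bg_mask &= ~np.asarray(exclude_mask, dtype=bool)
    if not bg_mask.any():
        raise ValueError("no background pixels left to compare against")
    interior_mean = float(frame.pixels[region].mean())
    bg_mean = float(frame.pixels[bg_mask].mean())
    if bg_mean == 0.0:
        return math.inf
    return interior_mean / bg_mean
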