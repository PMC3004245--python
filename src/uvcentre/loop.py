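"""Stage-1 centring: sample-holder recognition on visible-light frames.

The holder is located in three steps — tip detection by gradient thresholding,
normalized cross-correlation (NCC) of a parametric "neck and shoulders"
template at the pin/loop junction, and an intensity centre-of-mass of the loop
silhouette inside the matched box. When the holder is non-standard or the
pattern match fails, the sample is modelled as a sphere with diameter 1.5x the
widest observed dimension and centred on the silhouette centroid instead.

Conventions: the pin enters from the image-left edge, so the holder tip is the
rightmost foreground edge pixel; all coordinates are 0-based (row, col).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from skimage.filters import sobel, threshold_otsu

from ._image import foreground_mask, weighted_centroid
from .errors import InsufficientAnglesError, NoObjectError
from .geometry import CentreSolution, Move3D, OffsetObservation, solve_centre
from .scene import SUPERSAMPLE, Frame

__all__ = [
    "FALLBACK_DIAMETER_FACTOR",
    "TipDetection",
    "PatternMask",
    "MatchResult",
    "LoopBox",
    "FallbackResult",
    "LoopAlignment",
    "detect_tip",
    "make_pattern_mask",
    "match_pattern",
    "ncc_map",
    "loop_centre",
    "fallback_sphere",
    "align_loop",
]

#: Spherical fallback model: assumed diameter / widest observed dimension.
FALLBACK_DIAMETER_FACTOR = 1.5


# -----------------------------------------------------------------------------
# tip detection


@dataclass(frozen=True)
class TipDetection:
    tip_px: tuple[int, int]  # (row, col)
    axis_direction: tuple[float, float]  # unit (d_row, d_col) toward the tip
    edge_pixel_count: int


def detect_tip(frame: Frame) -> TipDetection:
    """Find the holder tip: the rightmost edge pixel of the silhouette.

    Edges are gradient-magnitude pixels above an Otsu-selected threshold,
    restricted to the neighbourhood of the cleaned foreground mask so camera
    noise cannot masquerade as the tip. The tip row is the mean edge row in
    the extremal column (the middle of a blunt tip). Raises
    :class:`NoObjectError` for an empty mount.
    """
    px = frame.pixels
    fg = foreground_mask(px)
    if not fg.any():
        raise NoObjectError("no foreground object detected (empty mount?)")
    grad = sobel(ndimage.median_filter(px, size=3))
    if float(np.ptp(grad)) < 1e-12:
        raise NoObjectError("no intensity edges detected")
    edges = grad > threshold_otsu(grad)
    edges &= ndimage.binary_dilation(fg, iterations=2)
    if not edges.any():
        raise NoObjectError("no foreground edges above threshold")
    rows, cols = np.nonzero(edges)
    cmax = int(cols.max())
    tip_row = int(round(float(rows[cols == cmax].mean())))
    return TipDetection(
        tip_px=(tip_row, cmax),
        axis_direction=(0.0, 1.0),
        edge_pixel_count=int(edges.sum()),
    )


# -----------------------------------------------------------------------------
# pattern mask + NCC matching


@dataclass(frozen=True)
class PatternMask:
    """Binary template of the holder's "neck and shoulders" silhouette: the
    thin pin (neck) widening into the left cap of the loop (shoulders).

    Generated parametrically; ``junction_col_px`` is the template column of the
    neck/shoulder transition, i.e. the loop's left edge when matched.
    """

    grid: np.ndarray  # bool 2D
    scale_um_per_px: float
    neck_width_um: float
    shoulder_width_um: float
    shoulder_drop_um: float
    neck_length_um: float
    loop_width_um: float
    holder_kind: str = "nylon_loop"

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=bool)
        if g.ndim != 2 or not g.any():
            raise ValueError("pattern mask must be 2D with non-empty foreground")
        if self.scale_um_per_px <= 0:
            raise ValueError("scale_um_per_px must be positive")
        object.__setattr__(self, "grid", g)

    @property
    def junction_col_px(self) -> float:
        return self.neck_length_um / self.scale_um_per_px


def make_pattern_mask(
    holder_kind: str = "nylon_loop",
    *,
    neck_width_um: float = 20.0,
    shoulder_width_um: float = 250.0,
    shoulder_drop_um: float = 40.0,
    neck_length_um: float = 60.0,
    loop_width_um: float = 300.0,
    scale_um_per_px: float = 2.0,
) -> PatternMask:
    """Render the neck-and-shoulders template for a holder family.

    The shoulders reproduce the left cap of the holder silhouette: an
    elliptical-annulus cap for nylon loops, a rectangular-frame cap for
    litholoops. ``shoulder_width_um`` is the full loop height,
    ``shoulder_drop_um`` how far into the loop the template extends.
    """
    s = scale_um_per_px
    ss = SUPERSAMPLE
    height_px = int(math.ceil(shoulder_width_um / s)) + 3
    width_px = int(math.ceil((neck_length_um + shoulder_drop_um) / s)) + 1
    rr = ((np.arange(height_px * ss) + 0.5) / ss - 0.5)[:, None]
    cc = ((np.arange(width_px * ss) + 0.5) / ss - 0.5)[None, :]
    v = (rr - (height_px - 1) / 2.0) * s  # um, 0 on the template mid-row
    u = cc * s - neck_length_um  # um, 0 at the neck/shoulder junction
    t = neck_width_um
    a, b = loop_width_um / 2.0, shoulder_width_um / 2.0
    neck = (u < 0) & (np.abs(v) <= t / 2)
    if holder_kind == "litholoop":
        outer = (np.abs(v) <= b) & (u >= 0)
        inner = (np.abs(v) <= b - t) & (u >= t)
        shoulders = outer & ~inner
    else:
        du = u - a  # ellipse centred one half-width right of the junction
        outer = (du / a) ** 2 + (v / b) ** 2 <= 1.0
        inner = (du / (a - t)) ** 2 + (v / (b - t)) ** 2 <= 1.0
        shoulders = (u >= 0) & outer & ~inner
    fine = (neck | shoulders).astype(float)
    coarse = fine.reshape(height_px, ss, width_px, ss).mean(axis=(1, 3))
    return PatternMask(
        grid=coarse > 0.5,
        scale_um_per_px=s,
        neck_width_um=neck_width_um,
        shoulder_width_um=shoulder_width_um,
        shoulder_drop_um=shoulder_drop_um,
        neck_length_um=neck_length_um,
        loop_width_um=loop_width_um,
        holder_kind=holder_kind,
    )


def ncc_map(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Normalized cross-correlation of ``template`` over every full placement.

    Direct (non-FFT) evaluation: exact to floating point, scores in [-1, 1].
    Placements where the window has (near-)zero variance score 0. Output shape
    is ``(R - r + 1, C - c + 1)``.
    """
    img = np.asarray(image, dtype=float)
    t = np.asarray(template, dtype=float)
    if t.shape[0] > img.shape[0] or t.shape[1] > img.shape[1]:
        raise ValueError("template larger than image")
    t0 = t - t.mean()
    tnorm = math.sqrt(float((t0 * t0).sum()))
    h, w = t.shape
    n = t.size
    out_shape = (img.shape[0] - h + 1, img.shape[1] - w + 1)
    if tnorm < 1e-12:
        return np.zeros(out_shape, dtype=float)

    # window sums via integral images (O(1) per placement)
    s1 = np.zeros((img.shape[0] + 1, img.shape[1] + 1))
    s2 = np.zeros_like(s1)
    s1[1:, 1:] = img.cumsum(axis=0).cumsum(axis=1)
    s2[1:, 1:] = (img * img).cumsum(axis=0).cumsum(axis=1)

    def box(s: np.ndarray) -> np.ndarray:
        return s[h:, w:] - s[:-h, w:] - s[h:, :-w] + s[:-h, :-w]

    wsum = box(s1)
    var = np.clip(box(s2) - wsum * wsum / n, 0.0, None)
    den = tnorm * np.sqrt(var)

    num = np.empty(out_shape, dtype=float)
    windows = sliding_window_view(img, t.shape)
    for i in range(out_shape[0]):  # row-chunked to bound memory
        num[i] = np.tensordot(windows[i], t0, axes=([-2, -1], [0, 1]))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 1e-12, num / np.where(den > 0, den, 1.0), 0.0)
    return np.clip(np.nan_to_num(out, nan=0.0), -1.0, 1.0)


@dataclass(frozen=True)
class MatchResult:
    """Best NCC placement of a pattern mask. ``location_px`` is the (row, col)
    of the template's top-left corner; ``junction_dcol`` the column offset from
    there to the pin/loop junction."""

    location_px: tuple[int, int]
    score: float
    accepted: bool
    template_shape: tuple[int, int]
    junction_dcol: float
    neck_width_px: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.score <= 1.0:
            raise ValueError("NCC score must lie in [-1, 1]")


def match_pattern(
    frame: Frame, mask: PatternMask, *, threshold: float = 0.6
) -> MatchResult:
    """NCC template match of the holder mask against a visible frame.

    The mask is resampled if its micrometre scale differs from the frame's.
    ``accepted`` is True iff the best score reaches ``threshold``.
    """
    template = mask.grid.astype(float)
    scale = mask.scale_um_per_px / frame.pixel_size_um
    if abs(scale - 1.0) > 1e-6:
        template = ndimage.zoom(template, scale, order=1)
        template = (template > 0.5).astype(float)
    if template.shape[0] > frame.shape[0] or template.shape[1] > frame.shape[1]:
        raise ValueError("pattern mask larger than the frame")
    scores = ncc_map(frame.pixels, template)
    loc = np.unravel_index(int(np.argmax(scores)), scores.shape)
    best = float(scores[loc])
    return MatchResult(
        location_px=(int(loc[0]), int(loc[1])),
        score=best,
        accepted=best >= threshold,
        template_shape=template.shape,
        junction_dcol=mask.neck_length_um / frame.pixel_size_um,
        neck_width_px=mask.neck_width_um / frame.pixel_size_um,
    )


# -----------------------------------------------------------------------------
# loop box + centre of mass


@dataclass(frozen=True)
class LoopBox:
    """Bounding box of the loop silhouette (pin excluded) and its
    intensity-weighted centre of mass."""

    row_min: int
    col_min: int
    row_max: int
    col_max: int
    centre_of_mass_px: tuple[float, float]

    def __post_init__(self) -> None:
        if self.row_min > self.row_max or self.col_min > self.col_max:
            raise ValueError("inverted bounding box")
        r, c = self.centre_of_mass_px
        if not (self.row_min - 0.5 <= r <= self.row_max + 0.5
                and self.col_min - 0.5 <= c <= self.col_max + 0.5):
            raise ValueError("centre of mass outside the box")


def loop_centre(frame: Frame, match: MatchResult) -> LoopBox:
    """Loop bounding box and centre of mass from an accepted pattern match.

    The box spans from the matched pin/loop junction to the rightmost
    foreground column; the centre of mass is the intensity-weighted centroid
    of foreground pixels inside the box (invariant under global intensity
    scaling, equivariant under translation).
    """
    if not match.accepted:
        raise ValueError("loop_centre requires an accepted pattern match")
    fg = foreground_mask(frame.pixels)
    if not fg.any():
        raise NoObjectError("no foreground inside the frame")
    junction = max(0, int(round(match.location_px[1] + match.junction_dcol)))
    cols_any = np.nonzero(fg.any(axis=0))[0]
    col_max = int(cols_any.max())
    if junction > col_max:
        junction = int(cols_any.min())
    box_mask = np.zeros_like(fg)
    box_mask[:, junction : col_max + 1] = True
    region = fg & box_mask
    if not region.any():
        raise NoObjectError("empty foreground inside the matched box")
    rows_any = np.nonzero(region.any(axis=1))[0]
    com = weighted_centroid(frame.pixels, region)
    return LoopBox(
        row_min=int(rows_any.min()),
        col_min=junction,
        row_max=int(rows_any.max()),
        col_max=col_max,
        centre_of_mass_px=com,
    )


# -----------------------------------------------------------------------------
# spherical fallback


@dataclass(frozen=True)
class FallbackResult:
    diameter_um: float
    widest_dimension_um: float
    centres_px: tuple[tuple[float, float], ...]  # one (row, col) per frame


def _trim_pin(fg: np.ndarray, pin_extent_px: float) -> np.ndarray:
    """Drop the leading (left) columns whose vertical foreground extent looks
    like the mounting pin, so the pin does not count as sample width. Only
    applies when the foreground touches the image-left edge (where the pin
    enters); free-standing objects are left untouched."""
    if not fg[:, 0].any():
        return fg
    out = fg.copy()
    cols = np.nonzero(fg.any(axis=0))[0]
    thresh = max(pin_extent_px, 2.0)
    for c in cols:
        rows = np.nonzero(fg[:, c])[0]
        extent = rows.max() - rows.min() + 1
        if extent > thresh:
            out[:, : c] = False
            return out
    return out  # nothing wider than a pin: keep everything


def fallback_sphere(
    frames: Sequence[Frame],
    *,
    pin_width_um: float = 30.0,
) -> FallbackResult:
    """Spherical sample model for non-standard holders or failed matches.

    The widest dimension is the maximum foreground extent (height or width,
    pin trimmed) over all frames; the assumed sphere diameter is exactly
    ``FALLBACK_DIAMETER_FACTOR`` (1.5) times that. Per-frame centres are the
    intensity-weighted centroids of the trimmed silhouettes.
    """
    if not frames:
        raise ValueError("need at least one frame")
    widest_px_um = 0.0
    centres: list[tuple[float, float]] = []
    any_fg = False
    for frame in frames:
        fg = foreground_mask(frame.pixels)
        if not fg.any():
            centres.append((math.nan, math.nan))
            continue
        any_fg = True
        fg = _trim_pin(fg, 1.5 * pin_width_um / frame.pixel_size_um)
        rows = np.nonzero(fg.any(axis=1))[0]
        cols = np.nonzero(fg.any(axis=0))[0]
        extent_px = max(rows.max() - rows.min() + 1, cols.max() - cols.min() + 1)
        widest_px_um = max(widest_px_um, float(extent_px) * frame.pixel_size_um)
        centres.append(weighted_centroid(frame.pixels, fg))
    if not any_fg:
        raise NoObjectError("no foreground in any frame")
    return FallbackResult(
        diameter_um=FALLBACK_DIAMETER_FACTOR * widest_px_um,
        widest_dimension_um=widest_px_um,
        centres_px=tuple(centres),
    )


# -----------------------------------------------------------------------------
# multi-angle alignment


@dataclass(frozen=True)
class LoopAlignment:
    move: Move3D
    solution: CentreSolution
    per_angle: tuple[dict, ...]
    used_fallback: bool


def align_loop(
    frames: Sequence[Frame],
    *,
    mask: PatternMask | None = None,
    beam_centre_px: tuple[float, float] | None = None,
    ncc_threshold: float = 0.6,
) -> LoopAlignment:
    """Stage-1 alignment: locate the loop in each visible frame and solve the
    3D stage move that brings its centre of mass to the beam position.

    Pattern matching is attempted per frame; if it fails on every frame (or
    leaves fewer than two usable angles) the spherical fallback centres are
    used for all frames instead.
    """
    visible = [f for f in frames if f.illumination == "visible"]
    if not visible:
        raise ValueError("no visible-mode frames supplied")
    omegas = [f.omega_deg for f in visible]
    uniq = {round(w % 180.0, 6) for w in omegas}
    if len(uniq) < 2:
        raise InsufficientAnglesError(
            "stage-1 alignment needs visible frames at >=2 angles distinct mod 180 deg"
        )
    if mask is None:
        mask = make_pattern_mask(scale_um_per_px=visible[0].pixel_size_um)

    per_angle: list[dict] = []
    centres: list[tuple[float, float] | None] = []
    for f in visible:
        entry: dict = {"omega_deg": f.omega_deg}
        try:
            entry["tip"] = detect_tip(f)
        except NoObjectError:
            entry["tip"] = None
        m = match_pattern(f, mask, threshold=ncc_threshold)
        entry["match"] = m
        if m.accepted:
            try:
                box = loop_centre(f, m)
                entry["box"] = box
                centres.append(box.centre_of_mass_px)
            except NoObjectError:
                entry["box"] = None
                centres.append(None)
        else:
            entry["box"] = None
            centres.append(None)
        per_angle.append(entry)

    good = [i for i, c in enumerate(centres) if c is not None]
    good_angles = {round(visible[i].omega_deg % 180.0, 6) for i in good}
    used_fallback = False
    if len(good_angles) < 2:
        fb = fallback_sphere(visible)
        used_fallback = True
        centres = [c if not math.isnan(c[0]) else None for c in fb.centres_px]
        for entry, c in zip(per_angle, centres):
            entry["fallback_centre"] = c
        good = [i for i, c in enumerate(centres) if c is not None]
        good_angles = {round(visible[i].omega_deg % 180.0, 6) for i in good}
        if len(good_angles) < 2:
            raise NoObjectError("holder not found at enough angles, even by fallback")

    observations = []
    for i in good:
        f = visible[i]
        br, bc = beam_centre_px if beam_centre_px is not None else (
            (f.shape[0] - 1) / 2.0,
            (f.shape[1] - 1) / 2.0,
        )
        c = centres[i]
        observations.append(
            OffsetObservation(
                omega_deg=f.omega_deg,
                dx_px=c[1] - bc,
                dy_px=c[0] - br,
                pixel_size_um=f.pixel_size_um,
            )
        )
    solution = solve_centre(observations)
    return LoopAlignment(
        move=solution.move,
        solution=solution,
        per_angle=tuple(per_angle),
        used_fallback=used_fallback,
    )
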