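"""Synthetic microscope scenes of loop-mounted protein crystals.

Renders the two illumination regimes of an automated centring station:

* **visible** backlight — the sample holder (nylon cryoloop or litholoop) is a
  bright, high-contrast silhouette while the crystal is nearly invisible
  against the buffer (low crystal/background contrast);
* **uv** fluorescence — the hutch lights are off, the background is dark, the
  holder fluoresces weakly and the protein crystal (aromatic residues) is by
  far the brightest object.

Every rendered frame comes with exact ground truth (the analytic projection of
the crystal's 3D offset, the holder tip and bounding box), so each downstream
stage of the pipeline can be tested without hardware.

Geometry: the holder enters from the image-left edge on a pin; the omega
rotation axis is image-horizontal through the beam centre; projections follow
:func:`uvcentre.geometry.predict_offset`. Sub-pixel geometry is rendered by
4x supersampling followed by box downsampling. Noise is Poisson-like shot
noise (variance proportional to signal) plus additive Gaussian read noise.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import OutOfFrameError
from .geometry import predict_offset

__all__ = [
    "IntensityLevels",
    "NoiseModel",
    "SceneSpec",
    "Frame",
    "GroundTruthSlice",
    "GroundTruth",
    "render_scene",
    "generate_fixture_set",
    "VISIBLE_LEVELS",
    "UV_LEVELS",
]

SUPERSAMPLE = 4

HolderKind = Literal["nylon_loop", "litholoop", "nonstandard"]
CrystalShape = Literal["box", "hexagon", "ellipse"]
Illumination = Literal["visible", "uv"]


@dataclass(frozen=True)
class IntensityLevels:
    """Mean intensities (arbitrary units, 0-1) of the three scene regions."""

    background: float
    loop: float
    crystal: float

    def __post_init__(self) -> None:
        for name, v in dataclasses.asdict(self).items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"intensity level {name}={v} outside [0, 1]")


#: Visible backlight: bright holder, crystal nearly indistinguishable from buffer.
VISIBLE_LEVELS = IntensityLevels(background=0.15, loop=0.70, crystal=0.20)
#: UV fluorescence: dark hutch, weakly fluorescing holder, bright crystal.
UV_LEVELS = IntensityLevels(background=0.03, loop=0.15, crystal=0.80)


@dataclass(frozen=True)
class NoiseModel:
    """Shot + read noise. Shot variance = ``shot_scale * signal``; read noise
    is additive Gaussian with ``read_sigma``. Defaults give SNR ~ 10 at the
    default UV crystal level."""

    shot_scale: float = 0.008
    read_sigma: float = 0.01

    def __post_init__(self) -> None:
        if self.shot_scale < 0 or self.read_sigma < 0:
            raise ValueError("noise parameters must be non-negative")

    def sigma_at(self, level: float) -> float:
        return math.sqrt(self.shot_scale * level + self.read_sigma**2)

    def snr_at(self, level: float) -> float:
        s = self.sigma_at(level)
        return math.inf if s == 0 else level / s


@dataclass(frozen=True)
class SceneSpec:
    """Parametric description of one simulated sample.

    Lengths are micrometres. ``crystal_offset_um`` and ``loop_offset_um`` are
    (x, y, z) positions relative to the rotation-axis/beam intersection, in the
    stage frame of :mod:`uvcentre.geometry`. The holder silhouette is a
    projected elliptical annulus (nylon loop), a rounded-rectangle frame with
    an aperture (litholoop) or a filled ellipse blob (nonstandard), attached to
    a pin entering from the image-left edge.
    """

    holder_kind: HolderKind = "nylon_loop"
    loop_width_um: float = 300.0
    loop_height_um: float = 250.0
    wire_thickness_um: float = 20.0
    crystal_shape: CrystalShape = "box"
    crystal_dims_um: tuple[float, float] = (80.0, 60.0)
    crystal_offset_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    loop_offset_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    pixel_size_um: float = 2.0
    frame_shape_px: tuple[int, int] = (256, 256)
    beam_centre_px: tuple[float, float] | None = None
    illumination: Illumination = "visible"
    visible_levels: IntensityLevels = VISIBLE_LEVELS
    uv_levels: IntensityLevels = UV_LEVELS
    noise: NoiseModel = field(default_factory=NoiseModel)
    exposure_ms: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("loop_width_um", "loop_height_um", "wire_thickness_um",
                     "pixel_size_um", "exposure_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if any(d <= 0 for d in self.crystal_dims_um):
            raise ValueError("crystal dimensions must be strictly positive")
        if len(self.crystal_dims_um) != 2 or len(self.crystal_offset_um) != 3:
            raise ValueError("crystal_dims_um is (w, h); crystal_offset_um is (x, y, z)")
        r, c = self.frame_shape_px
        if r < 8 or c < 8:
            raise ValueError("frame must be at least 8x8 px")
        if self.wire_thickness_um * 2 >= min(self.loop_width_um, self.loop_height_um):
            raise ValueError("wire thicker than the loop silhouette")

    # -- derived conveniences -------------------------------------------------

    def beam_centre(self) -> tuple[float, float]:
        if self.beam_centre_px is not None:
            return tuple(map(float, self.beam_centre_px))
        r, c = self.frame_shape_px
        return ((r - 1) / 2.0, (c - 1) / 2.0)

    def levels(self, illumination: Illumination | None = None) -> IntensityLevels:
        mode = illumination or self.illumination
        return self.uv_levels if mode == "uv" else self.visible_levels

    def crystal_snr(self, illumination: Illumination | None = None) -> float:
        return self.noise.snr_at(self.levels(illumination).crystal)

    def widest_holder_dimension_um(self) -> float:
        """Widest dimension of the holder silhouette proper (pin excluded)."""
        return max(self.loop_width_um, self.loop_height_um)


@dataclass(frozen=True)
class Frame:
    """One 2D grayscale micrograph with calibration and acquisition tags."""

    pixels: np.ndarray
    pixel_size_um: float
    illumination: Illumination
    omega_deg: float
    exposure_ms: float = 300.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("frame pixels must be a 2D grid")
        if not np.all(np.isfinite(px)) or np.any(px < 0):
            raise ValueError("frame intensities must be finite and non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class GroundTruthSlice:
    """Exact per-angle answers for one rendered scene."""

    omega_deg: float
    crystal_centroid_px: tuple[float, float]  # (row, col)
    loop_centre_px: tuple[float, float]
    loop_tip_px: tuple[float, float]
    loop_box_px: tuple[float, float, float, float]  # row_min, col_min, row_max, col_max


@dataclass(frozen=True)
class GroundTruth:
    """Ground truth for a fixture set: the true 3D crystal position and the
    analytic per-angle projections it induces."""

    crystal_centre_3d_um: tuple[float, float, float]
    loop_offset_um: tuple[float, float, float]
    widest_dimension_um: float
    slices: tuple[GroundTruthSlice, ...]

    def slice_at(self, omega_deg: float) -> GroundTruthSlice:
        for s in self.slices:
            if abs(s.omega_deg - omega_deg) < 1e-9:
                return s
        raise KeyError(f"no ground truth at omega={omega_deg}")


# -----------------------------------------------------------------------------
# rendering


def _fine_coords_um(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Supersampled pixel-centre coordinates in micrometres relative to the
    beam centre: (v rows down, u cols right), each 2D."""
    rows, cols = spec.frame_shape_px
    br, bc = spec.beam_centre()
    s = SUPERSAMPLE
    rr = (np.arange(rows * s) + 0.5) / s - 0.5
    cc = (np.arange(cols * s) + 0.5) / s - 0.5
    v = (rr - br)[:, None] * spec.pixel_size_um
    u = (cc - bc)[None, :] * spec.pixel_size_um
    return np.broadcast_to(v, (rows * s, cols * s)), np.broadcast_to(u, (rows * s, cols * s))


def _project_um(offset_um: Sequence[float], omega_deg: float) -> tuple[float, float]:
    """(u, v) micrometre image position of a 3D stage offset at omega."""
    dx, dy = predict_offset(tuple(offset_um), omega_deg, 1.0)
    return dx, dy


def _crystal_mask(u: np.ndarray, v: np.ndarray, spec: SceneSpec, omega_deg: float) -> np.ndarray:
    cu, cv = _project_um(spec.crystal_offset_um, omega_deg)
    w, h = spec.crystal_dims_um
    du, dv = u - cu, v - cv
    if spec.crystal_shape == "box":
        return (np.abs(du) <= w / 2) & (np.abs(dv) <= h / 2)
    if spec.crystal_shape == "ellipse":
        return (du / (w / 2)) ** 2 + (dv / (h / 2)) ** 2 <= 1.0
    # flat-top hexagon with vertices (+-w/2, 0), (+-w/4, +-h/2)
    return (np.abs(dv) <= h / 2) & (np.abs(du) <= w / 2 - (w / 4) * (np.abs(dv) / (h / 2)))


def _holder_mask(u: np.ndarray, v: np.ndarray, spec: SceneSpec, omega_deg: float) -> np.ndarray:
    """Holder silhouette (loop + pin) at this angle, as a boolean fine grid.

    The loop plane is modelled as always facing the camera; rotation moves the
    loop centre per the forward model but does not foreshorten the silhouette.
    """
    lu, lv = _project_um(spec.loop_offset_um, omega_deg)
    a, b = spec.loop_width_um / 2, spec.loop_height_um / 2
    t = spec.wire_thickness_um
    du, dv = u - lu, v - lv
    if spec.holder_kind == "nylon_loop":
        outer = (du / a) ** 2 + (dv / b) ** 2 <= 1.0
        inner = (du / (a - t)) ** 2 + (dv / (b - t)) ** 2 <= 1.0
        loop = outer & ~inner
        left_edge = lu - a
    elif spec.holder_kind == "litholoop":
        outer = (np.abs(du) <= a) & (np.abs(dv) <= b)
        inner = (np.abs(du) <= a - t) & (np.abs(dv) <= b - t)
        loop = outer & ~inner
        left_edge = lu - a
    else:  # nonstandard: filled ellipse blob
        loop = (du / a) ** 2 + (dv / b) ** 2 <= 1.0
        left_edge = lu - a
    pin = (np.abs(dv) <= t / 2) & (u <= left_edge + t)
    return loop | pin


def _check_in_frame(spec: SceneSpec, omega_deg: float) -> None:
    cu, cv = _project_um(spec.crystal_offset_um, omega_deg)
    w, h = spec.crystal_dims_um
    rows, cols = spec.frame_shape_px
    br, bc = spec.beam_centre()
    s = spec.pixel_size_um
    col_lo, col_hi = bc + (cu - w / 2) / s, bc + (cu + w / 2) / s
    row_lo, row_hi = br + (cv - h / 2) / s, br + (cv + h / 2) / s
    if col_lo < 0 or row_lo < 0 or col_hi > cols - 1 or row_hi > rows - 1:
        raise OutOfFrameError(omega_deg)


def _downsample(fine: np.ndarray) -> np.ndarray:
    s = SUPERSAMPLE
    r, c = fine.shape[0] // s, fine.shape[1] // s
    return fine.reshape(r, s, c, s).mean(axis=(1, 3))


def _frame_rng(spec: SceneSpec, omega_deg: float, illumination: Illumination) -> np.random.Generator:
    mode_idx = 0 if illumination == "visible" else 1
    return np.random.default_rng(
        [int(spec.seed) % 2**31, mode_idx, int(round(omega_deg * 1000.0)) % 2**31]
    )


def _ground_truth_slice(spec: SceneSpec, omega_deg: float) -> GroundTruthSlice:
    br, bc = spec.beam_centre()
    s = spec.pixel_size_um
    cu, cv = _project_um(spec.crystal_offset_um, omega_deg)
    lu, lv = _project_um(spec.loop_offset_um, omega_deg)
    a, b = spec.loop_width_um / 2, spec.loop_height_um / 2
    return GroundTruthSlice(
        omega_deg=omega_deg,
        crystal_centroid_px=(br + cv / s, bc + cu / s),
        loop_centre_px=(br + lv / s, bc + lu / s),
        loop_tip_px=(br + lv / s, bc + (lu + a) / s),
        loop_box_px=(
            br + (lv - b) / s,
            bc + (lu - a) / s,
            br + (lv + b) / s,
            bc + (lu + a) / s,
        ),
    )


def render_scene(
    spec: SceneSpec,
    omega_deg: float,
    illumination: Illumination | None = None,
) -> tuple[Frame, GroundTruthSlice]:
    """Render one frame at rotation angle ``omega_deg``.

    Deterministic for fixed (spec, omega, illumination): the per-frame RNG is
    derived from ``spec.seed``, the illumination mode and the angle.
    """
    mode: Illumination = illumination or spec.illumination
    _check_in_frame(spec, omega_deg)
    levels = spec.levels(mode)
    v, u = _fine_coords_um(spec)
    holder = _holder_mask(u, v, spec, omega_deg)
    crystal = _crystal_mask(u, v, spec, omega_deg)
    fine = np.full(u.shape, levels.background, dtype=float)
    fine[holder] = levels.loop
    fine[crystal] = levels.crystal  # crystal occludes the wire where they overlap
    clean = _downsample(fine)

    noise = spec.noise
    if noise.shot_scale > 0 or noise.read_sigma > 0:
        rng = _frame_rng(spec, omega_deg, mode)
        shot = rng.standard_normal(clean.shape) * np.sqrt(noise.shot_scale * clean)
        read = rng.standard_normal(clean.shape) * noise.read_sigma
        clean = np.clip(clean + shot + read, 0.0, None)

    frame = Frame(
        pixels=clean,
        pixel_size_um=spec.pixel_size_um,
        illumination=mode,
        omega_deg=float(omega_deg),
        exposure_ms=spec.exposure_ms,
    )
    return frame, _ground_truth_slice(spec, omega_deg)


def generate_fixture_set(
    spec: SceneSpec,
    angles: Sequence[float],
    modes: Sequence[Illumination] = ("visible", "uv"),
) -> tuple[list[Frame], GroundTruth]:
    """Render one frame per angle per illumination mode, with ground truth.

    Identical (spec, angles, seed) give bit-identical frames.
    """
    angles = list(angles)
    if not angles:
        raise ValueError("need at least one rotation angle")
    for w in angles:
        if not (0.0 <= w < 360.0):
            raise ValueError(f"angles must lie in [0, 360): got {w}")
    frames: list[Frame] = []
    slices: list[GroundTruthSlice] = []
    for w in angles:
        gt_slice = None
        for mode in modes:
            frame, gt_slice = render_scene(spec, w, mode)
            frames.append(frame)
        assert gt_slice is not None
        slices.append(gt_slice)
    truth = GroundTruth(
        crystal_centre_3d_um=tuple(map(float, spec.crystal_offset_um)),
        loop_offset_um=tuple(map(float, spec.loop_offset_um)),
        widest_dimension_um=spec.widest_holder_dimension_um(),
        slices=tuple(slices),
    )
    return frames, truth
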