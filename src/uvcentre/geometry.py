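"""Goniometer geometry: mapping 3D stage positions to per-angle image offsets
and solving the inverse problem from multi-angle observations.

Conventions (fixed once, shared by the simulator and the solver):

* Image coordinates are 0-based ``(row, col)`` with the origin at the top-left
  pixel. ``dx`` is a column offset, ``dy`` a row offset; ``dy`` increases
  *downward*.
* The stage frame is ``(x, y, z)``: ``x`` along the omega rotation axis
  (image-horizontal), ``y`` the image-vertical direction at omega = 0, and
  ``z`` the viewing direction at omega = 0.
* A positive omega is a right-handed rotation about the +x axis, so a point at
  stage position ``(x, y, z)`` (micrometres, relative to the beam/rotation-axis
  intersection) appears in the camera at

      dx_px = x / pixel_size
      dy_px = (y * cos(omega) - z * sin(omega)) / pixel_size

The translation that centres an object observed at position ``p`` is ``-p``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InsufficientAnglesError

__all__ = [
    "Move3D",
    "OffsetObservation",
    "CentreSolution",
    "predict_offset",
    "solve_centre",
]


@dataclass(frozen=True)
class Move3D:
    """A 3D stage translation in micrometres.

    ``x_um`` is along the rotation axis; ``y_um``/``z_um`` are the
    perpendicular pair (``y`` = image-vertical at omega = 0, ``z`` = viewing
    direction at omega = 0).
    """

    x_um: float
    y_um: float
    z_um: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x_um, self.y_um, self.z_um)):
            raise ValueError("Move3D components must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x_um, self.y_um, self.z_um], dtype=float)

    def __neg__(self) -> "Move3D":
        return Move3D(-self.x_um, -self.y_um, -self.z_um)

    def __add__(self, other: "Move3D") -> "Move3D":
        return Move3D(
            self.x_um + other.x_um, self.y_um + other.y_um, self.z_um + other.z_um
        )

    def __sub__(self, other: "Move3D") -> "Move3D":
        return self + (-other)


@dataclass(frozen=True)
class OffsetObservation:
    """A 2D image offset of the target relative to the beam centre at one
    rotation angle. ``dx_px`` is columns (image-horizontal), ``dy_px`` rows
    (downward-positive)."""

    omega_deg: float
    dx_px: float
    dy_px: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        if not (
            math.isfinite(self.dx_px)
            and math.isfinite(self.dy_px)
            and math.isfinite(self.omega_deg)
        ):
            raise ValueError("offsets and angle must be finite")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


def predict_offset(
    move: Move3D | Sequence[float], omega_deg: float, pixel_size_um: float
) -> tuple[float, float]:
    """Forward model: image offset (dx_px, dy_px) of a point at stage position
    ``move`` (micrometres) when viewed at rotation angle ``omega_deg``."""
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    x, y, z = (move.as_array() if isinstance(move, Move3D) else np.asarray(move, float))
    w = math.radians(omega_deg)
    dx = x / pixel_size_um
    dy = (y * math.cos(w) - z * math.sin(w)) / pixel_size_um
    return dx, dy


def _angles_degenerate(omegas_deg: Sequence[float]) -> bool:
    """True if the angle set cannot separate y from z: all angles coincide
    modulo 180 degrees (to 1e-9 deg)."""
    mod = np.mod(np.asarray(omegas_deg, float), 180.0)
    if mod.size < 2:
        return True
    d = np.abs(mod[:, None] - mod[None, :])
    d = np.minimum(d, 180.0 - d)  # circular distance, period 180
    return float(d.max()) < 1e-9


@dataclass(frozen=True)
class CentreSolution:
    """Least-squares result of multi-angle centring.

    ``position_um`` is the solved 3D position of the target; ``move`` is the
    stage translation that brings it onto the beam (``-position``).
    ``residual_px`` is the RMS of the per-observation offset residuals;
    ``flagged`` marks wildly inconsistent observations (residual above the
    threshold) — the solution is still returned.
    """

    move: Move3D
    position_um: tuple[float, float, float]
    residual_px: float
    flagged: bool


def solve_centre(
    observations: Sequence[OffsetObservation],
    *,
    residual_threshold_px: float = 2.0,
) -> CentreSolution:
    """Solve the 3D position that explains per-angle 2D offsets, least squares.

    Requires at least two observations whose angles are distinct modulo 180
    degrees; otherwise the y/z pair is unidentifiable and
    :class:`InsufficientAnglesError` is raised. The x component reduces to the
    mean of the horizontal offsets (it is omega-independent in the model).
    """
    obs = list(observations)
    if len(obs) < 2:
        raise InsufficientAnglesError(
            f"need >=2 observations at angles distinct mod 180 deg, got {len(obs)}"
        )
    if _angles_degenerate([o.omega_deg for o in obs]):
        raise InsufficientAnglesError(
            "rotation angles coincide modulo 180 deg; y/z are unidentifiable"
        )

    rows = []
    rhs = []
    for o in obs:
        w = math.radians(o.omega_deg)
        s = o.pixel_size_um
        rows.append([1.0 / s, 0.0, 0.0])
        rhs.append(o.dx_px)
        rows.append([0.0, math.cos(w) / s, -math.sin(w) / s])
        rhs.append(o.dy_px)
    a = np.asarray(rows, float)
    b = np.asarray(rhs, float)
    pos, *_ = np.linalg.lstsq(a, b, rcond=None)
    resid = a @ pos - b
    rms = float(np.sqrt(np.mean(resid**2)))
    return CentreSolution(
        move=Move3D(-float(pos[0]), -float(pos[1]), -float(pos[2])),
        position_um=(float(pos[0]), float(pos[1]), float(pos[2])),
        residual_px=rms,
        flagged=rms > residual_threshold_px,
    )
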