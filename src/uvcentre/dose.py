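"""UV exposure and dose accounting for the centring protocol.

The centring protocol exposes the sample to short synchronized UV pulses: by
default a single 300 ms exposure at each of three rotation angles, with a
reference dose of 16 µW delivered into a 200 µm spot per 1 s exposure. The
primary accumulated-dose figure follows the instrument's own accounting — the
per-exposure power summed over exposures (3 x 16 = 48 µW, "about 50 µW") —
which adds powers without scaling by the exposure time. Because that mixes
power and dose units, an *alternative accounting* in µJ (power x exposure
time x number of exposures) is reported alongside. Safety compares per-area
power densities against the published damage threshold of 0.1 mW in a 150 µm
spot.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "BeamProfile",
    "ExposurePlan",
    "SafetyThreshold",
    "DoseReport",
    "aperture_dose",
    "accumulated_dose",
    "safety_check",
]


def _spot_area_um2(diameter_um: float) -> float:
    return math.pi * (diameter_um / 2.0) ** 2


@dataclass(frozen=True)
class BeamProfile:
    """A measured 2D beam-profile grid of power densities.

    ``density_uW_per_um2[i, j]`` is the power density at grid node
    ``(i * step, j * step)`` relative to the grid centre. Profiles measured as
    power through a scanning aperture convert via
    :meth:`from_aperture_powers`. ``wavelength_nm`` is informational.
    """

    density_uW_per_um2: np.ndarray
    step_um: float = 200.0
    aperture_diameter_um: float = 200.0
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.density_uW_per_um2, dtype=float)
        if d.ndim != 2 or d.size == 0:
            raise ValueError("beam profile must be a non-empty 2D grid")
        if np.any(d < 0) or not np.all(np.isfinite(d)):
            raise ValueError("power densities must be finite and non-negative")
        if self.step_um <= 0 or self.aperture_diameter_um <= 0:
            raise ValueError("grid step and aperture diameter must be positive")
        object.__setattr__(self, "density_uW_per_um2", d)

    @classmethod
    def from_aperture_powers(
        cls,
        powers_uW: np.ndarray,
        step_um: float = 200.0,
        aperture_diameter_um: float = 200.0,
        wavelength_nm: float | None = None,
    ) -> "BeamProfile":
        """Build a profile from per-point powers measured through the scanning
        aperture (power / aperture area = density)."""
        area = _spot_area_um2(aperture_diameter_um)
        return cls(
            density_uW_per_um2=np.asarray(powers_uW, float) / area,
            step_um=step_um,
            aperture_diameter_um=aperture_diameter_um,
            wavelength_nm=wavelength_nm,
        )

    def grid_coords_um(self) -> tuple[np.ndarray, np.ndarray]:
        nr, nc = self.density_uW_per_um2.shape
        r = (np.arange(nr) - (nr - 1) / 2.0) * self.step_um
        c = (np.arange(nc) - (nc - 1) / 2.0) * self.step_um
        return r, c


def aperture_dose(
    profile: BeamProfile,
    centre_um: tuple[float, float] = (0.0, 0.0),
    *,
    diameter_um: float | None = None,
    n_sub: int = 256,
) -> float:
    """Power (µW) through a circular aperture centred at ``centre_um``.

    Integrates the bilinear interpolant of the density grid over the circle,
    with an anti-aliased boundary. An aperture reaching outside the measured
    support is clipped (density 0 outside) with a warning; fully outside gives
    0 µW.
    """
    d = diameter_um if diameter_um is not None else profile.aperture_diameter_um
    if d <= 0:
        raise ValueError("aperture diameter must be positive")
    radius = d / 2.0
    r_grid, c_grid = profile.grid_coords_um()
    cy, cx = centre_um
    if (
        cy - radius < r_grid[0]
        or cy + radius > r_grid[-1]
        or cx - radius < c_grid[0]
        or cx + radius > c_grid[-1]
    ):
        warnings.warn(
            "aperture extends outside the measured beam-profile support; clipped",
            stacklevel=2,
        )
    interp = RegularGridInterpolator(
        (r_grid, c_grid),
        profile.density_uW_per_um2,
        bounds_error=False,
        fill_value=0.0,
    )
    h = d / n_sub
    ax = cy + (np.arange(n_sub) + 0.5) * h - radius
    ay = cx + (np.arange(n_sub) + 0.5) * h - radius
    yy, xx = np.meshgrid(ax, ay, indexing="ij")
    rr = np.hypot(yy - cy, xx - cx)
    # anti-aliased circular window: fraction of each cell inside the aperture
    frac = np.clip((radius - rr) / h + 0.5, 0.0, 1.0)
    dens = interp(np.column_stack([yy.ravel(), xx.ravel()])).reshape(yy.shape)
    return float((dens * frac).sum() * h * h)


@dataclass(frozen=True)
class ExposurePlan:
    """The centring exposure protocol: one UV pulse per acquisition angle."""

    exposure_ms: float = 300.0
    n_angles: int = 3
    per_exposure_dose_uW: float = 16.0
    spot_diameter_um: float = 200.0

    def __post_init__(self) -> None:
        if self.exposure_ms <= 0 or self.spot_diameter_um <= 0:
            raise ValueError("exposure time and spot diameter must be positive")
        if self.n_angles < 0:
            raise ValueError("n_angles must be >= 0")
        if self.per_exposure_dose_uW < 0:
            raise ValueError("per-exposure dose must be >= 0")


@dataclass(frozen=True)
class SafetyThreshold:
    """Published damage threshold: 0.1 mW (100 µW) in a 150 µm spot."""

    power_uW: float = 100.0
    spot_diameter_um: float = 150.0

    def __post_init__(self) -> None:
        if self.power_uW <= 0 or self.spot_diameter_um <= 0:
            raise ValueError("threshold power and spot diameter must be positive")

    @property
    def density_uW_per_um2(self) -> float:
        return self.power_uW / _spot_area_um2(self.spot_diameter_um)


@dataclass(frozen=True)
class DoseReport:
    """Accumulated-dose accounting and the safety verdict.

    ``accumulated_uW`` follows the instrument accounting (per-exposure power x
    number of exposures). ``alternative_accumulated_uJ`` is the
    time-integrated variant (power x exposure seconds x exposures), flagged as
    alternative accounting because the primary figure adds powers.
    """

    per_exposure_uW: float
    n_angles: int
    exposure_ms: float
    accumulated_uW: float
    alternative_accumulated_uJ: float
    plan_density_uW_per_um2: float
    threshold_density_uW_per_um2: float
    verdict: str  # "pass" | "warn"

    def __post_init__(self) -> None:
        expected = self.per_exposure_uW * self.n_angles
        if not math.isclose(self.accumulated_uW, expected, rel_tol=1e-12, abs_tol=1e-12):
            raise ValueError("accumulated dose must equal per-exposure x n_angles")
        if self.verdict not in ("pass", "warn"):
            raise ValueError("verdict must be 'pass' or 'warn'")

    def to_dict(self) -> dict:
        return {
            "per_exposure_uW": self.per_exposure_uW,
            "n_angles": self.n_angles,
            "exposure_ms": self.exposure_ms,
            "accumulated_uW": self.accumulated_uW,
            "alternative_accumulated_uJ": self.alternative_accumulated_uJ,
            "alternative_accounting": "per_exposure_uW * exposure_s * n_angles",
            "plan_density_uW_per_um2": self.plan_density_uW_per_um2,
            "threshold_density_uW_per_um2": self.threshold_density_uW_per_um2,
            "verdict": self.verdict,
        }


def safety_check(report: "DoseReport", threshold: SafetyThreshold) -> str:
    """Compare the per-area density of a single exposure against the damage
    threshold's density; ``pass`` iff strictly below (the boundary is unsafe).
    """
    return "pass" if report.plan_density_uW_per_um2 < threshold.density_uW_per_um2 else "warn"


def accumulated_dose(
    plan: ExposurePlan | None = None,
    threshold: SafetyThreshold | None = None,
) -> DoseReport:
    """Accumulated UV dose of a centring run under the given exposure plan.

    Linear in the number of angles and independent of frame content.
    """
    plan = plan or ExposurePlan()
    threshold = threshold or SafetyThreshold()
    accumulated = plan.per_exposure_dose_uW * plan.n_angles
    alt_uj = plan.per_exposure_dose_uW * (plan.exposure_ms / 1000.0) * plan.n_angles
    plan_density = plan.per_exposure_dose_uW / _spot_area_um2(plan.spot_diameter_um)
    report = DoseReport(
        per_exposure_uW=plan.per_exposure_dose_uW,
        n_angles=plan.n_angles,
        exposure_ms=plan.exposure_ms,
        accumulated_uW=accumulated,
        alternative_accumulated_uJ=alt_uj,
        plan_density_uW_per_um2=plan_density,
        threshold_density_uW_per_um2=threshold.density_uW_per_um2,
        verdict="pass",
    )
    return dataclasses.replace(report, verdict=safety_check(report, threshold))
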