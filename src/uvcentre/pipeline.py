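"""Orchestration of the full two-step centring procedure.

Step 1 aligns the sample holder using the visible-light frames (tip, pattern
match, box centre of mass, multi-angle solve). Step 2 illuminates with UV,
removes the measured holder silhouette from each UV frame, segments the
fluorescing crystal and solves the precise 3D move. The inter-stage move is
applied *virtually* — stage-2 offsets are measured in the original camera
coordinates and the moves composed — since only a simulator backend ships.
A dose report for the executed exposure plan is attached.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal, Sequence

from pydantic import BaseModel, Field, field_validator

from . import crystal as uvx
from . import loop as lp
from .dose import DoseReport, ExposurePlan, SafetyThreshold, accumulated_dose
from .errors import InsufficientAnglesError, NoCrystalError, NoObjectError, UVCentreError
from .geometry import Move3D, OffsetObservation, solve_centre
from .io import load_frames_dir
from .scene import Frame

__all__ = ["CentringConfig", "CentringReport", "run_centring"]


class CentringConfig(BaseModel):
    """Validated configuration of a centring run; every default is the shipped
    protocol value and every field is overridable (e.g. from a JSON file)."""

    pixel_size_um: float = Field(default=2.0, gt=0)
    beam_centre_px: tuple[float, float] | None = None
    angles_deg: list[float] = Field(default_factory=lambda: [0.0, 45.0, 90.0])
    exposure_ms: float = Field(default=300.0, gt=0)
    ncc_threshold: float = Field(default=0.6, ge=-1.0, le=1.0)
    holder_kind: Literal["nylon_loop", "litholoop", "nonstandard"] = "nylon_loop"
    loop_width_um: float = Field(default=300.0, gt=0)
    loop_height_um: float = Field(default=250.0, gt=0)
    wire_thickness_um: float = Field(default=20.0, gt=0)
    edge_sigma_px: float = Field(default=2.0, ge=0.5)
    edge_threshold: float | None = Field(default=None, ge=0)
    band_width_px: int = Field(default=3, ge=0)
    min_crystal_area_px: int = Field(default=25, ge=1)
    per_exposure_dose_uW: float = Field(default=16.0, ge=0)
    dose_spot_diameter_um: float = Field(default=200.0, gt=0)
    threshold_power_uW: float = Field(default=100.0, gt=0)
    threshold_spot_diameter_um: float = Field(default=150.0, gt=0)
    seed: int = 0

    @field_validator("angles_deg")
    @classmethod
    def _angles_in_range(cls, v: list[float]) -> list[float]:
        if not v:
            raise ValueError("need at least one acquisition angle")
        for w in v:
            if not (0.0 <= w < 360.0):
                raise ValueError(f"angle {w} outside [0, 360)")
        return v

    @classmethod
    def from_json(cls, path: str | Path) -> "CentringConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def pattern_mask(self) -> lp.PatternMask:
        return lp.make_pattern_mask(
            self.holder_kind if self.holder_kind != "nonstandard" else "nylon_loop",
            neck_width_um=self.wire_thickness_um,
            shoulder_width_um=self.loop_height_um,
            loop_width_um=self.loop_width_um,
            scale_um_per_px=self.pixel_size_um,
        )

    def edge_params(self) -> uvx.EdgeParams:
        return uvx.EdgeParams(
            sigma_px=self.edge_sigma_px, zero_crossing_threshold=self.edge_threshold
        )

    def exposure_plan(self, n_angles: int | None = None) -> ExposurePlan:
        return ExposurePlan(
            exposure_ms=self.exposure_ms,
            n_angles=len(self.angles_deg) if n_angles is None else n_angles,
            per_exposure_dose_uW=self.per_exposure_dose_uW,
            spot_diameter_um=self.dose_spot_diameter_um,
        )

    def safety_threshold(self) -> SafetyThreshold:
        return SafetyThreshold(
            power_uW=self.threshold_power_uW,
            spot_diameter_um=self.threshold_spot_diameter_um,
        )


Status = Literal["centred", "fallback_used", "no_crystal", "failed"]


@dataclasses.dataclass(frozen=True)
class CentringReport:
    """Machine-readable outcome of one centring run (no timestamps, so
    identical inputs give byte-identical serializations)."""

    status: Status
    final_move_um: tuple[float, float, float]
    stage1_move_um: tuple[float, float, float] | None
    stage2_move_um: tuple[float, float, float] | None
    stage1: dict
    stage2: dict
    dose: dict
    log: tuple[str, ...]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def _beam_centre(frame: Frame, config: CentringConfig) -> tuple[float, float]:
    if config.beam_centre_px is not None:
        return tuple(config.beam_centre_px)
    return ((frame.shape[0] - 1) / 2.0, (frame.shape[1] - 1) / 2.0)


def _group_frames(
    frames: Sequence[Frame], config: CentringConfig
) -> dict[float, dict[str, Frame]]:
    grouped: dict[float, dict[str, Frame]] = {}
    for f in frames:
        grouped.setdefault(round(f.omega_deg, 6), {})[f.illumination] = f
    missing = []
    for w in config.angles_deg:
        have = grouped.get(round(w, 6), {})
        lost = [m for m in ("visible", "uv") if m not in have]
        if lost:
            missing.append(f"omega={w:g}: missing {'+'.join(lost)} frame(s)")
    if missing:
        raise UVCentreError("incomplete frame set: " + "; ".join(missing))
    return grouped


def run_centring(
    frames: Sequence[Frame] | str | Path,
    config: CentringConfig | None = None,
) -> CentringReport:
    """Run the full two-step centring over angle-tagged frames.

    ``frames`` is either a directory of TIFF/PNG frames named
    ``{mode}_{omega:03d}.tif`` or an in-memory sequence of
    :class:`~uvcentre.scene.Frame`. Deterministic given inputs + config.
    """
    config = config or CentringConfig()
    if isinstance(frames, (str, Path)):
        frames = load_frames_dir(frames, pixel_size_um=config.pixel_size_um)
    grouped = _group_frames(frames, config)
    log: list[str] = []

    visible = [grouped[round(w, 6)]["visible"] for w in config.angles_deg]
    uv = [grouped[round(w, 6)]["uv"] for w in config.angles_deg]
    beam = _beam_centre(visible[0], config)

    # ---- stage 1: holder alignment on visible frames
    stage1: dict = {}
    stage1_move: Move3D | None = None
    used_fallback = False
    try:
        alignment = lp.align_loop(
            visible,
            mask=config.pattern_mask(),
            beam_centre_px=beam,
            ncc_threshold=config.ncc_threshold,
        )
        stage1_move = alignment.move
        used_fallback = alignment.used_fallback
        stage1 = {
            "move_um": tuple(alignment.move.as_array()),
            "residual_px": alignment.solution.residual_px,
            "flagged": alignment.solution.flagged,
            "used_fallback": alignment.used_fallback,
            "per_angle": [
                {
                    "omega_deg": e["omega_deg"],
                    "tip_px": None if e["tip"] is None else e["tip"].tip_px,
                    "match_score": e["match"].score,
                    "match_accepted": e["match"].accepted,
                    "box": None
                    if e.get("box") is None
                    else (
                        e["box"].row_min,
                        e["box"].col_min,
                        e["box"].row_max,
                        e["box"].col_max,
                    ),
                    "centre_of_mass_px": None
                    if e.get("box") is None
                    else e["box"].centre_of_mass_px,
                }
                for e in alignment.per_angle
            ],
        }
        log.append(
            f"stage1: holder aligned, move={tuple(round(float(v), 3) for v in alignment.move.as_array())} um"
            + (" (spherical fallback)" if used_fallback else "")
        )
    except (NoObjectError, InsufficientAnglesError) as exc:
        stage1 = {"error": str(exc)}
        log.append(f"stage1 failed: {exc}")

    # ---- stage 2: UV crystal centring (offsets measured in original
    # coordinates; the stage-1 move is composed virtually)
    stage2: dict = {"per_angle": []}
    observations: list[OffsetObservation] = []
    edge_params = config.edge_params()
    for vis_frame, uv_frame in zip(visible, uv):
        entry: dict = {"omega_deg": uv_frame.omega_deg}
        holder = uvx.holder_mask_from_visible(vis_frame)
        cleaned = uvx.remove_loop_model(
            uv_frame, holder, band_width_px=config.band_width_px
        )
        try:
            edges = uvx.log_edge_map(cleaned, edge_params)
            measure = uvx.segment_crystal(
                cleaned,
                edges,
                beam_centre_px=beam,
                min_area_px=config.min_crystal_area_px,
            )
            entry["centroid_px"] = measure.centroid_px
            entry["extent_um"] = measure.extent_um
            entry["mean_interior_intensity"] = measure.mean_interior_intensity
            observations.append(
                OffsetObservation(
                    omega_deg=uv_frame.omega_deg,
                    dx_px=measure.centroid_px[1] - beam[1],
                    dy_px=measure.centroid_px[0] - beam[0],
                    pixel_size_um=uv_frame.pixel_size_um,
                )
            )
        except (NoCrystalError, ValueError) as exc:
            entry["error"] = str(exc)
            log.append(f"stage2 omega={uv_frame.omega_deg:g}: {exc}")
        stage2["per_angle"].append(entry)

    final_move: Move3D | None = None
    status: Status
    distinct = {round(o.omega_deg % 180.0, 6) for o in observations}
    if len(distinct) >= 2:
        solution = solve_centre(observations)
        final_move = solution.move
        stage2["residual_px"] = solution.residual_px
        stage2["flagged"] = solution.flagged
        status = "fallback_used" if used_fallback else "centred"
        log.append(
            f"stage2: crystal centred, move={tuple(round(float(v), 3) for v in final_move.as_array())} um"
        )
    else:
        status = "no_crystal" if stage1_move is not None else "failed"
        final_move = stage1_move if stage1_move is not None else Move3D(0.0, 0.0, 0.0)
        log.append(
            "stage2: no crystal found at enough angles; "
            + ("reporting stage-1 move" if stage1_move is not None else "no move available")
        )

    stage2_move = None
    if status in ("centred", "fallback_used") and stage1_move is not None:
        stage2_move = tuple((final_move - stage1_move).as_array())

    dose_report: DoseReport = accumulated_dose(
        config.exposure_plan(n_angles=len(uv)), config.safety_threshold()
    )

    return CentringReport(
        status=status,
        final_move_um=tuple(final_move.as_array()),
        stage1_move_um=None if stage1_move is None else tuple(stage1_move.as_array()),
        stage2_move_um=stage2_move,
        stage1=stage1,
        stage2=stage2,
        dose=dose_report.to_dict(),
        log=tuple(log),
    )
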