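"""Frame and report IO.

Frames are written as 16-bit grayscale TIFF with the acquisition metadata
(pixel size, illumination mode, rotation angle, exposure, intensity scale)
embedded as JSON in the TIFF description tag. File names follow the
``{mode}_{omega:03d}.tif`` convention (e.g. ``visible_045.tif``,
``uv_090.tif``) so angle and mode are recoverable without a database.
Ground truth is a JSON sidecar per fixture set.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .scene import Frame, GroundTruth, GroundTruthSlice

__all__ = [
    "frame_filename",
    "write_frame",
    "read_frame",
    "save_fixture_set",
    "load_frames_dir",
    "ground_truth_to_dict",
    "ground_truth_from_dict",
]

_DN_SCALE = 16383.5  # digitizes intensities in [0, 4] into 16 bits
_NAME_RE = re.compile(r"^(visible|uv)_(\d{1,3})\.(?:tif|tiff|png)$")


def frame_filename(frame: Frame) -> str:
    return f"{frame.illumination}_{int(round(frame.omega_deg)):03d}.tif"


def write_frame(frame: Frame, path: str | Path) -> Path:
    path = Path(path)
    dn = np.round(np.clip(frame.pixels, 0.0, 4.0) * _DN_SCALE).astype(np.uint16)
    meta = {
        "pixel_size_um": frame.pixel_size_um,
        "illumination": frame.illumination,
        "omega_deg": frame.omega_deg,
        "exposure_ms": frame.exposure_ms,
        "dn_scale": _DN_SCALE,
    }
    tifffile.imwrite(path, dn, description=json.dumps(meta))
    return path


def read_frame(path: str | Path, *, pixel_size_um: float | None = None) -> Frame:
    """Read a frame written by :func:`write_frame`, or any grayscale TIFF/PNG
    named per the ``{mode}_{omega}`` convention (then ``pixel_size_um`` is
    required and intensities are rescaled to [0, 1])."""
    path = Path(path)
    meta: dict = {}
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            data = page.asarray()
            desc = page.tags.get("ImageDescription")
            if desc is not None:
                try:
                    meta = json.loads(desc.value)
                except (TypeError, ValueError):
                    meta = {}
    else:
        import imageio.v3 as iio  # png fallback

        data = iio.imread(path)
        if data.ndim == 3:
            data = data.mean(axis=-1)
    if meta:
        pixels = data.astype(float) / float(meta.get("dn_scale", _DN_SCALE))
        return Frame(
            pixels=pixels,
            pixel_size_um=float(meta["pixel_size_um"]),
            illumination=meta["illumination"],
            omega_deg=float(meta["omega_deg"]),
            exposure_ms=float(meta.get("exposure_ms", 300.0)),
        )
    m = _NAME_RE.match(path.name)
    if m is None:
        raise ValueError(
            f"{path.name}: no embedded metadata and name does not follow "
            "'{mode}_{omega}.tif'"
        )
    if pixel_size_um is None:
        raise ValueError(f"{path.name}: pixel_size_um required for bare images")
    data = data.astype(float)
    peak = data.max()
    return Frame(
        pixels=data / peak if peak > 0 else data,
        pixel_size_um=pixel_size_um,
        illumination=m.group(1),
        omega_deg=float(m.group(2)),
    )


def ground_truth_to_dict(truth: GroundTruth) -> dict:
    return dataclasses.asdict(truth)


def ground_truth_from_dict(d: dict) -> GroundTruth:
    slices = tuple(
        GroundTruthSlice(
            omega_deg=s["omega_deg"],
            crystal_centroid_px=tuple(s["crystal_centroid_px"]),
            loop_centre_px=tuple(s["loop_centre_px"]),
            loop_tip_px=tuple(s["loop_tip_px"]),
            loop_box_px=tuple(s["loop_box_px"]),
        )
        for s in d["slices"]
    )
    return GroundTruth(
        crystal_centre_3d_um=tuple(d["crystal_centre_3d_um"]),
        loop_offset_um=tuple(d["loop_offset_um"]),
        widest_dimension_um=d["widest_dimension_um"],
        slices=slices,
    )


def save_fixture_set(
    frames: Sequence[Frame],
    truth: GroundTruth | None,
    out_dir: str | Path,
) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = [write_frame(f, out_dir / frame_filename(f)) for f in frames]
    if truth is not None:
        gt_path = out_dir / "ground_truth.json"
        gt_path.write_text(json.dumps(ground_truth_to_dict(truth), indent=2))
        written.append(gt_path)
    return written


def load_frames_dir(
    frames_dir: str | Path, *, pixel_size_um: float | None = None
) -> list[Frame]:
    frames_dir = Path(frames_dir)
    paths = sorted(
        p
        for p in frames_dir.iterdir()
        if p.suffix.lower() in (".tif", ".tiff", ".png")
    )
    if not paths:
        raise FileNotFoundError(f"no TIFF/PNG frames found in {frames_dir}")
    return [read_frame(p, pixel_size_um=pixel_size_um) for p in paths]
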