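import dataclasses
import math

import numpy as np
import pytest
from skimage.measure import find_contours

import uvcentre as uc
from uvcentre import crystal as ux

from conftest import NOISELESS, make_frame


def naive_log_convolution(pixels: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Brute-force dense convolution oracle with mirror boundaries."""
    kh, kw = kernel.shape
    rh, rw = kh // 2, kw // 2
    padded = np.pad(pixels, ((rh, rh), (rw, rw)), mode="reflect")
    out = np.zeros_like(pixels, dtype=float)
    flipped = kernel[::-1, ::-1]
    for i in range(pixels.shape[0]):
        for j in range(pixels.shape[1]):
            out[i, j] = (padded[i : i + kh, j : j + kw] * flipped).sum()
    return out


def square_measure(frame: uc.Frame, r0, r1, c0, c1) -> ux.CrystalMeasure:
    """Hand-built measure over a rectangular region (for contrast tests)."""
    region = np.zeros(frame.shape, dtype=bool)
    region[r0:r1, c0:c1] = True
    contour = max(find_contours(region.astype(float), 0.5), key=len)
    return ux.CrystalMeasure(
        contour=contour,
        centroid_px=((r0 + r1 - 1) / 2, (c0 + c1 - 1) / 2),
        extent_px=(float(c1 - c0), float(r1 - r0)),
        extent_um=(float(c1 - c0), float(r1 - r0)),
        mean_interior_intensity=float(frame.pixels[region].mean()),
        region_mask=region,
        background=0.0,
    )


# -----------------------------------------------------------------------------
# LoG kernel + edge map


def test_log_kernel_is_zero_mean():
    for sigma in (0.8, 1.0, 2.0, 3.5):
        k = ux.log_kernel(sigma)
        assert abs(k.sum()) <= 1e-6


def test_constant_frame_has_zero_response_and_no_edges():
    em = ux.log_edge_map(make_frame(np.full((32, 32), 0.4)))
    assert np.allclose(em.response, 0.0, atol=1e-12)
    assert not em.edges.any()


def test_log_response_matches_dense_convolution_oracle():
    px = np.zeros((9, 9))
    px[4, 4] = 1.0
    frame = make_frame(px)
    params = ux.EdgeParams(sigma_px=1.0)
    em = ux.log_edge_map(frame, params)
    oracle = naive_log_convolution(px, ux.log_kernel(1.0))
    assert np.abs(em.response - oracle).max() <= 1e-9


def test_log_kernel_larger_than_frame_rejected():
    with pytest.raises(ValueError):
        ux.log_edge_map(make_frame(np.zeros((10, 10))), ux.EdgeParams(sigma_px=4.0))


def test_edge_params_validation():
    with pytest.raises(ValueError):
        ux.EdgeParams(sigma_px=0.3)
    with pytest.raises(ValueError):
        ux.EdgeParams(zero_crossing_threshold=-1.0)


def test_step_edge_detected_at_boundary():
    px = np.full((40, 40), 0.05)
    px[10:30, 10:30] = 0.9
    em = ux.log_edge_map(make_frame(px))
    rows, cols = np.nonzero(em.edges)
    assert len(rows) > 0
    # edges hug the square boundary (within the LoG support)
    assert rows.min() >= 6 and rows.max() <= 33
    assert cols.min() >= 6 and cols.max() <= 33


# -----------------------------------------------------------------------------
# loop removal


def uv_pair(spec, omega=0.0):
    vis, _ = uc.render_scene(spec, omega, "visible")
    uvf, gt = uc.render_scene(spec, omega, "uv")
    return vis, uvf, gt


def test_removal_of_loop_only_scene_leaves_background():
    lvl = uc.IntensityLevels(0.03, 0.15, 0.03)  # crystal invisible
    spec = uc.SceneSpec(uv_levels=lvl, noise=NOISELESS)
    vis, uvf, _ = uv_pair(spec)
    cleaned = ux.remove_loop_model(uvf, ux.holder_mask_from_visible(vis))
    assert cleaned.pixels.max() <= 0.03 + 1e-9
    with pytest.raises(uc.NoCrystalError):
        ux.segment_crystal(cleaned, ux.log_edge_map(cleaned))


def test_removal_passes_through_outside_band_bit_exact(noiseless_spec):
    vis, uvf, _ = uv_pair(noiseless_spec)
    mask = ux.holder_mask_from_visible(vis)
    band = ux.loop_band(mask, 3)
    cleaned = ux.remove_loop_model(uvf, mask, band_width_px=3)
    assert np.array_equal(cleaned.pixels[~band], uvf.pixels[~band])
    assert not np.array_equal(cleaned.pixels, uvf.pixels)


def test_disjoint_crystal_pixels_untouched(noiseless_spec):
    vis, uvf, gt = uv_pair(noiseless_spec)
    cleaned = ux.remove_loop_model(uvf, ux.holder_mask_from_visible(vis))
    crystal = uvf.pixels >= 0.8  # interior of the fluorescing crystal
    assert crystal.any()
    assert np.array_equal(cleaned.pixels[crystal], uvf.pixels[crystal])


def test_missing_loop_geometry_warns_and_passes_through(noiseless_spec):
    _, uvf, _ = uv_pair(noiseless_spec)
    with pytest.warns(UserWarning):
        out = ux.remove_loop_model(uvf, None)
    assert out is uvf


def test_bright_loop_dim_crystal_segmented_after_removal():
    """When the holder outshines the crystal in UV, removal of the holder
    model is what makes the segmentation land on the crystal."""
    lvl = uc.IntensityLevels(background=0.03, loop=0.9, crystal=0.5)
    spec = uc.SceneSpec(
        uv_levels=lvl, crystal_offset_um=(15.0, -10.0, 0.0), noise=NOISELESS
    )
    vis, uvf, gt = uv_pair(spec)
    cleaned = ux.remove_loop_model(uvf, ux.holder_mask_from_visible(vis))
    measure = ux.segment_crystal(cleaned, ux.log_edge_map(cleaned))
    assert abs(measure.centroid_px[0] - gt.crystal_centroid_px[0]) <= 1.0
    assert abs(measure.centroid_px[1] - gt.crystal_centroid_px[1]) <= 1.0


# -----------------------------------------------------------------------------
# segmentation


def test_centred_square_measured_exactly():
    px = np.full((64, 64), 0.05)
    px[22:42, 22:42] = 0.9  # 20x20 bright square
    frame = make_frame(px)
    measure = ux.segment_crystal(frame, ux.log_edge_map(frame))
    assert measure.centroid_px == pytest.approx((31.5, 31.5), abs=0.5)
    assert measure.extent_px[0] == pytest.approx(20.0, abs=2.0)
    assert measure.extent_px[1] == pytest.approx(20.0, abs=2.0)
    assert measure.mean_interior_intensity > 0.5


def test_simulated_crystal_measured_within_tolerance(noiseless_spec):
    vis, uvf, gt = uv_pair(noiseless_spec, omega=45.0)
    cleaned = ux.remove_loop_model(uvf, ux.holder_mask_from_visible(vis))
    measure = ux.segment_crystal(cleaned, ux.log_edge_map(cleaned))
    assert abs(measure.centroid_px[0] - gt.crystal_centroid_px[0]) <= 1.0
    assert abs(measure.centroid_px[1] - gt.crystal_centroid_px[1]) <= 1.0
    w_px = noiseless_spec.crystal_dims_um[0] / noiseless_spec.pixel_size_um
    h_px = noiseless_spec.crystal_dims_um[1] / noiseless_spec.pixel_size_um
    assert measure.extent_px[0] == pytest.approx(w_px, abs=2.0)
    assert measure.extent_px[1] == pytest.approx(h_px, abs=2.0)
    assert measure.extent_um[0] == pytest.approx(
        measure.extent_px[0] * noiseless_spec.pixel_size_um
    )


def test_largest_of_two_crystals_selected():
    px = np.full((96, 96), 0.05)
    px[20:30, 20:30] = 0.9  # small: 10x10
    px[50:70, 40:60] = 0.9  # large: 20x20 (4x the area)
    frame = make_frame(px)
    measure = ux.segment_crystal(frame, ux.log_edge_map(frame))
    assert measure.centroid_px == pytest.approx((59.5, 49.5), abs=1.0)


def test_no_crystal_error_on_empty_frame():
    frame = make_frame(np.full((48, 48), 0.03))
    with pytest.raises(uc.NoCrystalError):
        ux.segment_crystal(frame, ux.log_edge_map(frame))


# -----------------------------------------------------------------------------
# line scans


def test_uniform_frame_profiles_flat():
    profile = ux.line_scans(make_frame(np.full((32, 40), 0.2)), (10, 15))
    assert np.all(profile.horizontal == 0.2) and len(profile.horizontal) == 40
    assert np.all(profile.vertical == 0.2) and len(profile.vertical) == 32


def test_point_outside_frame_rejected():
    with pytest.raises(ValueError):
        ux.line_scans(make_frame(np.zeros((32, 32))), (40, 10))


def test_scans_through_crystal_peak_inside_span(noiseless_spec):
    _, uvf, gt = uv_pair(noiseless_spec)
    profile = ux.line_scans(uvf, gt.crystal_centroid_px)
    w_px = noiseless_spec.crystal_dims_um[0] / noiseless_spec.pixel_size_um
    cols = np.argsort(profile.horizontal)[::-1][:5]
    assert np.all(np.abs(cols - gt.crystal_centroid_px[1]) <= w_px / 2 + 1)


def test_uv_scan_contrast_exceeds_visible(noiseless_spec):
    """The paired visible-light scan through the same point shows a much lower
    peak-to-background ratio than the UV scan."""
    vis, uvf, gt = uv_pair(noiseless_spec)
    p_uv = ux.line_scans(uvf, gt.crystal_centroid_px)
    p_vis = ux.line_scans(vis, gt.crystal_centroid_px)

    def peak_to_background(profile):
        h = profile.horizontal
        return h.max() / np.median(h)

    assert peak_to_background(p_uv) > peak_to_background(p_vis)


# -----------------------------------------------------------------------------
# contrast score


def test_uniform_frame_contrast_is_one():
    frame = make_frame(np.full((64, 64), 0.3))
    measure = square_measure(frame, 20, 40, 20, 40)
    assert ux.contrast_score(frame, measure) == pytest.approx(1.0)


def test_contrast_matches_mask_mean_oracle(noiseless_spec):
    vis, uvf, _ = uv_pair(noiseless_spec)
    mask = ux.holder_mask_from_visible(vis)
    cleaned = ux.remove_loop_model(uvf, mask)
    measure = ux.segment_crystal(cleaned, ux.log_edge_map(cleaned))
    band = ux.loop_band(mask, 3)
    got = ux.contrast_score(cleaned, measure, exclude_mask=band)
    inside = cleaned.pixels[measure.region_mask].mean()
    outside = cleaned.pixels[~measure.region_mask & ~band].mean()
    assert got == pytest.approx(inside / outside, rel=1e-12)


def test_zero_background_flagged_infinite():
    px = np.zeros((64, 64))
    px[20:40, 20:40] = 0.9
    frame = make_frame(px)
    measure = square_measure(frame, 20, 40, 20, 40)
    assert ux.contrast_score(frame, measure) == math.inf


def test_uv_contrast_exceeds_visible_on_paired_fixtures(noiseless_spec):
    for seed in range(3):
        spec = dataclasses.replace(noiseless_spec, seed=seed, noise=uc.NoiseModel())
        vis, uvf, _ = uv_pair(spec)
        mask = ux.holder_mask_from_visible(vis)
        band = ux.loop_band(mask, 3)
        cleaned = ux.remove_loop_model(uvf, mask)
        measure = ux.segment_crystal(cleaned, ux.log_edge_map(cleaned))
        uv_score = ux.contrast_score(uvf, measure, exclude_mask=band)
        vis_score = ux.contrast_score(vis, measure, exclude_mask=band)
        assert uv_score > vis_score
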