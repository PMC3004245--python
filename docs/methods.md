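# Methods

## Problem and model

`uvcentre` solves crystal centring as two image-analysis stages plus one
geometric solve. All image coordinates are 0-based `(row, col)` with the
origin at the top-left pixel; all µm↔px conversions go through a single
`pixel_size_um` calibration; the beam centre defaults to the frame centre
`((rows−1)/2, (cols−1)/2)` and is configurable.

**Goniometer geometry.** The stage frame is `(x, y, z)` with `x` along the ω
rotation axis (image-horizontal), `y` image-vertical at ω = 0 and `z` the
viewing direction at ω = 0. Positive ω is a right-handed rotation about +x,
`dy` is measured downward (row-increasing), so a point at `(x, y, z)` µm
appears at

    dx_px = x / s,    dy_px = (y·cos ω − z·sin ω) / s.

Any consistent convention would do; simulator and solver share this one
constant definition. The inverse problem is an ordinary least squares over
all observations; `x` reduces to the mean of the horizontal offsets because
the model makes `dx` ω-independent. Two angles distinct modulo 180° are
necessary and sufficient to separate `y` from `z`; degenerate sets raise an
error rather than returning a rank-deficient solution. A residual RMS above
2 px (configurable) flags the solution as inconsistent but still returns it.

## Synthetic scenes

The generator renders what the two illumination regimes of a centring
station look like, not photorealistic micrographs:

* geometry — a holder entering on a pin from the image-left edge: a nylon
  loop (projected elliptical annulus), a litholoop (rounded-rectangle frame
  with an aperture) or a non-standard blob (filled ellipse); a convex
  crystal (box, hexagon or ellipse) at a 3D offset from the rotation axis.
  The loop plane is modelled as always facing the camera: rotation moves
  silhouette centres by the forward model above but does not foreshorten
  them. The camera is modelled as viewing exactly along the beam (no
  parallax between camera and beam axes).
* intensities (arbitrary units 0–1) — visible backlight: background 0.15,
  holder 0.70, crystal 0.20 (the crystal is nearly invisible against the
  buffer); UV fluorescence: background 0.03, holder 0.15, crystal 0.80.
  These defaults reproduce the qualitative contrast inversion between the
  two modes and are the conditions under which the contrast and recovery
  suites run.
* noise — Poisson-like shot noise (variance = `shot_scale`·signal, default
  `shot_scale` = 0.008, i.e. SNR ≈ 10 at the UV crystal level) plus additive
  Gaussian read noise (default σ = 0.01). The SNR-5 campaigns raise the read
  noise to σ = 0.1386 so that crystal-level SNR is exactly 5.
* sub-pixel geometry — 4× supersampling followed by box downsampling, which
  is what makes the 0.5 px rendered-centroid-vs-analytic-projection property
  hold.
* determinism — each frame's RNG is derived from (scene seed, illumination
  mode, angle), so fixture sets are bit-reproducible and identical whether
  frames are rendered singly or in batches.

What the generator does **not** emulate — optical point-spread, ice rings,
solvent artefacts, holder foreshortening, camera/beam parallax, non-uniform
illumination — bounds what the passing suites show: they validate the
algorithmic chain (template matching, silhouette removal, LoG segmentation,
multi-angle solve, unit handling) under controlled contrast and noise, not
robustness to every artefact of real beamline imagery.

## Stage 1: holder recognition

* Foreground extraction: 3×3 median filter, Otsu threshold, removal of
  connected components under 50 px, and an absolute dynamic-range floor of
  0.1 intensity units so noise-only (empty-mount) frames yield an empty mask
  rather than a spurious Otsu split.
* Tip: Sobel gradient magnitude, Otsu-thresholded, restricted to the
  foreground neighbourhood; the tip is the rightmost edge pixel (pin enters
  image-left by convention), its row the rounded mean edge row of that
  column — the middle of a blunt tip.
* Pattern match: the "neck and shoulders" template is generated
  parametrically (pin thickness, loop height, loop width, cap depth) with
  the same geometric primitives as the simulator, never from stored images;
  matching is exact normalized cross-correlation computed directly
  (integral-image window statistics + per-row template products, no FFT),
  so the score equals a brute-force NCC to ~1e−12. Acceptance threshold
  default 0.6, configurable — a filled blob scores ≈ 0.69 against the nylon
  template, so stricter thresholds route such holders to the fallback.
* Box and centre: the box spans from the matched pin/loop junction to the
  rightmost foreground column; the centre of mass is the intensity-weighted
  centroid of foreground pixels in the box (scale-invariant,
  translation-equivariant).
* Spherical fallback: widest dimension = maximum foreground extent (height
  or width) over all frames, with leading pin-like columns trimmed only when
  the silhouette touches the image-left edge; assumed diameter is exactly
  1.5× that. The maximum-over-frames aggregation is this package's choice.

## Stage 2: UV crystal segmentation

* Holder removal re-uses the stage-1 model geometrically: the silhouette
  measured on the paired visible frame (same ω), dilated by `band_width_px`
  (default 3), is replaced by the background estimate. The whole wire is
  removed, not just its outline — removing only the outline leaves a
  residual wire stripe whose own closed contour can swallow the loop
  interior downstream. Pixels outside the band pass through bit-exactly.
  Whether removal uses the visible-light model or the UV image itself is
  exposed via the API (any boolean mask can be supplied); the visible-light
  model is the default.
* Background estimate: median of pixels below the Otsu threshold (the
  lights-off background is globally dark), with 1.4826×MAD as a robust noise
  sigma.
* LoG edges: the kernel is the sampled analytic Laplacian-of-Gaussian,
  DC-corrected to zero sum; convolution uses mirror boundaries. Defaults
  σ = 2 px and zero-crossing threshold 1% of the frame's dynamic range, both
  configurable. An edge is a 4-neighbour sign change with both flanks above
  threshold; a response sampled exactly at zero on the crossing line (the
  generic case for symmetric scenes) is handled by comparing the flanking
  samples across the near-zero pixel.
* Region extraction: zero-crossing rings are closed against small
  noise-induced gaps by dilate(2 px) → fill holes → erode(2 px) — closing
  *after* filling, because eroding a thin bridge before the fill re-opens
  it. Candidate regions need ≥ 25 px area and mean interior intensity above
  background + 3σ; the largest wins, ties broken by proximity to the beam
  centre. Extents are read after discarding the outer (positive-response)
  half of the LoG ring, whose zero crossing sits on the physical boundary.
  The centroid is the background-subtracted intensity-weighted centre of
  mass of the region.
* Degenerate outcomes are typed: empty mount (`NoObjectError`) is distinct
  from holder-present-but-no-crystal (`NoCrystalError`).

## Dose accounting

The accumulated dose follows the instrument's own accounting: per-exposure
power × number of exposures (3 × 16 µW = 48 µW for the default protocol),
which adds powers without scaling by exposure time. Because that mixes
power and dose units, the report also carries a time-integrated variant in
µJ (power × exposure seconds × exposures, 14.4 µJ for the defaults) flagged
as alternative accounting. Spots are treated as circles of the stated
diameters for per-area density normalization; safety passes iff the
single-exposure density is strictly below the 0.1 mW / 150 µm-spot damage
threshold (the boundary is unsafe). Measured beam-profile grids are
integrated over the circular aperture by bilinear interpolation with an
anti-aliased disc window (256 sub-samples per axis).

## Pipeline

`run_centring` composes the stages over angle-tagged frames
(`{mode}_{omega:03d}.tif`). The inter-stage move is applied virtually —
stage-2 offsets are measured in the original camera coordinates and the
moves composed — since only a simulator backend ships; a hardware adapter
would apply the stage-1 move physically between stages. Stage-1 and stage-2
share the angle list by default but the stages tolerate partial per-angle
failures: statuses are `centred`, `fallback_used` (stage 1 fell back but the
crystal was centred), `no_crystal` (stage-1 move still reported) and
`failed`. Reports contain no timestamps, so identical inputs give
byte-identical JSON.

## Problem sizes and defaults used by the verification suites

The large campaigns run on 160×160 px frames at 3 µm/px (a 480 µm field of
view, chosen as a realistic camera region of interest): 200 seeded noiseless
scenes and 200 at crystal SNR 5 for end-to-end recovery, and 200 paired
UV/visible fixtures for the contrast comparison, with crystal offsets drawn
uniformly within ±30 µm of the rotation axis and loop offsets within
±10 µm. Unit and oracle tests use 256×256 px at 2 µm/px and frames ≤ 64×64
for brute-force comparisons. The full 3-angle pipeline on a 512×512 fixture
completes in about 3 s on one CPU.

## Known limitations

* The loop-removal band assumes the holder silhouette is measurable on the
  visible frame; a crystal overlapping the wire in projection loses the
  overlapped pixels to the band, biasing the centroid toward the visible
  part.
* The pattern match assumes the configured holder family and nominal
  dimensions; badly mis-specified dimensions lower the NCC score until the
  spherical fallback takes over.
* The widest-dimension measurement is silhouette-based and pixel-quantized;
  Otsu binarization of anti-aliased edges under-reads extents by roughly a
  pixel per side at low magnification.
* The dose budget is bookkeeping, not photochemistry: no wavelength
  dependence or damage kinetics.
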