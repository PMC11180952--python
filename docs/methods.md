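# Methods

## Acquisition model

The package models a fixed camera photographing the face of a paraffin
block after every k-th microtome cut. Geometry is fully determined by the
acquisition parameters:

| parameter | default | meaning |
|---|---|---|
| `fov_mm` | (150, 100) | field of view of the camera, mm |
| `resolution_px` | (1500, 1000) | sensor frame, px (native rig: 6000×4000) |
| `cut_thickness_um` | 20 | microtome cut thickness, µm |
| `photo_every_k` | 10 | photograph each k-th cut |
| `target_voxel_mm` | 0.2 | isotropic voxel size of the output volume |

Derived quantities: pixel size = fov_w/res_w (square pixels enforced to
1e-9), slice spacing Δz = cut·k/1000 mm. With the native 6000×4000 frame the
pixel size is 0.025 mm and an 8× downsampling matches the 0.2 mm spacing;
the default working frame is the same FOV at 1500×1000 px (0.1 mm pixels,
2× downsampling), chosen so that simulations and the test suite run in
seconds-to-minutes on one CPU while exercising identical code paths. The
native geometry remains available through configuration.

Pixel coordinates place pixel centers at integers, origin top-left, x
rightward, y downward; continuous coordinate u corresponds to physical
position (u+0.5)·pixel_size.

## Synthetic blockface generator

The phantom is an ellipse (semi-axes 52×33 mm, centered in the FOV) split
into three 120° angular sectors colored blue/red/green — distinguishable
surrogates for arterial territories labeled by injected colored gelatin —
on a light paraffin background, with four dark disks (radius 2.5 mm) near
the corners as fiducials. Sector colors must differ pairwise by ≥ 64 in
some channel so arg-max-channel classification is well posed; markers must
lie outside the ellipse at every modulation amplitude. The outline is
modulated sinusoidally along the stack (amplitude 5%, period 40 slices) to
mimic a changing specimen cross-section; a static phantom
(`shape_modulation_amp=0`) gives byte-identical slices under zero jitter,
which anchors the generator's determinism tests.

Per-slice perturbations (all `JitterSpec` fields, drawn from a seeded
`numpy` Generator so equal seeds give bit-identical stacks):

* magnification: pinhole model scale_i = d₀/(d₀ + i·Δz), default
  d₀ = 500 mm — the simplest physically faithful monotone shrink for a
  camera whose distance to the block face grows by one slice spacing per
  photograph; `d0_mm = inf` disables drift;
* rotation U(−1°, 1°) and translation U(−20, 20) px about/plus the frame
  center — small rig movements;
* exposure gain U(0.9, 1.1) and per-channel white-balance tint
  U(0.95, 1.05). The real exposure differences are qualitative
  ("slight"); these ranges are visible but leave the markers the darkest
  structures by a wide margin.

Rendering is analytic and anti-aliased: each output pixel is the box mean
of 4×4 membership samples mapped through the inverse ground-truth
transform, multiplied by gain·tint, then quantized round-half-up with
clipping at 255. Because gains act before quantization, exact linearity
(e.g. doubling under gain 2) holds on flat palette regions but not on
anti-aliased edge pixels, which re-quantize; tests assert linearity on the
flat regions. Ground truth per slice records the exact phantom→image
transform, the photometric gains, and the analytic marker centers (the
transform applied to the physical marker positions, not re-measured from
the raster). A configuration whose drift/jitter pushes any marker out of
frame is rejected up front.

What the generator does **not** emulate: tissue texture, specular flash
reflections, depth of field, lens distortion, knife chatter, or debris.
Passing tests therefore demonstrate correctness of the geometry/photometry
pipeline under the modeled degradations, not robustness to arbitrary real
photographs — on real data the Hough score floor and the paraffin-patch
placement are the knobs to revisit.

## Fiducial detection

Grayscale (ITU-R 601) → inversion and normalization by the maximum (making
detection invariant to global exposure gain) → Canny edges (σ = 2,
thresholds 0.1/0.3 on the normalized image) → circular Hough accumulation
over integer radii spanning the configured range (default 0.7–1.3× the
nominal marker radius in px) → peak extraction with greedy euclidean
non-maximum suppression at 2·r_max separation, strongest first, ties broken
toward lower (y, x) for determinism. Scores are accumulator strengths
normalized by circumference, so a complete circle scores near 1 at any
radius; the default floor is 0.3. Fewer surviving peaks than expected raise
a `DetectionError` carrying the count; a structureless (constant) image
short-circuits to that error.

Subpixel refinement: Otsu's threshold on a window covering the detected
circle plus a surrounding annulus separates marker from background locally;
the center is the centroid of below-threshold pixels inside the circle
weighted by (threshold − intensity), so anti-aliased edge pixels contribute
fractionally. On synthetic disks this lands within ~0.05 px of the analytic
center and within 0.5 px of an exhaustive template-search oracle.

Corner labels (TL/TR/BL/BR) are assigned by quadrant relative to the image
center; two detections in one quadrant raise an `AmbiguityError` naming the
quadrant. The labeled set validates that each marker sits in its quadrant
and at least one radius from every border.

## Alignment

Deliberately two-stage, matching the method it reimplements: the scale is
estimated first (mean of the six marker-pair distance ratios), then the
rotation/translation is fit on the scale-corrected points and the given
scale is folded into the returned transform unchanged — the transform's
scale always equals `compute_magnification`'s output exactly. The rigid fit
is the closed-form least-squares solution θ = atan2(Σ p×q, Σ p·q) on
centered points with analytic translation; the RMS corner residual is
attached to the result (as a `RigidFit` wrapper, since the transform
dataclass is frozen). A joint 4-dof similarity fit (`estimate_similarity`)
is provided for comparison but not used by the pipeline. Degenerate marker
geometry — pairwise distances under 1 px for the scale, or a centered point
spread whose second singular value collapses for the fit — raises
`DegenerateGeometryError`.

Resampling into the reference frame uses cubic-spline interpolation
(`scipy.ndimage.affine_transform`, `grid-constant` boundary) at full input
resolution, before any downscaling; out-of-frame pixels are filled with the
per-channel median of a 10 px border ring of the image (approximating
paraffin, so the volume has no dark frames). Pure integer translations at
unit scale take an exact copy path. Registration target is always the first
image of the stack.

## Color normalization

Order: white balance → enhancement → brightness transfer, applied to the
*aligned* images so the paraffin patch stays on paraffin despite camera
drift.

* White balance neutralizes the patch at its own mean luminance
  L = (m_R+m_G+m_B)/3 (gains L/m_c). Neutralizing at L rather than at 255
  keeps overall brightness unchanged and cannot blow out the image; the
  operation is idempotent up to ±1 re-quantization. A patch channel mean
  below 1 is an error; a patch channel std above 12 logs a warning (the
  patch probably is not pure paraffin).
* Enhancement: out = gray + f·(in − gray) with ITU-R 601 gray; default
  f = 1.3, a purely cosmetic boost; f = 1 is a byte-exact identity.
* Brightness transfer matches the HSV value channel's mean/std to the
  reference (first slice by default; a `global` mean-stats mode is
  available). HSV uses the standard hexcone model via scikit-image with
  V ≡ max(R, G, B) on the [0, 255] scale. Source statistics are computed on
  the whole frame; with self-referenced statistics the operation is an
  identity to ±1.

## Volume assembly and NIfTI

Lanczos-3 downsampling goes through Pillow's `resize` (the canonical
implementation of that filter); output dimensions are rounded so physical
extent is preserved within one output pixel, and a constant image is a
fixed point. The builder requires all slices to share dimensions and pixel
size, and errors (`AnisotropyError`) unless in-plane resolution equals
slice spacing within 1e-9 mm — isotropy is enforced, never silently
arranged. The pipeline performs this check before any stage runs.

NIfTI-1 output via nibabel: default datatype RGB24 (structured
(R, G, B) uint8 voxels); `split_channels` writes a 4-D uint8 array instead
for viewers that render only grayscale. The affine is diag(v, v, v, 1) —
slice index along +z of a right-handed frame, in-plane axes following image
x/y; no anatomical orientation is claimed since none is defined for a
phantom. Round trips are bit-exact, and a test cross-reads the file with
SimpleITK as an independent implementation.

## Numerical choices

* 8-bit quantization everywhere is round-half-up (`floor(x+0.5)`) with
  clipping to [0, 255]; each operation quantizes exactly once.
* Rotations are stored wrapped to (−π, π]; scale > 0 always (a block cannot
  flip between cuts), so reflections are rejected at construction.
* Hough tie-breaks prefer lower (y, then x); all stack iteration is in
  slice order — the pipeline is deterministic end to end and reruns are
  byte-identical (asserted on uncompressed NIfTI bytes).
* Problem sizes in the tests: most unit tests run a 600×400 px frame
  (0.25 mm pixels); the end-to-end checks use the default 1500×1000 frame
  with n = 10–20 slices, the scale at which the full suite completes in a
  few minutes on one CPU.

## Known limitations

* Exactly four markers, one per quadrant; elliptical marker fitting and
  learning-based detection are out of scope.
* Rigid/similarity registration only — no deformable registration, and no
  section-to-blockface histology registration.
* The brightness-transfer source statistics use the whole frame, not a
  specimen mask; with a large specimen/paraffin ratio change along the
  stack this can under-correct.
* Visualization, vessel segmentation and quantitative territory mapping are
  downstream of this package.
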