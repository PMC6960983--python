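# Methods

## The measurement problem

The thickness of a grain resting on a plane is the dimension perpendicular
to that plane. Stereo reconstruction of the grain's *highest* point is not
possible by classical correspondence matching: grain surfaces are smooth,
texture-poor and mutually similar. `grainstereo` instead reconstructs the
grain's *occluding edge* — the silhouette rim, which both cameras do see —
and converts mean rim height into thickness through a population argument.

## Half-height hypothesis

A grain is modelled as a convex solid whose silhouette rim sits at height
`h` above the plane with one face up and `H − h` with the other, where `H`
is the thickness. Writing `δ = |h − H/2|` for the rim-plane offset of an
asymmetric grain, a fair coin flip over resting faces gives

    E[rim height] = ½h + ½(H − h) = H/2,

so `H_hat = 2 × mean rim height` is unbiased over randomly scattered
grains. The estimator's standard error is `2δ/√n` for `n` grains: the
per-grain asymmetry is the dominant noise source, and it is *statistical*,
not geometric. With the defaults used here (δ = 0.15 mm, n = 20) that
floor is ≈ 0.067 mm per scene — larger than the geometric error of the
pipeline itself (~0.01–0.03 mm, see below). The per-grain mean height is
computed first and then averaged over grains; pooling all edge points
would weight grains by boundary length.

## Camera model and geometry

Pinhole cameras with interior orientation (principal point x0, y0 and
principal distance f, pixels), Brown–Conrady distortion (k1, k2, k3 radial;
p1, p2 tangential; applied to f-normalised coordinates) and exterior
orientation (projection centre Xs, Ys, Zs in mm; Euler angles φ, ω, κ in
radians, rotation `R = R_φ(Y) · R_ω(X) · R_κ(Z)`). Photo coordinates are
principal-point-referenced, x right / y up; raster (row, col) indices are
0-based, top-left origin, with `x = col − W/2 − x0`, `y = −(row − H/2) − y0`.

* **Undistortion** inverts the forward model by fixed-point iteration to a
  forward-reprojection residual < 1e-6 px (cap 50 sweeps). Observed points
  are undistorted before any geometric computation.
* **Space resection** solves the six exterior-orientation unknowns per
  camera by Gauss–Newton on the collinearity residuals of ≥ 4 board control
  points (convergence when the largest update < 1e-8, cap 100 iterations;
  central-difference Jacobian). The default initial guess — nadir attitude,
  (Xs, Ys) at the control centroid, Zs from the object/image extent ratio —
  is adequate for near-nadir rigs. Collinear control (singular normal
  equations) and non-convergence raise distinct errors. Noise-free
  recovery is exact to ~1e-9; with the synthetic board's centroid
  quantisation (~0.02 px) the recovered orientation is within ~0.02 mm.
* **Space intersection** solves each matched point pair as linear least
  squares on the rearranged collinearity equations (4 equations, 3
  unknowns), then applies one Gauss–Newton refinement step and keeps
  whichever solution has the smaller RMS reprojection residual.
  Near-parallel rays (zero baseline) are rejected as degenerate.

## Control points

The board is a grid of circles of known radius and spacing; the upper-left
circle centre is the object-frame origin, X along the long side. Detection
is Otsu thresholding, round-component filtering (eccentricity < 0.6,
solidity > 0.85, area within [0.5, 2]× the median candidate), and an
intensity-weighted sub-pixel centroid over a slightly dilated footprint —
accurate to ≲ 0.05 px on rendered boards and invariant to symmetric blur.
Grid ordering clusters photo-frame y then x by largest gaps; it assumes the
board appears within 45° of upright, tolerates missing (occluded) circles,
and reports ambiguous assignments as errors. Circles partially covered by
grains are simply dropped — resection is overdetermined.

## Segmentation

Graying uses the ITU-R 601 weights; median filtering (default 3×3,
edge-replicated) precedes Otsu binarisation. Connected components are
8-connected; area limits default to [0.2, 3.0]× the median component area
(self-scaling), removing broken kernels and clumped grains — clumps are
removed, not split. Holes are filled; boundaries come from Moore-neighbour
tracing, oriented counter-clockwise in the photo frame; centroids are
unweighted means of member pixels (matching operates on the binary mask).
Board-circle components are masked out of grain candidates, and components
touching the image border (truncated silhouettes) are dropped.

## Edge correspondence

Each boundary is described by its polar-distance signature: distances from
the centroid to the boundary, resampled by linear interpolation at 1°
steps (360 samples, polar axis +x, counter-clockwise; at a multiply-crossed
angle the outermost crossing wins; an angular gap > 20° is pathological).
Grain-level pairing projects each right-image centroid through the board
plane into the left image and takes the nearest left centroid (greedy
one-to-one, default gate of half the minimum left inter-centroid distance).
Edge-level pairing maximises the Pearson correlation between the left
signature and the right signature over all 360 circular shifts, evaluated
in one FFT pass; shift k pairs left angle i with right angle (i+k) mod 360.

An elongated elliptical silhouette is nearly 2-fold symmetric, so shifts k
and k+180 are near-tied in correlation and image noise can select the
wrong one — which pairs opposite rim points and ruins the heights. The
pipeline therefore collects all correlation peaks within 0.02 of the
maximum and keeps the candidate whose intersected points have the smallest
mean reprojection residual: a texture-free, stereo-consistency tie-break.
Zero-variance signatures (perfect circles) are flagged degenerate and
skipped.

## Synthetic scenes

The generator emulates the measurement setup: a 4×6 circle grid (16 mm
spacing, 2.5 mm radius), two nadir cameras 350 mm above the board with an
80 mm baseline (base-height ratio ≈ 0.23, inside the accuracy window for
low-relief scenes) and 0.1 mm/px image scale; image size is computed so
both cameras cover the board plus margin (1760 × 640 px at defaults).
Grains have semi-axes a ≈ 3.5 mm, b ≈ 1.1 mm (elongation ≥ 2, with small
uniform jitter), thickness H = 1.8 mm and rim offset δ = 0.15 mm —
plausible values for medium rice kernels; δ is deliberately generous, and
is swept in tests rather than asserted. Placement is rejection-sampled so
silhouettes clear each other and the circles; flips are fair Bernoulli.

The rim is rendered as the planar ellipse at the grain's rim height,
projected exactly through each camera and filled with 3×3 sub-pixel
coverage anti-aliasing, followed by Gaussian blur (σ = 0.5 px) and additive
gray noise (σ = 2 levels). Modelling the silhouette by its rim curve keeps
the ground truth analytic; it ignores full-3D self-occlusion, which is a
small effect for near-nadir cameras and short baselines.

`rim_inset_px` emulates the under-segmentation of translucent grain edges
seen on real imagery: the contour is inset in planform and lifted onto the
grain's upper surface (a half-ellipsoid cap with vertical semi-axis
H − rim height), which rises toward the interior. Because both views then
observe a genuinely higher 3D curve, the measured thickness increases —
reproducing the sign of the bias reported on real grains. Plain
image-space erosion of a planar rim would *not* produce this bias: equal
radial erosion in both views shifts both rays to the same displaced object
point on the rim plane and leaves the reconstructed height unchanged.

What passing synthetic tests do **not** show: robustness to real-world
illumination gradients, shadows, translucency, touching grains, or
texture; those enter only through the noise, blur and inset knobs.

## Numerical choices and edge cases

* Correlation ties are broken toward the smallest shift (deterministic).
* Negative reconstructed heights are kept, keeping the noise distribution
  unbiased; an optional reprojection-residual cap (off by default) can
  drop grossly mismatched pairs.
* Digital boundaries: an 8-connected digital circle of radius 20 px has
  inner-corner boundary pixels up to ~1 px inside the nominal radius;
  polar signatures inherit that quantisation, which averages out over a
  grain's 360 samples but leaves ~0.05 mm of per-grain height noise — a
  single grain therefore measures noticeably worse than a population.
* Determinism: identical inputs and seeds give byte-identical scenes,
  renders and reports.

## Problem sizes used in the test suite

Synthetic studies run at desk scale: 8–20 grains per scene, 1760 × 640 px
images, 50 scenes for the accuracy study, 12 replicates per point for the
sample-size sweep (n ∈ {2, 5, 10, 20}). At these sizes the full suite and
the acceptance script each complete in a few minutes on one CPU.

## Known limitations

* The half-height argument is population-level; per-grain thickness from a
  single asymmetric grain is biased by ±2δ by construction.
* Epipolar geometry is not used to constrain matching (shape signatures
  plus stereo-consistency disambiguation suffice here); it would be the
  natural next step for speed and robustness.
* Interior orientation and distortion are inputs (from any standard
  single-plane checkerboard calibration); the package does not solve
  self-calibration.
* Touching grains are removed by the area filter rather than split by
  watershed; heavily occluded boards (fewer than 4 visible circles) cannot
  be oriented.
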