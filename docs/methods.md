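# Methods

`craniosex` estimates the sex of a skull from two quantified cranial
regions: the supraorbital margin (the upper rim of the eye socket, classically
"blunt thick" in males and knife-edge sharp in females) and the frontal
sagittal arc (the midline forehead profile, more inclined in males, with a
more prominent frontal eminence in females).  This note records the model,
the tunable parameters, the synthetic-data design, and the numerical
choices a maintainer would want to know.

## 1. Supraorbital-margin texture

The margin is represented as a height map f(x, y) on a regular grid
(`SurfaceHeightMap`).  Its gradient field is estimated by a continuous
wavelet transform

    W_psi(b, a) = (1/a) ∫ psi((x − b)/a) f(x) dx ,

with the two mother wavelets psi_x = ∂phi/∂x and psi_y = ∂phi/∂y of the
2D Gaussian phi = exp(−‖x‖²/2), giving ∇W = (W_psi_x, W_psi_y).  Notes:

* **Normalization** is 1/a (not the more common 1/a² 2D convention) — kept
  deliberately to match the transform definition the feature was designed
  around.  Since downstream thresholds act on orientations and relative
  magnitudes, the choice only rescales ∇W globally.
* **Discretization.** The kernels (1/a)·psi((·)/a) are sampled on the grid
  with the pixel-area quadrature weight and correlated with f using
  reflected boundaries.  Support is truncated at 7 dilation lengths; on
  smooth inputs the result then matches direct quadrature of the defining
  integral to better than 1e−6 (asserted in the tests).  A kernel wider
  than the grid raises `ScaleError`, as does a scale below half a pixel
  (unresolvable).
* **Scale units.** The published optimum scale 0.00005 is quoted in the
  capture software's coordinate units, which are not recoverable.  The
  package therefore gives every height map a physical `spacing` per pixel,
  default 2.5e−5, under which the canonical scale a = 5e−5 spans 2 pixels.
  The parameter-sweep list `DEFAULT_SCALES` (2.5e−5 … 4e−4) covers 1 to 16
  pixels at that spacing.

The texture is the Shannon entropy of the gradient orientation
distribution: per pixel, orientations theta = atan2(W_psi_y, W_psi_x) of the
surrounding window are histogrammed into B equal bins over [−pi, pi),
normalized to rho, and E = −Σ rho ln rho (natural log; bounds 0 ≤ E ≤ ln B).
Defaults: window 5, B = 36 (10° bins).  Entries with gradient magnitude
below `mag_floor` are dropped; windows with no qualifying entry get E = 0.
The default floor is **5% of the maximum gradient magnitude**.  A
near-zero floor is unusable in practice: any observation noise fills flat
regions with uniformly random orientations, saturating the entropy there
and flooding the subsequent segmentation, while a 5% relative floor
removes noise-dominated pixels and keeps the deterministic valley texture.
The floor is exposed in `MarginConfig` for other data regimes.

Orientation entropy is translation-invariant (up to borders) and exactly
invariant under 90° grid rotations when B is a multiple of 4 — both are
asserted as tests.

**Valley segmentation.** The "surface height value" is measured as depth
below the least-squares reference plane of the height map (plane − z,
positive below).  A pixel joins the valley mask when depth ≤ th *and*
E ≥ te; defaults th = 2 voxels, te = 0.8, the optimum of the original
parameter study.  The direction of the two inequalities makes the mask
grow with th and shrink with te (a monotonicity the tests assert).  Two
features summarize the mask: **area** (pixel count) and **thickness**, the
number of binary erosions with a 3×3 square structuring element needed to
empty the mask (a solid 7×7 square has thickness 4).  The 3×3 square is
chosen over the cross because it reproduces that worked value.

## 2. Frontal-arc Fourier descriptors

The frontal profile enters as ≥ 8 ordered 3D landmarks with strictly
increasing x (18 by convention).  The chain is:

1. degree-6 least-squares polynomial fit of y on x, after mapping x to
   [−1, 1] for conditioning; a Levenberg–Marquardt pass on the same
   residual refines the fit (for this linear model it confirms the
   optimum; the refined residual never exceeds the linear one).
   Coefficients are reported in both the normalized and the raw x basis;
2. projection to the XY plane (z is dropped);
3. evaluation at 32 uniform half-open grid points x_m = x_min + m·Δ/32,
   m = 0…31 — half-open so the index set matches the 32-point expansion;
4. the trigonometric expansion A0 = (1/32)ΣY_m,
   A_k = (1/16)ΣY_m cos(2πkm/32), B_k = (1/16)ΣY_m sin(2πkm/32), k = 1…16,
   P_k = √(A_k² + B_k²), and the size-free amplitudes P′_k = P_k·100/A0.

Scaling the whole curve scales every P_k and A0 by the same factor, so P′
is invariant to skull size — asserted as a property test.  The Nyquist
term k = 16 is computed with the same 1/16 weight as the other harmonics;
the inverse transform therefore applies the compensating ½ factor, making
forward-then-inverse exact to 1e−9 on any 32-vector.  A0 = 0 leaves P′
undefined (`NormalizationError`); P is still reported.

## 3. Classifier

Fused features are the 18-vector [area, thickness, P′₁…P′₁₆].  Because raw
areas (10²–10³) would swamp the P′ values inside an isotropic RBF
distance, features are z-scored with training-set statistics only;
constant features pass through with a warning.

The soft-margin dual

    max_α Σα_i − ½ ΣΣ y_i y_j α_i α_j k(x_i, x_j),
    0 ≤ α_i ≤ C,  Σ α_i y_i = 0,

with RBF kernel k(x, x′) = exp(−‖x − x′‖²/δ²) (the exponent is negative; a
positive exponent would not be a kernel), is solved by maximal-violating-
pair SMO: pairwise coordinate steps along directions that keep Σα_i y_i = 0
exact, clipped to the box, until the KKT gap falls below tol (1e−3 by
default).  The bias is the mean of y_k − f_k over free support vectors, or
the midpoint of the KKT interval when none is free.  The solver is checked
in the tests against a brute-force SLSQP quadratic program on small
instances (agreement 1e−4) and against libsvm via scikit-learn on larger
ones; predictions are sign(f), exact ties reported as +1 with a flag.

Hyperparameters (C, δ) are chosen by stratified 5-fold cross-validated
accuracy over the log₂ grids 2⁻⁵ ≤ C ≤ 2¹⁵ and 2⁻¹⁵ ≤ δ ≤ 2⁵ with exponent
step 0.5 (41 × 41 cells); accuracy ties break toward smaller C, then
smaller δ.  Cross-validation is used because the original description does
not say how "accuracy rate" was measured during the search; CV is the
standard choice that avoids consuming the test set.  Grid fits run with a
3000-iteration budget — the optimum cells converge in a few hundred
iterations; pathological corners (huge C with near-singular kernels) are
scored with their current iterate rather than aborting the search.

Evaluation uses a per-class 70/30 stratified split with round-half-up
allocation: 73 males and 60 females give 51 + 42 = 93 training and
22 + 18 = 40 test samples.  Reports carry per-class tested/correct/
misjudged counts and the correct rate correct/tested × 100 rounded to one
decimal (20/22 → 90.9, 17/18 → 94.4).

**On monotonicity in C.** The quantity guaranteed monotone in C at the
optimum is the total hinge slack Σξ_i, and the tests assert exactly that;
the 0–1 training-error count is only heuristically decreasing (hinge and
0–1 losses can disagree by a point or two on overlapping data), so it is
asserted on near-separable data where the heuristic is exact.

## 4. Synthetic dimorphic-skull generator

Reference CT collections of sexed skulls are available only on
application, so the generator emulates the two regions with closed-form
templates plus i.i.d. Gaussian observation noise.  Both templates are
exact at noise_sd = 0, which the zero-noise tests exploit.

**Margin template** (64 × 64 default):

    z = −d·box(y) + 0.15·box(y)·sin(2πx/8)·sin(2πy/8)

where box(y) is a flat-bottomed groove with logistic walls of steepness
s = `edge_sharpness` (1/voxel), centred on the grid with half-width
w = 0.14·rows/s, and d = `valley_depth` (voxels).  Design intent:

* wall steepness encodes sharp-vs-blunt: max curvature across the edge
  grows as d·s²/(6√3), strictly monotone in s (the invariant is measured
  on an oversampled template, since the integer grid aliases once the wall
  is sub-pixel; the pixel-level finite-difference contrast between s = 1
  and s = 4 is also asserted);
* groove width shrinks as 1/s — a knife-edge margin is proportionally
  narrow — which is what makes male masks larger in area *and* thickness;
* the in-groove corrugation (amplitude 0.15 voxels, wavelength 8 voxels)
  gives the groove floor the directionally disordered gradient field that
  real bone texture shows, so the entropy criterion selects exactly the
  groove band.  Amplitude is kept small enough that the wall term
  dominates the curvature summary at all realistic s ≥ 0.5.

Defaults: male s = 1.0, d = 1.8; female s = 3.0, d = 1.2; noise_sd 0.03.
With these, zero-noise features are (area, thickness) ≈ (667, 4) male vs
(244, 2) female, and the ordering is stable under the default noise.

**Frontal template** on x ∈ [0, 1]:

    y = −10 + σ(6(x − 0.35)) − 3·tan(`forehead_slope`)·x
        + `eminence_amplitude`·exp(−(x − 0.55)²/(2·0.12²))

a tilted logistic forehead arc plus a Gaussian eminence bump; the −10
baseline keeps A0 well away from 0 so the P′ normalization is stable, as
for real profile coordinates.  Defaults: male slope 0.35 rad, eminence
0.3; female slope 0.15 rad, eminence 1.0.  Landmarks are n equally spaced
stations on x (18 by default); noise is applied to y and z only — the
calibration stations are fixed along the arc — because unbounded Gaussian
x-noise would violate the strict x-monotonicity the downstream fit
requires.  Per-individual seeds derive from the master seed through
`numpy.random.SeedSequence`, so populations are exactly reproducible.

**What the generator does not model:** anatomically realistic skull
geometry, spatially correlated scanner noise, mesh holes, asymmetry, age
structure, or population variation beyond the two parameter presets.
Passing tests therefore demonstrate that the feature chain measures what
it claims on surfaces with the documented dimorphism — not field
performance on real CT data, which requires access to a real collection
through the `read_obj_heightmap` / CSV entry path.

## 5. Pipeline, sizes and determinism

`run_pipeline` chains synthesis (or a manifest of real files) → median
denoising (window 3) → margin features → frontal features → fusion →
split → standardization → grid search → evaluation, and aborts naming the
failing stage.  Outputs carry a SHA-256 config hash; a rerun with the same
config and seed is byte-identical.

Default experiment sizes keep a full run light: a 133-skull population
(73/60, the study composition) with the complete 41 × 41 × 5-fold search
runs in about half a minute on one core; the acceptance harness uses the
same sizes.  The OBJ path renders meshes by orthographic frontal
projection (x right, y up, z toward viewer), taking the nearest-surface
depth per cell and inpainting uncovered cells by nearest neighbor — a
deliberate, documented stand-in for the original interactive screenshot
capture, whose geometry is not recoverable.

## 6. Known limitations

* The absolute wavelet-scale convention is a package-defined mapping
  (spacing 2.5e−5 per pixel); analyses of real height maps should set
  `spacing` from their own capture geometry.
* FCM segmentation and Canny contours are provided for the real-image
  entry path and are exercised on synthetic imagery only.
* The printed training allocation "(51 males and 40 females)" of the
  70/30 split is arithmetically inconsistent with its own totals
  (40 + 18 ≠ 60); the package reproduces every consistent count
  (93/40 split; 51 M train; 22 M / 18 F test) with 42 female training
  samples.
* Grid-search accuracy surfaces at extreme (C, δ) corners may come from
  iteration-capped fits; the reported optimum is unaffected in all tested
  regimes.
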