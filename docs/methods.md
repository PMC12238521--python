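# Methods

## Imaging model

The package uses the standard pinhole decomposition: world → camera
(`p_c = R p + t`, lengths in mm), camera → metric image plane at focal
distance `f` (perspective divide and scale), metric → pixel through the
upper-triangular intrinsic matrix

```
A = [ f/dx   γ    u0 ]
    [  0    f/dy  v0 ]
    [  0     0     1 ]
```

Pixels are 0-based, x right, y down, origin at the top-left corner; the
principal point lives in the same frame. Lens distortion is the 2-term
radial model applied in metric coordinates, `x_d = x(1 + k1 r² + k2 r⁴)`
with `r` in mm (so k1 is mm⁻², k2 mm⁻⁴), defaulting to zero; undistortion
is a fixed-point iteration capped at 20 steps and verified by re-distorting
(round-trip better than 1e-9 px on any plausible sensor). The skew γ is
carried through the whole chain but defaults to 0 — it is part of the
calibration state, not something the rest of the pipeline relies on.

## Flat-port refraction

A ray from an underwater point crosses the window glass twice:
water → glass and glass → air, with Snell's law
`n_r sin α = n_g sin α_g = n_a sin α_air` linking the three segment angles.
With the window parallel to the sensor and the port standoff `d` measured
from the camera's external focal point, the underwater and equivalent-air
image coordinates are both parameterised by the water-side incidence α:

```
x_r(α) = T·tan(arcsin(n_r sin α / n_g)) + (d−T)·tan(arcsin(n_r sin α / n_a))
x_a(α) = T·tan(arcsin(n_a sin α / n_g)) + (d−T)·tan α
```

Placing the interface at the external focal point (`d = f`, the package
default) is what makes this map depth-independent, so a single underwater
image can be converted to its equivalent air image without knowing the
target range. Both equations are strictly increasing in α on
`[0, arcsin(n_a/n_r))`, so each direction of the conversion is a bracketed
1-D root solve: Brent's method on α with xtol 1e-14, the bracket kept 1e-9
rad clear of the critical angle. Round-trip error is ~1e-14 mm in practice;
the contract is 1e-9 mm. Coordinates demanding incidence beyond the
critical angle raise a total-internal-reflection error; at the reference
constants (d = 3, T = 2.8, n = 1/1.6/1.33) the valid air-side field ends at
x_a ≈ 1.72 mm, comfortably outside the fish-keypoint regime but inside the
far corners of a wide sensor — keypoint-level application therefore flags
such points invisible rather than failing the whole view.

Three model variants:

* **single** — the glass slab ignored, one water/air interface; closed form
  `x_a = d·tan(arcsin(n_a sin(arctan(x_r/d))/n_r))`.
* **parallel** — the pair above; the default. With glass ~3 mm thick, i.e.
  comparable to the focal length, the secondary refraction is not
  negligible: the single-interface model over-magnifies increasingly with
  incidence, the parallel model sits strictly below it across the whole
  valid field (both magnification curves grow monotonically — refractive
  pincushion — but accounting for the slab flattens the curve).
* **tilted** — the window at angle β to the sensor plane, derived along the
  tilt direction:

  ```
  x_r(α) = T·[tan(arcsin(n_r sin α / n_g)) − tan β]
           + (d − T/cos β)·tan(arcsin(n_r sin α / n_a) − β)
  x_a(α) = T·[tan(arcsin(n_a sin α / n_g)) − tan β]
           + (d − T/cos β)·tan(α − β)
  ```

  This is a 1-D construction and is exact only in the tilt plane; the
  package applies it along the image x-axis and treats the orthogonal axis
  as a parallel system. Note the tilted maps are **not** odd functions for
  β > 0 (the `tan(α−β)` term breaks the symmetry), so the solver works on
  the signed incidence angle; at β = 0 the formulas collapse to the
  parallel pair exactly (to 1e-12 in the tests). Geometry requires
  `d > T/cos β`; violating it raises a port-geometry error. Installation
  tilts are small in practice, which is why `parallel` is the default.

Keypoint correction is **coordinate-level**, not a dense image remap: each
visible keypoint is lifted to metric coordinates, the 1-D map is applied to
its radial distance from the principal axis (azimuth preserved — the
parallel/single systems are rotationally symmetric), and the result is
mapped back to pixels. With the port at the focal point, metric image
coordinates coincide with the model's interface-plane coordinates, so no
extra scaling is involved.

## Calibration

Zhang's planar method, linear closed form only (no bundle adjustment):
Hartley-normalised DLT homographies per checkerboard view, the two
absolute-conic constraints per view stacked and solved by SVD, intrinsics
extracted in closed form, per-view pose from `r1 = A⁻¹h1/‖A⁻¹h1‖` with the
rotation projected to the nearest orthonormal matrix by SVD and the sign
fixed so the target sits in front of the camera. Fewer than three views,
repeated poses (rank-deficient constraints) and an indefinite conic are
reported as distinct errors. Only the matrix A is identifiable from
homographies; factoring it into (f, dx, dy) requires an assumed focal
length (default 1 mm), which affects nothing downstream — all projections
depend on A only. On noiseless synthetic views recovery is ~1e-13 relative;
with 0.5 px corner noise the per-component RMS reprojection residual sits
near 0.5 px, slightly above the noise floor because the linear solution is
not the maximum-likelihood refinement.

## Triangulation and length

Each keypoint pair gives four linear equations in (X, Y, Z) obtained by
eliminating the projective depths from the two projection equations; the
4×3 system is solved by `numpy.linalg.lstsq` (orthogonal factorisation —
no normal equations, for conditioning). Rays parallel within 1e-8 rad are
rejected as degenerate. An independent two-ray midpoint closed form (used
only in tests and the acceptance script) agrees to 1e-9 mm on noiseless
input. When intrinsics carry distortion, pixels are undistorted to ideal
pinhole coordinates before entering the linear system.

Body length is the 3D Euclidean distance from the mouth landmark to a tail
reference point. The schema defines two tail-fin landmarks and no single
"tail" point, so the default `tail_rule` is the midpoint of the two fins
(selectable to either fin); when only one fin is jointly visible the
midpoint rule degrades to that fin. Error statistics: per-fish relative
error `RE = |L_t − L_a|/L_a·100%` and its arithmetic mean MRPE.

## Keypoint schema and metrics

Nine landmarks in fixed order (mouth, eye, dorsal_fin1/2, tail_fin1/2,
anal_fin, top_fin, pelvic_fin), binary visibility. The COCO-dialect reader
accepts the standard three-state visibility, mapping 2 → 1; the writer
emits {0, 1}. NME is the mean pixel error over jointly visible keypoints
divided by a normaliser, taken here as the fish bounding-box diagonal (the
only box available for fish). AP uses greedy IoU matching (ties by highest
IoU, then earliest prediction) and all-point precision–recall integration
over the 0.50:0.05:0.95 threshold sweep; an image set with no ground truth
yields a null AP rather than a number.

## Synthetic scenes

The simulator is the oracle for every stage, so its defaults *are* the
study conditions: fish lengths 80–105 mm placed at 300–700 mm range
(nominally 500 mm — a tank-scale working distance), f = 3 mm lens, 2.8 mm
glass, indices 1.0/1.6/1.33, port at the focal point. The stereo baseline
(60 mm, parallel optical axes) and the sensor (1280×720, 3 µm pitch,
centred principal point) are package assumptions; the sensor was sized so
the whole fish regime, including the ~1.33× underwater radial
magnification, stays inside both frames.

Fish geometry is a fixed 9-landmark template scaled so the mouth-to-tail
chord equals the requested length exactly; interior landmarks get seeded
uniform shape jitter up to 2% of the length, the two tail fins get mirrored
jitter (preserving their midpoint, hence the nominal length), and a `bend`
parameter bows the interior landmarks laterally without moving the chord
endpoints. Poses keep fish roughly broadside (|yaw| ≤ 25°, small
pitch/roll) — the regime in which a two-endpoint length is meaningful.

Rendering produces, per view, the equivalent-air pinhole projection and the
underwater observation (forward flat-port map applied radially, then
N(0, σ²) pixel noise, σ = 0.5 px by default — a plausible keypoint-detector
jitter; the noise model is a knob, not a claim). Out-of-frame and beyond-TIR
landmarks are flagged invisible. One integer seed drives a top-level
`SeedSequence`; all sub-draws derive from it, and noise variates are drawn
even at σ = 0 so visibility and coordinates are reproducible bit-for-bit
across noise settings of the same seed.

What passing synthetic tests does **not** show: detector errors on real
imagery are neither Gaussian nor isotropic, real fish bend more than the
template, enclosure geometry (d, T, β) is never known exactly, and water
turbidity or wavelength-dependence of the indices are not modelled. The
synthetic results bound the geometric pipeline's error, not a field
system's.

## Problem sizes in the checks

The acceptance script and test suite size their Monte-Carlo runs as: 10⁴
round-trip points per refraction model, 10³ triangulated points, 100
noiseless end-to-end scenes, and 100 noisy repeats of a 13-fish measurement
group (13 fish being the measurement-campaign group size the default scene
emulates). These sizes give stable statistics while keeping a full run in
seconds.

## Known limitations

* The tilted model is separable (tilt axis × parallel axis), exact only for
  points on the tilt plane's axes.
* No nonlinear calibration refinement; with noisy corners the closed-form
  intrinsics are slightly biased.
* Straight-chord length only — no centerline/medial-axis length for
  strongly curved fish.
* One glass slab; dome ports, multi-layer windows and dispersion are out of
  scope.
* Keypoint pairing across views is by annotation id, not epipolar matching;
  multi-fish association is the caller's job.
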