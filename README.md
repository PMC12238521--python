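# fishstereo

Non-contact measurement of fish body length from a binocular camera in a
flat-port waterproof housing. Aimed at aquaculture monitoring, where
netting and anaesthetising fish to measure them is slow, stressful and
error-prone: a stereo pair filmed through the tank wall or a housing window
can do the job — *if* the refraction of light at the water → glass → air
interfaces is corrected before triangulating.

`fishstereo` implements that correction and everything around it:

* **Flat-port refraction models.** A camera behind a plane-parallel window
  sees each point displaced radially outward (refractive pincushion). For a
  port placed at the external focal point (standoff `d` = focal length `f`),
  the underwater image coordinate `x_r` and the equivalent-air coordinate
  `x_a` are tied together by the water-side incidence angle α:

  ```
  x_r(α) = T·tan(arcsin(n_r·sin α / n_g)) + (d−T)·tan(arcsin(n_r·sin α / n_a))
  x_a(α) = T·tan(arcsin(n_a·sin α / n_g)) + (d−T)·tan α
  ```

  with glass thickness `T` and refractive indices `n_a/n_g/n_r`
  (air/glass/water). Inverting either equation for α (bracketed root
  finding; both are strictly monotone below the total-internal-reflection
  bound `arcsin(n_a/n_r)`) gives an exact pixel-level map between the
  underwater image and the image an in-air camera would have formed.
  A single-interface model (glass ignored, closed form) and a tilted-window
  model (window at angle β to the sensor) are also provided; the tilted
  model reduces to the parallel one at β = 0 and the parallel one to the
  single-interface model at T = 0.
* **Stereo measurement.** Corrected keypoints from both views are
  triangulated by least squares from the stacked linear system of the two
  projection matrices `M = A[R|t]`, and the body length is the Euclidean
  distance `L = √((X_H−X_T)² + (Y_H−Y_T)² + (Z_H−Z_T)²)` between the mouth
  point and the tail point (midpoint of the two tail-fin landmarks by
  default). Accuracy is reported as per-fish relative error
  `RE = |L_t − L_a|/L_a·100%` and its mean over fish (MRPE).
* **Zhang planar calibration** from checkerboard corner correspondences
  (normalised DLT homographies, closed-form intrinsics from the
  absolute-conic constraints, per-view poses, reprojection report).
* **A 9-keypoint fish schema** (mouth, eye, dorsal fin ends, tail fin
  top/bottom, anal/top/pelvic fins) with COCO-dialect JSON I/O and the
  usual evaluation metrics (NME normalised by the bounding-box diagonal,
  AP over an IoU-threshold sweep).
* **A synthetic scene simulator** — parameterised 3D fish, a default rig
  (f = 3 mm, T = 2.8 mm, n = 1/1.6/1.33, 60 mm baseline, fish of 80–105 mm
  at 300–700 mm) and the forward refraction map — which provides exact
  ground truth for every stage.

## Worked example

Simulate a noise-free scene, measure it, and compare against ground truth:

```
$ fishstereo simulate --seed 7 --n-fish 3 --noise-sigma 0 --out scene/
simulated 3 fish (seed=7, sigma=0.0 px) -> scene

$ fishstereo measure --rig scene/rig.yaml --left scene/left.json \
    --right scene/right.json --truth scene/truth.csv \
    --out meas.csv --stats stats.json
measured 3 fish -> meas.csv
MRPE = 0.0000% over 3 fish
```

`meas.csv` holds one row per fish with the body length and the triangulated
(X, Y, Z) of every landmark; with exact keypoints the measured lengths equal
the simulated truth to machine precision, hence the 0.0000% MRPE. Re-running
with `--model none` (no refraction correction) on the same files prints
`MRPE = 3.3410%` — the systematic error a naive underwater triangulation
commits at this geometry. The same comparison under 0.5 px keypoint noise is
what separates the corrected (≈0.6% MRPE) from the uncorrected (≈1.7%)
pipeline in the acceptance run below.

From Python the same pipeline is three calls:

```python
from fishstereo import RefractionModel, measure_fish, random_scene

scene = random_scene(seed=7, n_fish=1)
m = measure_fish(scene.observations["left"][0], scene.observations["right"][0],
                 scene.rig, model=RefractionModel.PARALLEL)
print(m.length_mm, scene.fish[0].length_mm)
```

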