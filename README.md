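# gridwarp

Geometric-distortion quality assurance for volumetric scanners with a 3D
grid phantom.

MR images are geometrically distorted by main-field inhomogeneity and
gradient-coil nonlinearity. For stereotactic and surgical planning these
distortions must be measured routinely and kept at the sub-millimeter
scale. `gridwarp` measures them from images of a simple grid phantom — a
lattice of 3 mm bars with vertices every 15 mm — given one geometrically
accurate reference volume (CT-like) and one or more distorted acquisitions
(MR-like), by two independent routes:

* **Template matching** — the grid vertices (control points, CPs) are
  localized in each volume by normalized cross-correlation with a 7.5 mm
  binary junction template, reduced to sub-voxel centers of mass, and
  paired across volumes; pair displacements are the distortion.
* **Nonrigid registration** — the reference volume is registered onto the
  distorted volume with a cubic B-spline free-form deformation
  `T(x) = x + Σ_ijk c_ijk β³((x − x_ijk)/h)`, optimized by adaptive
  stochastic gradient descent over a multiresolution pyramid (metric: mean
  squares or Mattes mutual information); the transform applied to the
  reference CPs yields the distortion at every landmark, and a dense
  displacement field everywhere else.

Displacement-magnitude distributions are summarized (max, mean, median,
quartiles), compared between methods under the half-pixel rule (differences
below half an image pixel are non-significant), profiled against distance
from the isocenter, and classified: max < 1 mm ⇒ high-performing,
max ≤ 2 mm ⇒ within the ±2 mm accreditation bound. Cell midpoints (centers
of 8 neighboring CPs) act as an overfitting diagnostic for the
registration. Because no public phantom datasets exist, the package ships a
first-class synthetic module: phantom geometry, two-contrast voxelization,
smooth analytic distortion fields, and seeded warping — every pipeline
claim is validated against analytically known ground truth.

## Worked example

```python
import numpy as np
from gridwarp import (build_grid_geometry, random_smooth_field, simulate_pair,
                      RegistrationParams, bspline_register,
                      stats_from_magnitudes, classify_performance)

geometry = build_grid_geometry(15.0, 3.0, (60.0, 60.0, 60.0))   # 125 CPs
field = random_smooth_field(seed=11, max_magnitude=2.0, domain_radius=52.0)
reference, observed = simulate_pair(geometry, field, voxel_spacing=1.0, seed=7)

transform = bspline_register(reference, observed,
                             RegistrationParams(fgs=30, nr=3, nss=3000, mni=500, seed=1))
measured = np.linalg.norm(transform.apply(geometry.vertices) - geometry.vertices, axis=1)
stats = stats_from_magnitudes(measured)
print(f"measured distortion: mean {stats.mean:.3f} mm, max {stats.max:.3f} mm")
print(classify_performance(stats))

true = geometry.vertices + field(geometry.vertices)
rmse = np.sqrt(((transform.apply(geometry.vertices) - true) ** 2).sum(1).mean())
print(f"vector RMSE vs analytic field: {rmse:.3f} mm")
```

prints

```
measured distortion: mean 0.921 mm, max 1.755 mm
{'max_mm': 1.7552060987838618, 'high_performing': False, 'acr_pass': True}
vector RMSE vs analytic field: 0.029 mm
```

The registration measures a 2 mm-peak distortion field with ~0.03 mm vector
accuracy at 1 mm voxels; the acquisition is (correctly) not sub-millimeter
but inside the ±2 mm accreditation bound. The `examples/` scripts walk
through each capability (simulation, detection, registration, parameter
sweep, full validation study), and the `gridwarp` CLI exposes the same
stages (`simulate`, `detect`, `register`, `analyze`, `sweep`, `qa`,
`validate`) for file-based use.

## Registration parameters

Four parameters govern the nonrigid stage and are tuned by a sequential
sweep (`gridwarp.sweep`): final grid spacing FGS (default 30 mm), number of
resolutions NR (3), spatial samples per iteration NSS (3000), and the
iteration cap MNI (500). FGS is the one that matters: below the 15 mm
vertex spacing the spline overfits between landmarks, which the midpoint
diagnostic exposes.

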