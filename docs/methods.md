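# Methods

## Problem and approach

MR images carry system-related geometric distortions (main-field
inhomogeneity, gradient-coil nonlinearity) that matter wherever
sub-millimeter spatial fidelity is required, e.g. stereotactic planning.
`gridwarp` measures those distortions from images of a 3D grid phantom:
a cubic lattice of solid bars (default 15 mm vertex spacing, 3 mm bar
thickness) immersed in a signal-producing medium. The lattice vertices are
the control points (CPs). Two independent measurement routes are
implemented:

1. **Template matching.** A binary template of a bar junction (default
   7.5 mm cube) is correlated over the volume (zero-normalized cross
   correlation). Suprathreshold blobs are reduced to correlation-weighted
   centers of mass; observed points are paired to reference points by
   greedy mutual-nearest-neighbor matching. The pair displacements are the
   distortion measurements.
2. **Nonrigid registration.** The geometrically accurate reference volume
   is registered onto the distorted volume with a cubic B-spline free-form
   deformation; the transform, which maps reference coordinates to observed
   coordinates, is applied to the reference CPs.

Agreement between the two routes — no summary statistic (max, mean,
median, Q1, Q3) differing by half an image pixel or more — is the
validation criterion, and the registration route then serves as the
routine QA tool.

## Coordinate conventions

All computation happens in a right-handed world frame in mm with the origin
at the phantom grid centroid ("isocenter"). Voxel (i, j, k) of a volume is
centered at `origin + (i, j, k) * spacing`; voxel indices appear only at
the NIfTI boundary. The recovered B-spline transform maps reference
(domain) coordinates to observed (target) coordinates, so it applies
directly to reference CPs.

## Synthetic acquisitions

No deposited image data exist for this problem class, so validation uses
simulated acquisitions with analytically known ground truth.

* **Geometry.** The maximal lattice centered in a given extent box;
  optional cylindrical trim (keep a vertex iff its radial distance from the
  height axis is at most `container_inner_radius − bar/2`). For the
  full-size phantom (120 × 150 × 150 mm, trim radius 75 mm) this realizes
  621 vertices and 416 cells; the exact assembly of a physical phantom may
  differ slightly, so the manifest records the realized counts.
* **Contrast.** Observed (MR-like): background 1000, grid 50 — a hyposignal
  grid in oil. Reference (CT-like): background −100, grid +120. Only the
  relative contrast matters; every operator is contrast- or
  polarity-parameterized.
* **Rendering.** A voxel takes grid intensity iff its center lies within
  `bar/2` of a bar axis in the Chebyshev (slab) sense. Voxel centers are
  placed half a voxel off the lattice planes so that bar surfaces fall
  between samples; this makes the rendered bar volume unbiased (checked
  against a Monte-Carlo volume oracle to <1%) and avoids voxel centers
  sitting exactly on material boundaries.
* **Distortion fields.** Smooth analytic vector fields, either low-order
  polynomials (random fields are drawn here and rescaled to a prescribed
  peak magnitude, default 2 mm — the scale of uncorrected scanner
  distortions) or radial polynomials `(Σ c_n r^n) r̂` mimicking the
  isocenter-outward growth of gradient nonlinearity. Volumes are warped by
  `T(x) = x + d(x)`: output intensity at x is the input sampled at
  `T⁻¹(x)`, with the inverse found per voxel by fixed-point iteration to a
  0.01 mm residual (linear interpolation by default, cubic optional).
* **Noise.** Additive Gaussian, seeded: sigma 20 on the MR-like volume
  (SNR 50 against the oil background — phantom imaging is high-SNR) and
  sigma 10 on the CT-like volume. A Rician model was considered and
  rejected: at these SNRs the operators are insensitive to the noise model,
  and the Gaussian keeps every stage linear in expectation.

What the simulation does **not** emulate: vendor reconstruction
idiosyncrasies, susceptibility/chemical-shift (patient-induced) effects,
intensity nonuniformity, container walls, and phantom manufacturing error.
Passing tests therefore demonstrate the correctness of the measurement
machinery on ideal smooth distortions, not the full error budget of a
physical QA session.

## Template-matching details

* Correlation is computed only where the template fully fits; the outer
  margin is set to −1.
* Threshold default 0.5 (configurable). Components smaller than 3 voxels
  are dropped; component peaks below threshold + 0.1 (just under a
  boundary junction's response) set a per-point review flag — the
  automated replacement for interactive visual verification.
* Centers of mass are weighted by the raw correlation values above
  threshold (binary COM available).
* **Non-maximum suppression.** On a lattice phantom the correlation also
  responds halfway along each bar (NCC ≈ 0.6 against ≈ 1.0 at an interior
  junction but only ≈ 0.6–0.7 at boundary junctions, where template bars
  extend past the grid). A plain threshold cannot separate these, so
  candidates closer than `min_separation` (default 9 mm ≈ 0.6 × vertex
  spacing) are pruned keeping the highest peak. This is a detection-stage
  choice, not a pairing constraint.
* Known limitation: at grid corners/edges the suprathreshold blob extends
  asymmetrically along the remaining bars, so the blob-averaged COM
  reports the field averaged over the blob rather than at the junction;
  under strongly non-uniform fields the template route underestimates
  corner displacements by up to a few tenths of a mm. The registration
  route does not share this bias, and the discrepancy concentrates at the
  phantom edge — visible in the method comparison as max-statistic
  differences larger than mean/median differences.

## Rigid pre-alignment

Six-parameter (rotations about world axes + translation) optimization,
restricted to voxels inside a 27 mm sphere around the isocenter where
distortions are negligible, so the pose estimate is not biased by them.
Metrics: mean squares (same contrast), an intensity-correlation metric
`1 − |r|` (cross-contrast; exact for any affine intensity relation,
including the inverted grid/background polarity), or histogram mutual
information. Optimization is Powell coarse-to-fine over Gaussian smoothing
levels (σ = 2, 0 voxels), preceded by a translation-only search — the
lattice makes the metric periodic in translation, and settling the shift
before releasing rotations avoids period-hopping — and followed by a
small-step polish. Observed volumes are then resampled onto the reference
grid (linear interpolation, border-median fill).

## Nonrigid registration

The free-form deformation is parameterized by 3-vector displacements on a
regular control lattice, interpolated by tensor-product cubic B-splines
(direct 4×4×4 window evaluation; outside the lattice support the boundary
polynomial pieces are continued, giving a finite, smooth extrapolated
field). Four parameters are exposed, mirroring the standard sweep:

| parameter | meaning | default | range |
|---|---|---|---|
| FGS | control-point spacing at the finest level (mm) | 30 | 5–60 |
| NR  | resolution levels | 3 | 1–6 |
| NSS | random samples per iteration | 3000 | 1000–7000 |
| MNI | iterations per level | 500 | 100–1000 |

Defaults are the sweep optimum (see below). Values outside the ranges are
allowed with a warning.

Per level (coarsest → finest): images are Gaussian-smoothed with
σ = 2^level / 2 voxels; the control spacing is FGS·2^level; the coarser
solution initializes the finer lattice by sampling its displacement at the
new control points and converting values to spline coefficients with a
spline prefilter. Each iteration draws NSS fresh uniform samples (with
sub-voxel jitter) from a mask — by default the minority-intensity (grid)
phase of the reference volume dilated by one bar thickness, which is where
all registration information lives — and takes a stochastic gradient step.

Metrics: mean squares, or a Mattes-style mutual information (32 bins, cubic
B-spline Parzen window on the moving intensity, hard binning on the fixed
intensity) with the standard analytic gradient. MI is the cross-modality
default.

**Step-size control.** Steps follow a decaying gain
`γ_k = a / (A + k + 1)^0.602` with A = 20. The scale `a` is estimated at
the start of every level by probing the gradient response to random
coefficient perturbations of one voxel: probing (rather than using the
gradient at the start point) matters because finer levels begin near their
optimum, where the actual gradient is nearly zero and a gradient-based gain
would explode. A trust region additionally caps any single step at one
voxel of coefficient motion. Bending-energy regularization is available but
defaults to 0. The run is fully deterministic given the seed (one
generator, keyed by seed and level).

## Error measures and QA statistics

* Per-acquisition displacement magnitudes are summarized as max / mean /
  median / Q1 / Q3 (quantiles by linear interpolation between order
  statistics — stated because cross-implementation comparisons differ here),
  with the location of the maximum recorded.
* **Midpoint diagnostic.** True distortions are smooth and nearly linear
  between neighboring vertices, so the centers of 8-vertex cells are
  additional checkpoints that a transform cannot have been fitted to.
  Overfitting (FGS well below the vertex spacing) shows up as midpoint
  error exceeding CP error; at FGS ≥ vertex spacing the two coincide.
* **Half-pixel rule.** Method statistic differences below half the
  observed volume's pixel size are non-significant. "Pixel size" is taken
  as the maximum voxel dimension (the conservative choice where in-plane
  and slice sizes differ).
* **Classification.** Max < 1.0 mm ⇒ high-performing (sub-millimeter);
  max ≤ 2.0 mm ⇒ within the ±2.0 mm accreditation bound. Boundaries:
  exactly 1.0 mm is not sub-millimeter; exactly 2.0 mm still passes.
* **Distance profile.** Per-CP displacement vs distance from the
  isocenter, with 10 mm-bin means for reporting (bin width is a choice;
  nothing downstream depends on it).

## Parameter sweep

Sequential coordinate descent: FGS first (with NR = 4, NSS = 3000,
MNI = 500 as the initial context), then NR, NSS, MNI, each optimum fixed
before the next sweep, and a final FGS re-sweep. "Optimum" is the global
minimum over the tested list, ties to the smaller value. Default grids —
FGS {5, 10, 15, 20, 30, 40, 60} mm, NR {1…6}, NSS {1000, 2000, 3000, 5000,
7000}, MNI {100, 200, 500, 1000} — cover the standard ranges and every
named landmark value. Per-acquisition seeds derive deterministically from
the master seed and acquisition index. On synthetic smooth fields the FGS
error curve is high at 5 mm (overfitting) and flat from 15 mm up, with the
minimum at an intermediate value; this shape, not the exact argmin, is the
tested property.

## Problem sizes used in tests and the acceptance run

Tests and the acceptance script use the standard grid (15 mm / 3 mm) over
a 60 mm cube — 125 vertices and 64 cells, rendered at 1 mm voxels — which
exercises interior, face, edge and corner vertices alike; the rigid
experiments use a 90 mm cube so the 27 mm ROI is strictly interior. The
full-size phantom geometry (1089 vertices untrimmed; 621 with the 75 mm
cylindrical trim) is constructed and checked in the geometry tests, and the
pipeline accepts it unchanged: problem size enters only through the number
of vertices and voxels.

## Numerical choices and degenerate inputs

* Warp inversion: fixed-point, 0.01 mm tolerance, 60-iteration cap;
  non-convergence (expansive or too-large fields) raises a dedicated error.
* NCC of a zero-variance template is rejected; an empty suprathreshold set
  warns and returns an empty set rather than raising.
* Pairing beyond `max_distance` (default half a vertex spacing) reports
  unmatched points instead of failing.
* B-spline lattices need ≥ 4 control points per axis; the registration
  lattice pads the mask bounding box by 2 control points per side.
* Registration with mismatched volume grids, an empty mask, or a
  non-finite metric raises with level/iteration context.
* Tie-breaks: sweep ties go to the smaller parameter value; NMS ties keep
  the earlier (higher-peak) candidate.

## Known limitations

* The bundled registration is a single-threaded stochastic optimizer tuned
  for phantom images; it is not a general-purpose clinical registration
  engine (no diffeomorphic guarantees, no GPU path). A backend seam allows
  substituting an external engine behind the same contract.
* Template-route corner bias (above) bounds the achievable method agreement
  at the phantom edge to a few tenths of a mm under strongly curved fields.
* The synthetic study validates machinery, not scanner physics: absolute
  distortion numbers from real acquisitions additionally include phantom
  manufacturing tolerance and acquisition effects that the simulation does
  not model.
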