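# Methods

`headmorph` personalizes a baseline all-hexahedral head finite-element mesh
to a subject by image registration. This note documents the model, the
conventions, the numerical choices, and what the synthetic validation does
and does not demonstrate.

## Coordinate and field conventions

Voxel indices are 0-based `(i, j, k)`; world coordinates are millimetres via
the NIfTI affine, `x = A[:3,:3] (i,j,k)ᵀ + A[:3,3]`. A displacement field
`u(x)` lives voxelwise on the *fixed* (baseline) grid, in world mm: the
point corresponding to `x` in the moving (subject) image is `x + u(x)`.
Warping is a pull-back, `out(x) = img(x + u(x))`, so warping the *subject*
image by `u` aligns it with the baseline, and warping the *baseline* by the
numerical inverse `u⁻¹` aligns it with the subject. All images and fields
entering a pipeline are resampled to the baseline grid first; out-of-domain
samples are 0 (not NaN), which keeps overlap metrics downstream defined.

## The personalization model

A pipeline is an ordered list of registration steps. Step *k* produces a
dense field `g_k` on the baseline grid; before step *k* runs, the
baseline-side mask is warped by the inverse chain of the already-computed
fields, so each step sees the progressively personalized baseline and only
has to capture the residual difference.

Two composition rules are implemented **literally and separately**:

* **Morphing** uses the *sum* `g_subj = g_demo + g_f1 + … + g_fn`. Mesh
  nodes move by `x_i = X_i + g_subj(X_i)` with `g_subj` interpolated
  trilinearly at the baseline node positions; connectivity and part labels
  never change.
* **Evaluation** warps the baseline image/labels through the *nested
  inverse chain* `g_fn⁻¹(… g_f1⁻¹(g_demo⁻¹(img)))`, first-registered step
  innermost.

The sum approximates the composition only when per-step fields are small or
have essentially disjoint support. The asymmetry is retained by design: it
is the framework being reproduced, and the hierarchical construction (each
step registered against the progressively warped baseline) keeps the
per-step residuals in the regime where the approximation holds. The field
summation evaluates every step at the baseline node positions; evaluating
at progressively warped positions is available via composing warps
manually but is not the default.

## Demons registration of binary masks

Feature steps register one segmented binary mask at a time (cranial
envelope, lateral ventricles, corpus callosum, lesions …). Raw binary
images have degenerate gradients, so both masks are converted to signed
Maurer distance maps (negative inside), clamped to ±20 mm so far-field
gradients do not dominate, and fed to the diffeomorphic Demons solver
(SimpleITK's `DiffeomorphicDemonsRegistrationFilter`, the
stationary-velocity scaling-and-squaring variant) inside a 3-level
Gaussian-smoothed shrink pyramid (50/30/20 iterations by default). Update
and field smoothing default to 1 and 1.5 voxels of the fixed grid
(expressed in mm in `DemonsParams`); all parameters are overridable per
step in the pipeline config.

**Compact support.** Per-iteration field smoothing is elastic-like: it
diffuses the boundary-driven displacement into regions where the mask
provides no constraint, leaving a large smooth tail far from the
structure. A tail is harmless for a single registration but corrupts the
*composition*: a ventricle feature step's tail displaces the already
well-aligned cranial boundary. Since a binary mask constrains the
transform only near its boundary, each returned field is therefore tapered
to zero with a C¹ quartic window beyond 15 mm from the union of the two
masks (fully zero beyond 15 + 25 mm). The taper widths trade locality
against invertibility: a narrow taper compresses the displacement over a
short distance and can push the field Jacobian toward zero, a wide taper
re-introduces the tail. The defaults keep the interior field Jacobian
comfortably positive (≈ 0.6 on the validation phantoms) and can be
disabled (`localize=False`) for single-step use.

Rigid pre-alignment is centroid + principal axes of the second moments,
with the four proper sign combinations of the axes tried and the
best-overlap candidate kept. For near-symmetric shapes (an ellipsoid is
invariant under 180° flips) the choice among symmetry-equivalent rotations
is arbitrary but harmless, since overlap decides.

## Field inversion

Inverses solve `f(x + h(x)) + h(x) = 0` by fixed-point iteration
`h_{k+1}(x) = −f(x + h_k(x))`, `h_0 = −f`, to a max-norm residual of
0.05 mm over interior grid points (50 iterations maximum; non-convergence
raises with the residual). The iteration converges for fields with
positive Jacobian and contraction constant below one; a non-positive
Jacobian is reported (or fatal under `strict`). The Jacobian map itself is
`det(I + ∇u)` with central differences in the interior and one-sided
stencils at faces, gradients taken in world mm.

## Mesh quality

Six per-element metrics are computed on the 8-node hexahedra, with the
customary pass thresholds: scaled Jacobian ≥ 0.5, warpage ≤ 30°,
skew ≤ 60°, aspect ratio ≤ 8, minimum face angle ≥ 30°, maximum face
angle ≤ 150°. Definitions (these vary across FE preprocessors, so values
are convention-dependent and stated here explicitly):

* **Scaled Jacobian** — at each of the 8 corners, the determinant of the
  three emanating edge vectors, each normalized to unit length; the
  element value is the minimum over corners. 1 for a perfect cube (and
  invariant under uniform scaling and rigid motion), ≤ 0 for degenerate or
  inverted elements. This *FE Jacobian* is a strictly stronger requirement
  than positivity of the image-space Jacobian map `det(I + ∇u)`: a field
  can be diffeomorphic at voxel resolution yet shear an element badly
  enough to invert a corner.
* **Warpage** — per quad face, the angle between the normals of the two
  corner triangles of a diagonal split (worst of both splits); element
  value is the worst face.
* **Skew** — per face, the deviation from 90° of the angle between the
  two mid-lines connecting opposite edge midpoints; worst face governs.
* **Aspect ratio** — max/min of the mean edge length along the three
  local axes.
* **Min/max angle** — extreme interior angles over all 24 face corners.

A personalized mesh is *satisfactory* when ≥ 95% of elements keep scaled
Jacobian ≥ 0.5; the pipeline warns (it does not abort) below the bound,
since quality is inspected post hoc.

## White-matter regrouping

After morphing, elements of the eligible parts (GM/WM by default) are
re-voted against the subject's segmented label image. Every voxel whose
cube can intersect an element (world-space bounding-box prefilter)
contributes a weight to that element: +1 per voxel vertex inside, +2 if
the voxel centroid is inside (max 10). Weights accumulate per label, the
element takes the argmax label. Background (label 0) participates in the
vote — otherwise a single stray foreground voxel would capture a mostly
empty element; ties and zero-weight elements keep their prior part.

The inside test inverts the trilinear isoparametric map by Newton
iteration (tolerance 1e-10, max 30 iterations, stalled or singular points
counted outside) and accepts `|ξ| ≤ 1 + 1e-9`; boundary points therefore
count as inside for *both* adjacent elements, which is harmless because
weighting is per element. A 24-tetrahedra decomposition serves as the
independent oracle in the tests, as does a no-prefilter full-enumeration
implementation of the vote.

## Overlap metrics

DICE(A,B) = 2|A∩B| / (|A|+|B|); missing (NaN) when both masks are empty.
HD95 is the maximum of the two directed 95th-percentile distances between
*boundary* voxel sets (morphological erosion difference), percentile by
linear interpolation between order statistics, KD-tree nearest-neighbour
queries for the directed distances. The directed distance uses max–min
(distance of a point to the nearest point of the other set); units default
to voxels, mm is available. Jaccard = DICE/(2−DICE). Aggregation over
subjects is the arithmetic mean over non-missing entries, reported
half-up-rounded to 2 decimals (means of printed decimals are rounded as
decimals, not as binary floats).

## The synthetic phantom

The phantom is a nested-ellipsoid head on a 64³ grid at 2 mm (the default
"desk-scale" resolution: every end-to-end run completes in minutes on one
CPU): a filled cranial ellipsoid (semi-axes 52/44/40 mm), a brain
ellipsoid (46/38/34 mm), a white-matter blob (30/25/22 mm) and a
ventricle-like cavity (8/13/9 mm), plus a piecewise-constant
tissue-contrast image smoothed at 1 voxel with seeded Gaussian noise
(σ = 2 intensity units). Subjects are produced by closed-form smooth
deformations whose Jacobian positivity is verified numerically at
construction:

* `global_scale` — `u = s·x`, default s = 0.1 (a 10% size change,
  a newborn-vs-adult-scale global difference);
* `ventricle_enlarge` — a C¹ compact radial bump in normalized ellipsoidal
  radius around the ventricle, amplitude set so the cavity volume scales
  by the requested factor (default 3, a hydrocephalus-like enlargement),
  support 2.6 ventricle radii;
* `lesion_bulge` — a directional compact bump (default 3 mm push over a
  16 mm support) near the cranial boundary;
* `composite` — the sum of the three.

Because the generating field is known in closed form, registration
recovery can be scored exactly; the subject's images and masks are the
baseline warped through the *numerical inverse* of the ground-truth field
(tolerance 0.02 mm), so subject masks are honest re-segmentations at voxel
resolution, not copies.

The baseline mesh is a structured n³ lattice (default 16³ = 4096 elements)
pushed through a bounded-distortion "rounded cube" map — a radius-weighted
blend of the identity and the radial cube-to-sphere map, blend weight 0.6,
uniformly shrunk to stay inside the brain ellipsoid. Full spherification
would crush the corner elements (scaled Jacobian ≈ 0.03); the blended map
keeps every element ≥ 0.75 at 16³ while covering most of the ellipsoid.
Parts (GM/WM/LV) are assigned from the phantom's tissue labels with the
same voxel-weight vote used for regrouping. The construction refuses specs
whose ventricle would span fewer than 2 elements.

**What the phantom does not emulate:** MRI contrast physics, bias fields,
sulci/gyri geometry, skull/CSF substructure, segmentation errors, or
topology differences between subjects. Passing the phantom suite shows the
machinery (registration, composition, inversion, morphing, voting,
scoring) is correct and that the pipeline preserves element quality under
realistic gross deformations; it does not certify accuracy on clinical
images, where mask quality and intensity registration dominate.

## Validation problem sizes

Unit tests run mask registrations on a 32³/4 mm version of the same
geometry; the acceptance suite and `scripts/acceptance.py` run the full
64³/2 mm phantom with the 16³-element mesh — a deliberate scale-down from
production head meshes (millions of elements, 1 mm images) chosen so the
whole suite runs on a single CPU in minutes. The quality statistics are
grid-convergence-stable in the sense that halving the voxel size changes
the regrouped element set by under 2% on smooth phantoms.

## Known limitations

* Intensity-based nonlinear registration is deliberately out of scope;
  external tools supply those fields through the 4D-NIfTI adapter
  (mm or voxel-displacement dialects).
* The summed field is not the exact composition of the per-step
  transforms; for large per-step displacements the morphing and the
  evaluation transforms can diverge (kept by design, see above).
* HD95 between voxelized boundaries underestimates sub-voxel surface
  distances; values below ~1 voxel are quantization-limited.
* The compact-support taper slightly reduces the captured displacement in
  the taper band; structures of interest should sit inside the support
  cap of their feature mask.
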