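# Methods

`gwrkit` implements a surface-based analysis of gray/white matter tissue
contrast: per-vertex intensity sampling around the cortical ribbon, the
gray-to-white intensity ratio (GWR), closest-distance cortical thickness,
FWHM-calibrated smoothing on the surface mesh, and vertex-wise group GLMs
with per-vertex covariate control and FDR thresholding.  This note records
the model, its assumptions, the parameters that matter, and the design
choices made where the design was genuinely open.

## The measurement model

A subject contributes a T1-weighted intensity volume `I(x)` (arbitrary
units, WM brighter than GM, GM brighter than CSF) and a corresponded pair
of triangle meshes: the white surface (gray/white boundary) and the pial
surface (gray/CSF boundary), sharing vertex indexing so that vertex `v` on
both surfaces spans the cortical ribbon.

Per vertex `v`:

- **GM intensity** `G(v) = I(w_v + f (p_v − w_v))`, with `w_v`, `p_v` the
  white and pial positions and `f = 0.35`: 35% of the way through the
  ribbon from the gray/white border.  The shallow depth keeps the sample
  conservatively close to the border so thin cortex and remote-tissue
  contamination perturb it as little as possible.
- **WM intensity** `W(v) = I(w_v − d n̂_v)`, with `n̂_v` the outward unit
  vertex normal and `d = 1 mm`: one millimetre subjacent to the border.
- **GWR** `R(v) = G(v) / W(v)`.  On T1-like data `R ∈ (0, 1)`; values
  drifting towards 1 mean *reduced* tissue contrast.  A ratio rather than
  a difference makes the measure invariant to global intensity scaling
  (scanner gain), which raw intensities are not.
- **Thickness** `t(v) = ½ [dist(w_v, pial) + dist(p_v, white)]`, the
  symmetric average of the two one-sided exact point-to-mesh closest
  distances.  A one-sided variant is available (`symmetric=False`).

Intensity lookup is trilinear; it reproduces constant and linear fields
exactly, which the tests exploit as oracles.  Sample points that leave the
volume become missing rather than clamped — clamping would silently bias
the ratio.  WM samples below a denominator floor (default 5% of the robust
WM median) are marked missing so near-zero denominators cannot explode the
ratio.

**The one genuine interpretation** in this stage: the GM sample travels
along the white→pial *correspondence segment*, not along the literal
normal ray.  For corresponded surfaces the correspondence vector is the
ribbon-spanning direction and remains well-defined where normals and
correspondence diverge (sulcal walls); on the spherical phantoms the two
coincide.  The WM sample uses the actual (negated) vertex normal because
no inner corresponding surface exists.  Vertex normals are area-weighted
averages of incident face normals; angle weighting was rejected as an
unneeded refinement at the mesh resolutions used.

## Smoothing

Maps are smoothed on the surface by iterated unweighted averaging over
`{v} ∪ N(v)` (each vertex with its edge neighbors; the vertex's own
inclusion makes constant maps exact fixed points and every step a
contraction).  The iteration count realizing a requested Gaussian FWHM is
calibrated per mesh: a unit impulse is smoothed step by step; after each
step the kernel's spread is summarized as the per-direction variance
`σ² = ½ Σ_v k(v) g(v)²` over geodesic distance `g` (for an isotropic 2D
kernel the per-direction variance is half the mean squared radial
distance), and the `N` minimizing `|√(8 ln 2 · σ²) − FWHM|` is kept.
Calibration is deterministic, cached on mesh contents, and cross-checked
by an independent half-maximum measurement of the realized kernel profile
(agreement within 10% at the 30 mm default on a fine mesh).  Geodesic
distances are graph (Dijkstra) distances over edge lengths; they
overestimate true surface geodesics by up to ~20% on a triangulation,
which is absorbed by the calibration because the same metric is used to
measure and to target.  The mesh resolution floors the achievable widths:
one iteration already spreads mass one edge length, so kernels much
narrower than ~2 edges cannot be realized and the calibration reports the
mismatch.  Iterations grow as (FWHM/edge)²; unreachable widths within the
iteration cap raise an error naming the achievable maximum.

Missing vertices stay missing and are excluded from their neighbors'
averages — missingness neither spreads nor contaminates.  Implementation
sums neighbor values and divides by the count (rather than applying a
precomputed row-stochastic matrix) so that constant maps are bit-exact
fixed points.

## Group statistics

At each vertex, ordinary least squares of the outcome across subjects on
`[1, group, nuisance…, r(v)…]`, where `r` are per-vertex regressors
(typically thickness) demeaned across subjects at each vertex.  The group
coefficient's two-sided t test (df = n_used − columns) gives the statistic
map; Benjamini–Hochberg step-up at q = 0.05 over the pooled non-missing
vertices sets the significance threshold (the positive-dependence variant,
standard for smoothed neuroimaging maps; no adaptive or BY option).
Per-vertex regressors implement "test the group effect while controlling a
local measure": e.g. whether a contrast difference survives controlling
thickness at each vertex.

Choices the literature leaves open, decided here:

- **Patient-only covariates** (antipsychotic dosage, illness duration,
  symptom severity) are undefined for controls.  They enter as
  patient-deviation regressors: deviation from the patient mean for
  patients, 0 for controls.  Raw inclusion would be rank-deficient or
  meaningless; the deviation coding keeps the column orthogonal to the
  group indicator in expectation while still adjusting patient outcomes.
- **Missing data**: listwise deletion per vertex for map values, global
  deletion for missing covariates.  Vertices with no residual degrees of
  freedom or an ill-conditioned local design are missing and excluded from
  the FDR family.
- **Two-sided tests** throughout; directional findings are read off the
  sign of the group beta.
- A perfect local fit (zero residual up to rounding) defines t = 0 rather
  than a ratio of two epsilon-scale quantities.
- One FDR family pools all vertices passed in; callers wanting
  per-hemisphere control simply call the threshold per hemisphere.

Estimation is fully deterministic; only the phantom generator consumes
seeds.

## The phantom generator

The synthetic cohort stands in for unavailable clinical MRI data.  Its
geometry is a radially perturbed sphere, deliberately not a brain: every
recovery target has a closed form on it, and realism is a non-goal.

- **Geometry**: white surface = icosphere of radius R (default 50 mm,
  brain-scale); pial vertex = white vertex pushed outward by the thickness
  field `t(u) = t₀ + a·P₂(u_z)` (default 3.0 ± 0.5 mm), a fixed low-order
  angular modulation keeping white/pial correspondence exactly radial.
- **Volume**: voxels labeled by radius (WM inside R, GM in the ribbon, CSF
  outside), optionally multiplied by a separable half-period cosine bias
  field spanning 1 ± bias_amplitude across the field of view, then
  degraded with additive i.i.d. Gaussian noise.  Default voxel 1.5 mm,
  noise SD 6 against a 30-unit GM–WM gap (per-voxel CNR 5, a realistic
  3 T regime).  Rician noise is deliberately not modeled.
- **Cohorts** (default 18 patients vs 18 controls, matched covariate
  distributions; dosage/duration/severity drawn for patients only):
  patients receive fractional WM/GM intensity reductions and/or an
  absolute thickness reduction confined to a geodesic disc ("patch",
  default radius 25 mm) around a center vertex.  On the surface, patch
  membership is by Dijkstra geodesic distance; in the volume, by the
  corresponding cone of directions — the two differ only in a ring of
  about one edge length at the boundary.  Every subject additionally gets
  a global thickness jitter (SD 0.15 mm) and a global intensity gain
  (SD 2%) emulating anatomical variability and scanner gain; the gain is
  exactly what the GWR must be invariant to, and what makes raw-intensity
  GLMs noisier than ratio GLMs in the examples.
- **Determinism**: all per-subject randomness derives from one seed via
  spawned generator streams; identical specs give bit-identical cohorts.

What the phantom does *not* emulate — folded geometry, partial-volume
fractions from a real point-spread function, registration error across
subjects (all phantom subjects share one mesh), spatially correlated
noise — bounds what passing tests show: they validate the *pipeline's
logic and numerics*, not its behavior on real cortical geometry.

## Validation studies and problem sizes

- **Noiseless shell** (R = 30 mm, t = 3 mm, 0.5 mm voxels, 2562 vertices):
  at this resolution both sample points sit ≥ 2 voxels from any tissue
  boundary, so trilinear sampling is exact by construction and the GWR
  must equal 80/110 everywhere; mean thickness must recover 3 mm within
  the mesh-discretization tolerance.  At 1 mm voxels the 1 mm WM offset
  itself sits within one interpolation cell of the boundary and worst-case
  corner mixing alone reaches ~2% — the finer grid isolates the
  pipeline's correctness from unavoidable partial-volume error.
- **Smoothing calibration**: 30 mm kernel on a subdivision-4, 100 mm
  sphere; half-maximum width within 10% of request.
- **Null FDR**: 200 replicates of 10,000 i.i.d. uniform p values; the mean
  false-discovery proportion must stay within two Monte-Carlo standard
  errors of q.
- **Case-control recovery** (two cohorts of 18 vs 18, 10242 vertices,
  1.5 mm voxels; ~1 minute total on one CPU): cohort A gives patients a
  10% WM-intensity reduction in the patch; cohort B a 1 mm thickness
  reduction with identical per-unit tissue intensities.  The recovery
  analyses smooth at 10 mm FWHM — matched to the 25 mm patch — because
  the validation targets *localization*: at the 30 mm analysis default the
  significant halo of a strong focal effect necessarily dilates far beyond
  the patch and a Dice score against the generating patch stops measuring
  anything about the pipeline.  30 mm remains the analysis default.
  Expected pattern: (a) WM-intensity extent exceeds GM-intensity extent;
  (b) the GWR significant set overlaps the true patch (Dice ≥ 0.5);
  (c) the GWR effect survives per-vertex thickness control in cohort A and
  collapses in cohort B.  For (c) the clean arena is the patch *core*
  (patch eroded by one kernel width): within a kernel width of the patch
  edge the smoothed GWR and smoothed thickness edge profiles differ
  slightly (and the volume cone vs surface disc definitions of the patch
  disagree in a one-edge ring), so a *linear* per-vertex control cannot
  absorb the group difference exactly there.  In the core, attenuation is
  complete (mean |t| well under 2, no significant vertices); the same
  caveat applies to real data, where the GWR–thickness relation is also
  nonlinear.

## Known limitations

- Graph geodesics and uniform neighbor averaging tie the smoother's
  accuracy to mesh quality; strongly anisotropic meshes would need
  cotangent weighting (not implemented — beyond the method description
  this package follows).
- Bias-field correction is the caller's responsibility: the GWR is
  invariant to *global* scaling but not to spatially varying gain; the
  phantom's bias field exists to quantify that sensitivity.
- Real FreeSurfer surfaces need the c_ras shift into scanner RAS; it is
  applied when the volume-geometry footer is present, and phantom
  surfaces are generated directly in world coordinates.
- Cross-subject correspondence is assumed given (maps already on a common
  mesh); spherical registration is out of scope.
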