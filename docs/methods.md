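# Methods

`craniomorph` implements a fully automated pipeline for 3D craniofacial
morphometry from brain-stripped T1-weighted head MRI: group-wise atlas
construction, deformation-based (Jacobian) voxel-wise statistics with
random-field correction, automatic landmark propagation, anthropometric
distance models, and a point-distribution model (PDM) with thin-plate-spline
face simulation.  This note records the models, the conventions, the
defaults and why, what the synthetic phantoms do and do not establish, and
the numerical choices made where the design was open.

## Coordinate and transform conventions

* World coordinates are millimetres, right-handed, given by the NIfTI
  voxel-to-world affine.  Landmarks, transforms and deformation fields all
  live in world space, so grids of different extents interoperate.
* Every transform is a **pull-back** map: it sends points of the *target*
  geometry into the *source* volume, and `resample(source, T, target)`
  evaluates the source at `T(x)` for each target voxel.  No function in the
  package takes a forward map; this removes the classic direction
  confusion.
* Interpolation is trilinear throughout; points outside a source volume
  read as zero (the volumes are brain-stripped heads on empty background).
* Affine transforms factor as `T · R(z,y,x) · Shear · Scale` with positive
  scales; the 6/9/12-parameter families add rotations+translations, scales,
  and shears in that order.  Parameters are uniquely recoverable from any
  matrix with a positive-determinant linear part (QR with sign fixing).

## Linear registration

6/9/12-parameter registration maximizes normalized cross-correlation (NCC)
of Gaussian-blurred intensities over a coarse-to-fine pyramid
(FWHM 8 → 4 → 2 mm, with the sampled grid strided 4/2/2) using a
Nelder–Mead simplex.  Internal parameters are scaled so one simplex unit is
1 mm of translation, 0.02 rad, 2 % of (log) scale or 0.02 of shear, and the
transform is parameterized about the target's intensity centroid so
rotations and scalings are well conditioned.  The initialization is the
centroid shift.  If the optimum does not improve NCC over the
initialization *under the final pyramid level's objective*, the
initialization is returned and a convergence warning is attached
(`result.converged = False`), never an exception.

## Nonlinear registration (node-grid, ANIMAL-style)

A multi-resolution schedule of `(step_size, iterations, blur_fwhm)` rows —
default 8/30/16, 8/30/8, 4/30/8, 4/30/4, 2/10/4, 2/10/2 (mm/count/mm) for
1-mm human data; 64-voxel phantoms use the reduced pyramid 8/4/2 at
10/10/5 iterations.  Per row:

1. both volumes are blurred at the stated FWHM;
2. control nodes are placed on the target lattice at the step spacing;
3. each node's local translation is optimized by a derivative-free
   Nelder–Mead simplex (3 parameters, initial edge `step/2`, ≤50
   evaluations) of the local NCC between the fixed target patch and the
   displaced source patch, inside a spherical search region of radius
   `3 × step`;
4. the data-driven update `D` is blended with its Gaussian-smoothed
   neighborhood field: `u ← α·D + (1−α)·G(D)` with
   `α = similarity / (similarity + stiffness·weight)` (defaults 0.3/1/1,
   i.e. α ≈ 0.23) and `G` a Gaussian over nodes with σ = one node spacing.
   Nodes without usable intensity (patch below 5 % of the image maximum or
   with no variance) take the smoothed value only;
5. the field is upsampled as initialization of the next row.

The returned field maps target (model) points to source (subject) points.

Open design points resolved here, configurable via `OptimizerConfig`:

* **Similarity window.** The window is a sphere of radius
  `window_factor × step` sampled at `step / window_samples_per_step`
  spacing; default radius `2 × step` at step spacing (~33 samples).  A
  window of radius `1 × step` proved noticeably noisier on phantoms: with
  few samples on a blurred image the NCC surface is nearly flat along
  iso-intensity surfaces and the node estimates drift tangentially (the
  aperture problem).
* **Minimal-deformation tie-break.** A node only moves off zero (first
  preference) or its incoming displacement (second) if the simplex optimum
  improves local NCC by more than `tie_epsilon` (default 3·10⁻³).  This
  quantifies the "keep zero displacement on flat similarity" rule and
  suppresses aperture-driven drift; `1e-6` (machine-level ties only) makes
  self-registration exact but admits spurious tangential moves under noise.
* **Minimal-deformation prior.** The node objective is
  `NCC − penalty · (|d|/search_radius)²` (default penalty 0.02): a move
  near the search boundary must buy a genuine similarity gain.  Together
  with the tie-break this caps isolated node excursions in flat-similarity
  regions without measurably degrading the recovery of true warps (the
  penalty at a 4-mm correction under the default search radii is below the
  typical similarity gain of a real match by an order of magnitude).
* The regularization blend smooths the *data field* of the current
  iteration; at a fixed point this equals smoothing the converged field,
  and it converges in practice in a handful of iterations.

Deformation-field inversion uses plain fixed-point iteration
`v ← −u(y + v)` (≤20 iterations, convergence to a quarter of the requested
tolerance, default 0.05 mm); inputs with non-positive Jacobian determinants
are rejected, and failure to reach tolerance at more than 1 % of nodes
raises a warning, not an error.  Transform averaging is done in
matrix-logarithm space (`expm(mean(logm))`), which is symmetric under
inversion — averaging a transform with its inverse gives the identity —
and is the standard choice for unbiased template construction.

## Group-wise atlas

1. rigid (6-dof) alignment of every volume to a seed subject
   (configurable index; the choice washes out after the next stage);
2. all-pairs 9-parameter registration.  Each unordered pair is registered
   once and the reverse direction reuses the matrix inverse (identical in
   exact arithmetic, half the cost).  Each subject's log-space average of
   the maps "other subject → me" (identity included) scales it to the
   population's average head size; the intensity mean of these scaled scans
   is the 9-parameter model.  The **head-size factor** is the product of
   the three scale parameters of this average transform (pull-back, average
   space → subject), so values above 1 mean a larger-than-average head.
3. 12-parameter registration of the *original* volumes to that average and
   a new intensity mean (the linear population model);
4. one nonlinear generation per schedule row: every subject is registered
   (warm-started from its previous field) to the previous generation's
   average; the voxel-wise mean of the resampled subjects becomes the next
   model.  The linear and nonlinear maps are composed so each original
   volume is interpolated exactly once into model space — repeated
   resampling measurably blurs the average.

After each nonlinear generation the new average is warped by the inverse of
the subjects' mean deformation and the per-subject fields are re-expressed
in the corrected coordinates (`unbias_mean_deformation=True` by default).
Without this, the evolving model drifts from the population mean shape —
blurred averages bias edges toward centers of curvature and every subject
inherits the bias — which is visible on phantoms as a nonzero mean
recovered field even when the planted warps sum to zero.  The correction is
the standard lightweight unbiasing used by sequential template builders; it
is not simultaneous (Joshi-style) template estimation, which remains out of
scope.  The residual limitation that remains is the per-subject accuracy
floor of the local-translation node optimizer (a few tenths of a millimetre
in intensity-visible directions on phantoms), which bounds how sharp the
average can get.

Automated QC replaces the study's visual inspection: each subject's final
in-mask NCC with the model is reported, subjects under the threshold
(default 0.85) are flagged and excluded from the final average — recorded
in `qc_report`, never silently dropped.

## Deformation-based morphometry

Jacobian determinants `det(I + ∂u/∂x)` of the model→subject fields are
evaluated on the model grid by central finite differences (one-sided at
borders) in world mm; values above 1 mean the subject is locally larger
than the model.  Raw determinants (not log) are analyzed to match the
expansion/contraction reading; callers can log-transform if symmetry
matters.  Maps are blurred (8-mm FWHM default), restricted to the face —
head voxels anterior to a coronal plane at the top of the forehead — and
fed to a voxel-wise OLS (sex + age + head size by default).  Sex is coded
female = +0.5 / male = −0.5, so positive coefficients mean larger values in
females and the age term is the between-sex average slope.

Residual smoothness is estimated from the variance of forward-differenced
normalized residuals (FWHM_j = √(4 ln 2 / λ_j), geometric mean across
axes); with fewer than 10 subjects the applied blur FWHM is used instead.
Family-wise error control solves `E[EC](t) = α` for the peak threshold,
using the Euler-characteristic densities of a t field and resel counts
obtained by counting points/edges/faces/cubes of the mask lattice; the
threshold is clipped between the uncorrected quantile and Bonferroni over
the in-mask voxels (the EC expansion is only valid for smooth fields).
Clusters form at that threshold with 18-connectivity; each gets a
peak-level corrected p (expected EC at its peak) and an approximate
cluster-extent p from the standard expected-cluster-size exponential
approximation — the latter is flagged approximate, and a permutation check
is recommended when extents matter.  Only the positive tail is reported;
flip the contrast for the other direction.

## Landmarks, anthropometrics, PDM

The 56-landmark face template (eyes, nose, lips, jaw/chin with two jaw
semi-landmarks, ears, forehead/brow, zygomatic) ships as code generating
anatomically named anchors on the synthetic template; the original study's
landmark table is not public, so this is a documented reconstruction, and
users can supply their own template TSV.  Propagation evaluates the
model→subject deformation at the template points; because that field lives
in the space of the 12-parameter registration, the output is free of global
head size — the registration-based analogue of Procrustes superposition.
Points outside the field lattice are flagged per point, never fatal.

Anthropometric distances (eye length/height, mouth width, ear-to-ear and
zygomatic widths, nose width, filtrum, nose–chin, lip–chin) and the first
five PC scores are modeled as `value ~ sex + age_c + age_c × sex` with age
centered (months); per-sex age slopes are reported as follow-ups with
delta-method standard errors.  PC scores can first be residualized on
percent body fat (simple regression) to separate soft-tissue from skeletal
effects.

The PDM concatenates the 56 × 3 coordinates, subtracts the **model's**
landmark coordinates (not the sample mean — the sample-mean offset then
legitimately appears in the scores; `center="sample_mean"` switches to the
conventional centering), and eigendecomposes the second-moment matrix via
SVD.  "Variance" therefore means mean-square deviation from the reference;
eigenvector signs are fixed so the largest-magnitude loading is positive.
Mode simulation displaces the reference by
`p · A · √λ_k · v_k` for proportions p = 0.2 … 1.0 with amplitude A = 3
standard deviations of the mode at full proportion — "adding a proportion
of the component score" is ambiguous because scores vary per subject; this
reading exaggerates the encoded feature relationships visibly and is
configurable.  The thin-plate spline uses the 3D kernel U(r) = r with an
explicit affine part; it interpolates the control points exactly,
reproduces affine maps with zero nonlinear weights, and its bending energy
`−Σ wᵀKw` vanishes exactly for affine displacements.

## Synthetic data: what it emulates, what it does not

The canonical template is an analytic head: an ellipsoidal soft-tissue
shell (semi-axes 18/20/24 mm about (32, 30, 32) on a 64³ 1-mm grid) with a
bright ~2-mm skull ring, an empty brain cavity (brain-extracted), face
features as intensity blobs (protruding nose, lips, chin, eye sockets,
brows, ears, cheekbones), and a fixed smooth intensity texture
(~11-mm wavelengths, ±18 %) standing in for muscle/fat heterogeneity.  All
feature widths are ≥2 mm so nothing is below the Nyquist limit of the
grid.  The texture matters: on an untextured shell, displacement components
tangent to iso-intensity surfaces are unobservable (the aperture problem)
and no intensity-driven registration can recover them; real T1 tissue is
textured.

Subjects are the template warped by an analytic forward map
`Scale ∘ RandomWarp ∘ FeatureBumps`:

* **Feature bumps** are 6-mm Gaussian displacement bumps with weight
  exactly 1 at their anchor landmark (nose length/width, chin protrusion,
  jaw width, lip thickness, forehead slope, mouth width), so a lone planted
  delta moves its anchor by exactly that amount; paired width features
  split the delta half per side.  Bounds: ±8 mm.
* **Random warps** are 12-mm-FWHM-blurred white-noise vector fields
  normalized to a head-RMS amplitude (default 1.5 mm), scaled down
  automatically if the total map's Jacobian would fall below 0.15
  (guaranteeing invertibility).
* **Head size** is an isotropic lognormal scale (default σ = 0.03) about
  the head center.

The volume is rendered by evaluating the template's *analytic* intensity at
the numerically inverted forward map — no interpolation, so the stored
pull-back field reproduces the volume exactly and the zero-deformation
phantom equals the template bit-for-bit.  Gaussian noise (default sd 2
intensity units, ~1 % of peak) and an optional ±10 % bias ramp are added
last.  Cohorts draw sex ~ Bernoulli(0.5), age uniform on 144–216 months,
and percent body fat with a sex offset and an optional coupling into a face
feature (to exercise the residualization check).  Default planted effects
emulate adolescent dimorphism: broader male jaw (−3 mm female-positive) and
mouth (−2 mm), more prominent female lips (+1.5 mm), and male-specific age
slopes on jaw width and nose length.

What a green synthetic test does **not** establish: performance on real
T1 contrast (no MRI physics, no N3-scale bias artifacts, no teeth/orthodontic
artifacts), robustness to brain-extraction errors, or the anatomical
validity of the reconstructed landmark template.  Statistical calibration
results transfer only insofar as real residuals are as well behaved as the
simulated ones.

## Scaling of the validation suite

The full-resolution schedule on 597 subjects is a cluster-scale
computation.  The test and acceptance suites run the identical code on
64³ phantoms with the reduced schedule: atlas checks use 6–8 subjects,
the RFT family-wise-error Monte-Carlo uses 500 replicates at 32³, the
statistical size checks use 200 replicate cohorts at the landmark level,
and the end-to-end determinism check uses 4 subjects with a 2-step
schedule.  Each scaled test notes this in its docstring; thresholds were
not altered to fit the smaller runs.

## Known limitations

* Cluster-extent p-values use the stationary-smoothness exponential
  approximation; permutation is recommended for publication-grade extents.
* The node optimizer estimates local translations only (no local affine),
  and the stiffness/weight/similarity blend is one reading of the sparse
  published description of the regularizer.
* Landmark correspondence is carried entirely by the registration; the two
  jaw semi-landmarks are fixed model-space points, not sliding landmarks.
* The atlas is the sequential hierarchical scheme; simultaneous unbiased
  (diffeomorphic) template estimation is out of scope.
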