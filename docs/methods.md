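# Methods

This note documents the models, numerical choices and limitations behind
`fetalrecon`, in the order the pipeline runs.

## Digital phantom and acquisition simulator

The phantom is a geometric stand-in for a mid-gestation fetal trunk: a
uterus shell, trunk, thorax, abdomen, heart, liver and brain as nested
ellipsoids, plus three dark tubular "vessels" (1.5–1.8 mm radius) inside
the thorax that give the super-resolution stage genuinely sub-slice
structure to recover.  Containment invariants (heart ⊂ thorax,
liver ⊂ abdomen, thorax ∪ abdomen ⊂ trunk, non-collinear landmark
configuration) are enforced numerically on ellipsoid boundary samples.
The intensity volume is band-limited with a 1.2 mm Gaussian because
tissue interfaces in MR images are not step edges at acquisition
resolution; without this, slice-profile blur of aliased edges dominates
every NCC comparison.  A smooth seeded random texture (amplitude 8 on
tissue values of 60–130, correlation length 4 mm) is added inside the
fetus so that intensity-based registration has non-degenerate structure
— a constant-intensity ellipsoid is rotationally ambiguous.

The default grid is 160³ at 0.7 mm (112 mm field of view, matching the
reconstruction resolution).  Desk-scale grids (`desk_spec(n)`) keep the
112 mm field of view and coarsen the voxels; experiments use 64³
(1.75 mm) so the full test suite runs in minutes on one CPU.

The simulator samples the phantom, moved by a rigid pose about the trunk
centroid, slice by slice through a Gaussian slice profile of
FWHM = slice thickness (7 quadrature taps over ±2σ; a boxcar profile is
available).  The acquisition default follows a clinical single-shot T2
protocol: 1.25 mm in-plane, 2.5 mm slice thickness, 1.25 mm slice
spacing (negative gap), interleaved slice order in 4 packages giving
5 mm within-package spacing; desk-scale runs scale these by the voxel
ratio (1.75/3.5/1.75 mm).  Corruption terms — per-slice rigid jitter, a
smooth multiplicative second-order polynomial bias field, and Gaussian
noise — are all drawn from a single seeded generator, so identical
(spec, seed) pairs are bit-identical.  No MR physics (T2 decay, k-space
sampling) and no maternal-breathing or deformable motion is modelled;
consequently passing tests demonstrate geometric and robustness
behaviour, not contrast fidelity on clinical data.

## Localisation

The global segmentation contract is a 4-class map (background, uterus,
brain, trunk).  Two backends share one configuration type.  The *oracle*
backend returns ground-truth labels sampled onto the stack grid during
simulation (including per-slice jitter, so "segmented" organs wobble the
way network outputs would); it makes the whole pipeline deterministic
and CNN-free, and is the only backend the test suite uses.  The *cnn*
slot describes a 5-level 3D UNet (32/64/128/256/512 channels, instance
norm, LeakyReLU, average pooling for the first two down-samplings then
max pooling, generalised Dice loss, Adam at lr 0.002, batch 2, 128³
input grid); selecting it without trained weights raises an explicit
`UntrainedBackendError` — never silent garbage — and running it requires
a PyTorch runtime that this package deliberately does not depend on.

Trunk post-processing keeps the largest 26-connected component (ties
broken by lexicographically smallest bounding-box origin, so the result
is deterministic) and crops to the mask bounding box dilated by 15 mm
(margin configurable; the dilation absorbs segmentation conservatism and
gives registration context).  `resample_to_grid` pads symmetrically to
equal world extents before scaling — aspect ratio is never stretched —
and updates the affine so world geometry is exactly preserved.

## Landmark pose estimation

Landmarks are the unweighted voxel-centre centroids of the thorax,
abdomen, heart and liver masks, in world mm.  Heart and liver voxels are
subtracted from thorax and abdomen *before* centroid computation
(clinically the organ masks come from two networks and may overlap; on
the phantom's exclusive label maps the subtraction is a no-op by
construction).  Intensity weighting was rejected: the labels, not the
intensities, define the fiducials.

`point_register` is the classical closed-form least-squares rigid fit:
centre both point sets, SVD of the cross-covariance, flip the smallest
singular direction if the rotation would be improper, translation from
the centroids.  Configurations whose centred source matrix has a
singular-value ratio below 1e-8 are rejected as degenerate.  The
transform is applied to the stack affine only — voxel data are never
resampled at this stage.  The atlas reference is a configurable set of
four points; for phantom work it is the untransformed phantom's own
landmark set, and it is serialised as JSON for external use.

Pose estimation from four well-separated landmarks is exact under rigid
motion and degrades gracefully with landmark error: a σ mm isotropic
perturbation of landmarks at configuration radius r produces a rotation
error of roughly σ/r radians, which the intensity-based refinement in
Step III then removes.

## Stack selection

All NCCs are Pearson correlations over the non-zero overlapping region,
with a defined value of 0 when the region has fewer than two voxels or
either side is constant (blank content counts as maximally dissimilar
rather than undefined).  `Ccor` is computed on the stack's own cropped
grid; `Csim` on a common isotropic grid (finest in-plane spacing among
the stacks, atlas axes) inside the union of transformed thorax masks.
The self term of `Csim` is included, following the literal definition;
it shifts every stack equally and cannot change any decision, and it is
trivially removable.  Inclusion uses strict inequalities with defaults
0.5 / 0.5 / 0.40.  An empty thorax mask gives volume 0 and is excluded
through the volume criterion — the "trunk absent" path.

Pairwise refinement registers each stack towards a provisional reference
frame (the least motion-corrupted stack under its landmark transform) and
keeps the landmark-only transform whenever registration diverges (final
NCC below the NCC at initialisation), logging the event.  After
refinement the pipeline re-anchors the mutually aligned ensemble to the
atlas: the stacks' landmark positions are mapped into the common frame,
averaged, and the average is point-registered to the atlas reference.
Averaging over the ensemble reduces the common-frame bias that would
otherwise be inherited from the single reference stack's landmark error
by roughly the square root of the number of stacks.  The template
is the voxelwise median over the stacks that cover each voxel; the mask
is the voxelwise mean of the binary masks thresholded at 0.5, i.e. the
majority vote, which is the median of binary values.

## Rigid registration

A multiresolution (factors 4/2/1) regular-step gradient descent over six
rigid parameters — axis-angle rotation about the fixed-region centroid
plus translation — maximising NCC sampled at the fixed-mask voxel
centres (strided per level, capped at 4000 points; full-grid resampling
is never needed for the cost).  Rotation parameters are scaled by the
region radius so one step unit moves peripheral voxels about 1 mm
regardless of whether it is a rotation or a translation.  Steps halve on
failure to improve and the level ends below 0.02 mm.  The optimiser is
strictly local: on the phantom its capture range ends between 45° and
90°, which is precisely the limitation the landmark initialisation
removes (the capture-range sweep in `experiments` reproduces the
classical-collapse / landmark-flat / combined-best pattern over
0–180°).

## Super-resolution reconstruction

The acquisition model treats each slice pixel as a Gaussian
slice-profile-weighted integral of the unknown volume (FWHM = slice
thickness, 5 taps), implemented as a sparse trilinear gather/scatter
pair so the forward and adjoint operators are exact transposes.  Where
part of the PSF footprint leaves the reconstruction grid the captured
weight renormalises the projection, keeping it an unbiased weighted
average at the boundary.  The in-plane PSF is approximated by the
trilinear interpolation footprint, which at an output grid finer than
the in-plane spacing is a sub-voxel kernel; modelling it explicitly
would triple the operator size for little gain at these scales.

Each outer iteration (default 3) performs: per-slice rigid registration
to the current volume, robust slice weighting, and a super-resolution
update.  Slice corrections model *within-stack* jitter, so a correction
that would move a slice by more than 5 mm is treated as a spurious
lock-on and reverted; without this trust region, grossly misregistered
slices can drag themselves onto plausible-looking planes of the volume
and defeat outlier rejection.

Slice weights combine a relative and an absolute view of the per-slice
residual (median absolute pixel error, in units of the pooled slice
intensity standard deviation — the median keeps partial-volume pixels at
the mask edge from dominating a slice's score):

* the *relative* part is an EM fit of a Gaussian-inlier /
  uniform-outlier mixture on log-residuals, anchored on the best-fitting
  decile.  The anchor matters: when a majority of slices is
  misregistered the consistent minority defines the inliers, and an
  unconstrained mixture would happily model the majority instead.  The
  inlier component's mean is tied to the anchor (+0.3 decades, capped at
  an absolute 0.35) and its spread bounded to [0.15, 0.4] decades;
* the *absolute* part brackets the posterior: a slice whose residual
  approaches half the data contrast is down-weighted regardless of the
  cohort (`exp(-½(e/0.5)²)` cap), while one below a fifth of the data
  contrast is kept even when the cohort's residual cluster is far
  tighter (`exp(-½(e/0.2)⁴)` floor).

Slices with weight below 0.5 count as excluded in the report.  The
super-resolution update minimises the weighted data misfit plus an
edge-preserving Huber penalty on finite-difference gradients (δ = 0.2 of
the data standard deviation, so the whole solve is exactly equivariant
under global intensity scaling), solved by conjugate gradients with
lagged Huber weights; the regularisation weight is normalised by the
observation-to-voxel ratio so its meaning does not drift with problem
size.  The robust objective is recorded per outer iteration and is
non-increasing on the test problems.

## Experiments

The rotation sweep follows the published protocol: angles
{0, 15, 30, 45, 60, 75, 90, 105, 120, 180}°, one identity-pose template
stack, six rotated stacks per angle, three registration scenarios.  The
six stacks realise all (axis, sign) combinations — ±X, ±Y, ±Z — each
about a single axis; composing the same ±angle about all three axes was
rejected because ±180° about three orthogonal axes composes to the
identity, which would make the largest sweep angle degenerate.

The ablation simulates severe-motion datasets (6 stacks in 6 slice
orientations, poses drawn with 95–140° rotations and ±10 mm
translations, interleaved 4-package acquisition with 2°/1.5 mm per-slice
jitter, 1.5σ noise and a 15 % bias field) and reconstructs them under
three scenarios: localisation only, plus landmark reorientation, plus
stack selection and median-template generation.  Landmark positions in
these runs carry fixed seeded 3 mm Gaussian perturbations, emulating the
few-mm centroid error of segmented (rather than oracle) landmarks that
the refinement step exists to absorb; the perturbations are shared
across scenarios so the comparison is paired.  In the scenarios without
stack selection, the template is the least motion-corrupted *whole*
stack — a single package has too sparse a slice coverage to referee
outlier rejection.  One stack (the one closest in pose to the unrotated
reference) is held out of every reconstruction and its
simulated-vs-original slice NCC measures generalisation.  Desk-scale
NCC magnitudes and exclusion percentages are not comparable to clinical
values; the orderings across scenarios are the reproducible object.

## Problem sizes

Defaults used by the test suite and the acceptance script: 64³ desk
phantoms for the sweep (10 angles × 6 stacks × 2 local registrations),
ablation (3 datasets × 3 scenarios, 24 package-units each) and
end-to-end runs, and the full 160³ / 0.7 mm phantom for the
super-resolution recovery check.  These sizes keep each experiment in
the 1–2 minute range on a single CPU while leaving every organ several
voxels across at the coarsest grid.

## Known limitations

* Motion between slices is rigid; deformable (bending/stretching) fetal
  motion is outside the model, as is any MR contrast physics.
* The oracle segmentation backend cannot mis-localise; robustness
  results concern registration and reconstruction, not segmentation
  failure modes.
* The relative/absolute residual bracketing assumes the pooled intensity
  std is a meaningful contrast scale; data with severe uncorrected
  intensity non-uniformity would need bias correction first (the
  simulator's bias fields are within what the linear per-stack intensity
  matching absorbs).
* The per-stack "pose error" reported by the pipeline measures each
  stack against the atlas frame; after ensemble re-anchoring the shared
  common-frame error is the ensemble-mean landmark error, typically well
  under a degree at full resolution and one to two degrees at desk
  scale.
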