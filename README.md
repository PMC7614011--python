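# fetalrecon

Automated reorientation and rigid slice-to-volume super-resolution
reconstruction of motion-corrupted fetal-thorax MRI stacks.

Fetal T2-weighted MRI is acquired as multiple stacks of fast 2D slices.
Each slice is sharp, but the fetus moves between slices and between
stacks, so the 3D volume assembled from any one stack is corrupted, and
early-gestation fetuses rotate so much (> 45–90°) that classical rigid
registration cannot bring the stacks into a common frame at all.
`fetalrecon` implements a fully automated pipeline that solves this in
four steps:

1. **Localise** — a multi-label global segmentation (background / uterus
   / brain / trunk) finds the fetal trunk in each stack; the largest
   connected component is kept and the stack is cropped to the trunk ROI.
2. **Pose** — the centroids of four organ masks (thorax, abdomen, heart,
   liver) serve as landmarks; least-squares rigid point registration
   (centroid alignment + SVD with reflection correction) of these
   landmarks to an atlas reference reorients every stack into standard
   radiological space by a pure NIfTI-header update.  Unlike
   gradient-descent registration this works for *any* initial rotation.
3. **Select** — pairwise rigid refinement, then per-stack quality
   metrics: within-stack motion corruption `Ccor(i)` (mean sequential-
   slice 2D NCC), mutual similarity `Csim(i)` (mean 3D NCC against all
   stacks), and thorax-mask volume deviation `Cvol(i)`.  Stacks are kept
   iff `Ccor(i) > 0.5·max Ccor`, `Csim(i) > 0.5·max Csim` and
   `Cvol(i) < 40 %`; the reference stack maximises `Ccor·Csim`; the
   template is the voxelwise median of the included reoriented stacks.
4. **Reconstruct** — rigid slice-to-volume super-resolution: each slice
   is modelled as a Gaussian slice-profile projection of the unknown
   volume (FWHM = slice thickness); reconstruction alternates per-slice
   rigid registration, robust per-slice weighting (EM fit of a
   Gaussian-inlier / uniform-outlier mixture on slice residuals), and a
   conjugate-gradient super-resolution update with edge-preserving
   regularisation, producing a 0.7 mm isotropic volume and a per-slice
   exclusion report.

A built-in digital phantom (nested-ellipsoid fetal trunk with organ
label maps and tubular vessels) and a stack-acquisition simulator
(slice profile, interleaved packages, per-slice jitter, bias field,
noise) make every stage testable end-to-end without clinical data.
Segmentation is pluggable: the deterministic *oracle* backend consumes
ground-truth labels carried with simulated stacks; the configuration for
an equivalent 3D UNet backend is included for use where a trained model
and a GPU runtime are available.

## Worked example

Simulate six stacks of the phantom with random rotations up to 120° and
translations up to 20 mm, then run the full pipeline:

```python
import numpy as np
import fetalrecon as fr
from fetalrecon import experiments as ex
from fetalrecon.pose import AtlasReference

spec = fr.desk_spec(64)                       # 112 mm FOV at 1.75 mm
img, glob_lm, organ_lm = fr.make_phantom(spec)
c = fr.trunk_centroid(glob_lm)
acq = fr.AcquisitionSpec(in_plane_mm=1.75, slice_thickness_mm=3.5,
                         slice_spacing_mm=1.75, n_packages=1,
                         slice_order="ascending", noise_sigma=1.0,
                         jitter_rot_deg=1.0, jitter_trans_mm=1.0)
rng = np.random.default_rng(42)
stacks = []
for i, D in enumerate(ex.stack_orientations()):
    pose = fr.RigidTransform.from_axis_angle(
        rng.normal(size=3), rng.uniform(-120, 120), center=c,
        translation=rng.uniform(-20, 20, 3))
    stacks.append(fr.simulate_stack(img, pose, acq,
                                    seed=int(rng.integers(2**31)),
                                    labels=(glob_lm, organ_lm),
                                    directions=D, name=f"stack{i}"))

cfg = fr.PipelineConfig(atlas=AtlasReference.from_organ_labels(organ_lm),
                        recon=fr.ReconConfig(output_resolution_mm=1.0,
                                             n_outer_iterations=2))
bundle = fr.run_pipeline(stacks, cfg)
print("reference stack:", bundle.reference)
print("excluded slices: %.1f%%" % bundle.report.excluded_percent())
for name, (e_deg, e_mm) in sorted(bundle.pose_errors.items()):
    print(f"{name}: pose error {e_deg:.2f} deg / {e_mm:.2f} mm")
```

Output:

```
reference stack: stack1
excluded slices: 2.8%
stack0: pose error 1.09 deg / 0.29 mm
stack1: pose error 0.85 deg / 0.23 mm
stack2: pose error 0.91 deg / 0.53 mm
stack3: pose error 0.68 deg / 0.47 mm
stack4: pose error 0.76 deg / 0.32 mm
stack5: pose error 1.44 deg / 0.51 mm
```

Every stack — including those rotated by more than 90°, far outside the
capture range of classical registration — is brought back to the atlas
frame within a few degrees and millimetres, and almost no slices are
rejected by the robust reconstruction.

The same pipeline is available from the shell:

```bash
fetalrecon simulate --out data/ --seed 1 --n-stacks 6 --max-rotation 120
fetalrecon run --indir data/ --out recon/ --res 0.7 --iters 3
fetalrecon experiment sweep --seed 1 --out sweep/
fetalrecon experiment ablation --seed 1 --out ablation/
```

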