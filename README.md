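# palsy3d

Objective grading of unilateral facial paralysis from dynamic 3D
photogrammetry. Clinicians grade palsy by watching patients perform
voluntary expressions; the grades are coarse and poorly reproducible
between observers. `palsy3d` implements the alternative: corresponded 3D
face meshes at rest and at peak expression are aligned, converted into
point-cloud pairs, and fed to a dual-branch PointNet that regresses the
expert-consensus severity grade.

The package is aimed at researchers in facial morphometrics and clinical
machine learning. Patient scans of this kind cannot be shared, so the
package also contains a first-class synthetic cohort generator that
reproduces the whole study design — symmetric face template, five
expression displacement fields, unilateral attenuation tied to a severity
grade, multi-rater grade panels — making every stage testable.

## The method

**Grades.** A modified Sunnybrook scale: three resting-symmetry parameters
and five voluntary-movement parameters (one per expression: eyebrow
raising, eye closure, smiling, cheek puffing, lip puckering), each graded
1 (no movement) to 5 (normal) by 7 assessors in 2 sessions. The training
target for a capture is the mode of the 14 observations; the panel's
internal accuracy is the mode count divided by 14.

**Geometry.** All meshes are conformed to a 7859-vertex template (vertex
`i` is the same anatomical point everywhere). For each capture, the rest
mesh is aligned to the template by partial Procrustes superimposition
(rotation R, translation t minimising Σᵢ‖R xᵢ + t − yᵢ‖², no scaling), and
the peak mesh is rigidly aligned to the rest mesh on three landmarks (inner
eye corners, nose tip), removing head motion. Facial asymmetry is the
per-vertex distance between a mesh and its Procrustes-aligned mirror image
(reflection re-indexed through the template's left-right vertex pairing);
left-sided palsies are mirrored so every deficit is right-sided.

**Network.** Input 1 is the rest cloud, input 2 the peak cloud, input 3 a
one-hot expression code. Each cloud passes through a shared per-point MLP
and channel-wise max pooling (a PointNet branch, exactly permutation
invariant); the two global features and the expression code feed a
fully-connected head with one output score per expression. Training
minimises the half mean squared error ½·mean((ŷ − y)²) of the score at the
sample's own expression slot, with Adam, batch 8. 160 original captures
are augmented to 960 samples (shared yaw rotation within ±15° plus 2%
Gaussian jitter per cloud) and split 768 train / 192 test. A prediction is
correct when |ŷ − y| < 0.5.

## Worked example

```bash
palsy3d run --out runs/demo --seed 1
```

runs the whole pipeline (synthesize cohort → simulate expert panels →
consensus → build samples → augment → split → train → evaluate → render
cohort maps) and prints per-stage logs. Equivalent library use:

```python
import numpy as np
from palsy3d import (CohortSpec, make_template, synthesize_cohort,
                     reflect_lateralize, build_sample, augment_all, split,
                     AugmentationConfig, NetworkConfig,
                     PointNetGradeRegressor, evaluate)
from palsy3d.grading import (parameter_for_expression, simulate_rater_panel,
                             consensus_mode)

template = make_template(7859, seed=1)
captures, truth = synthesize_cohort(CohortSpec(master_seed=1), template)

rater_rng = np.random.default_rng(8)
originals = []
for cap in captures:
    cap = reflect_lateralize(cap, template)
    cell = simulate_rater_panel(
        int(truth[(cap.subject_id, cap.expression)]),
        parameter=parameter_for_expression(cap.expression), rng=rater_rng)
    originals.append(
        build_sample(cap, template, float(consensus_mode(cell.ravel()).mode)))

samples = augment_all(originals, AugmentationConfig(seed=2))
ds = split(samples, seed=3, mode="naive")   # flat 768 / 192 protocol
model = PointNetGradeRegressor.from_config(NetworkConfig.desk(epochs=200, seed=4))
model.fit(ds.train)
report = evaluate(model, ds.test)
for name, acc in report.accuracy.items():
    print(f"{name:16s} {acc:.3f}")
print(f"min accuracy {report.min_accuracy:.3f}  "
      f"MSE {report.mse:.3f}  R2 {report.r2:.3f}")
```

Output from this exact run (seeds as shown, ~15 min on one CPU):

```
eyebrow_raising  0.568
eye_closure      0.477
smiling          0.512
cheek_puffing    0.742
lip_puckering    0.703
min accuracy 0.477  MSE 0.704  R2 0.639
```

Each accuracy is the fraction of held-out test samples of that expression
whose predicted grade lies strictly within half a grade of the expert
consensus; `report.confusion` holds the per-expression confusion matrices
over rounded 1-5 grade bins. The regression itself is strong (R² ≈ 0.6-0.8
across seeds, monotone in the true severity); the strict half-grade
accuracies are bounded by the 2% augmentation jitter, which on a
face-sized cloud is of the same order as one grade step of movement —
`docs/methods.md` quantifies this and explains what the two split modes
(`naive` above, leakage-safe `grouped` by default) each measure.

## Command line

```
palsy3d synth  --patients 16 --controls 16 --seed 1 --out data/   # PLY meshes + manifest
palsy3d build  --data data/ --out built/ --seed 2                 # align, augment, split
palsy3d train  --data built/ --out model.npz --epochs 200         # fit the regressor
palsy3d eval   --model model.npz --data built/ --report rep.json  # accuracies, confusion
palsy3d maps   --data data/ --out maps/                           # cohort colour maps
palsy3d run    --out runs/demo --seed 1 [--dry-run]               # everything end to end
```

Exit codes: 0 success, 1 validation error, 2 runtime error.
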