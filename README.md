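# canalgrade

Quantitative grading of **lumbar central canal stenosis (LCCS)** from a
sagittal T2-weighted MRI volume plus vertebra / intervertebral-disc (IVD) /
spinal-canal segmentation masks. The package is aimed at spine-imaging
researchers who have 3D segmentations (e.g. from a U-net) and want objective,
traceable stenosis measurements and severity grades at every disc level —
without acquiring angled axial sequences.

## What it computes

For each IVD level the pipeline:

1. fits a 3D plane to the disc by PCA of its voxel coordinates — the
   eigenvector of the coordinate covariance with the smallest eigenvalue is
   the disc's through-plane axis and defines the angulation of the
   reconstructed axial view;
2. reslices the volume orthogonally to that axis into 41 planes at 0.5 mm
   spacing (mid-disc ± 10 mm), with trilinear interpolation for intensities
   and nearest-neighbour for the canal mask;
3. measures on every plane the dural sac cross-sectional area
   (CSA, mm²), the largest antero-posterior diameter (APD, mm) and the mean
   CSF signal inside the canal mask (FSL); planes within the most caudal
   15 mm of the canal are discarded (the sac tapers naturally there);
4. ranks the planes per metric (ascending — smaller is more stenotic, for
   FSL too, since CSF effacement darkens the canal) and keeps the plane
   with the lowest cumulative rank as the **most stenotic plane**;
5. divides its metrics by a single mid-vertebral reference measurement at
   the cranially adjacent vertebra (angulation = mean of the two
   neighbouring disc normals), yielding the ratio features
   rCSA / rAPD / rFSL that normalise out body-size and level differences.

The six features feed two random-forest classifiers evaluated with tenfold
cross-validation (90-10 splits): a **multiclass** model for the 4-class
ordinal severity scale (0 none … 3 severe; 208 trees, depth 46, 1 sample
per leaf, stratified folds) and a **binary** stenosis model (grades 2–3 vs
0–1; 29 trees, depth 72, 23 samples per leaf). Evaluation implements
quadratically weighted kappa (κw), ROC/AUC, the Youden-optimal operating
point (J = sensitivity + specificity − 1), operating points matched to a
reader's sensitivity or specificity, confusion-matrix summaries
(accuracy/PPV/NPV) and percentile-bootstrap confidence intervals.

A synthetic spine phantom (curved CSF-bright canal, tilted discs, stacked
vertebral bodies, grade-dependent canal constrictions and signal loss,
Rician-style noise) provides fully characterised test data, so every stage
is testable without patient images.

## Worked example

```python
from canalgrade import (PhantomSpec, generate_study, measure_study,
                        generate_feature_dataset, cross_validate, ForestConfig,
                        quadratic_weighted_kappa, roc_and_auc, youden_optimal)

# render a two-level phantom: severe stenosis at L4-L5, normal L3-L4
image, labels, truth = generate_study(
    PhantomSpec(levels={"L4-L5": 3, "L3-L4": 0}, seed=7))
records, errors = measure_study(image, labels, study_id="demo")
for r in records:
    print(f"{r.level}: CSA={r.csa:.1f} mm2  APD={r.apd:.1f} mm  "
          f"FSL={r.fsl:.0f}  rCSA={r.r_csa:.2f}")
```

prints

```
L4-L5: CSA=52.2 mm2  APD=8.0 mm  FSL=158  rCSA=0.34
L3-L4: CSA=150.2 mm2  APD=13.5 mm  FSL=390  rCSA=1.01
```

— the severely constricted L4-L5 level shows roughly a third of the
reference canal area (the phantom's generative grade-3 area factor is 0.35,
and the unconstricted tube's analytic area is 153.9 mm²), while the normal
L3-L4 level sits at its reference size. Grading a 600-level synthetic
cohort:

```python
df = generate_feature_dataset(600, seed=0)
mc = cross_validate(df, ForestConfig.multiclass(seed=0))
print(quadratic_weighted_kappa(mc.y_true, mc.oof_predictions.astype(int)))
# 0.952
bc = cross_validate(df, ForestConfig.binary(seed=0))
roc = youden = roc_and_auc(bc.oof_predictions, bc.y_true)
opt = youden_optimal(roc)
print(roc.auc, opt.sensitivity, opt.specificity)
# 0.994 0.964 0.968
```

i.e. out-of-fold κw ≈ 0.95 agreement with the generative grades and
near-perfect binary discrimination when the generative effect sizes hold.

## Command line

```
canalgrade simulate --out-dir sim --n-studies 2 --seed 0
canalgrade measure  --volume sim/phantom-0000_t2.nii.gz \
                    --labels sim/phantom-0000_labels.nii.gz --out features.csv
canalgrade train    --features features.csv --mode binary --out model.joblib
canalgrade predict  --model model.joblib --features features.csv --out pred.csv
canalgrade evaluate --predictions pred.csv --grades sim/grades.csv \
                    --mode binary --out report.json
canalgrade ablate   --features features.csv --out ablation.csv
```

Each run writes a JSON manifest (input digests, seeds, version) next to its
output. Per-level measurement failures are reported but do not fail a run.

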