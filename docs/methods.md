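# Methods

## Measurement model

The object of measurement is the dural sac as delineated by a spinal-canal
segmentation co-registered with a sagittal T2 volume. All geometry is done
in physical (mm) LPS patient coordinates derived from the image header;
nothing assumes axis-aligned acquisitions.

**Disc plane.** Each IVD's orientation is estimated by PCA of the physical
coordinates of its labelled voxels. The eigenvector with the smallest
eigenvalue of the 3×3 coordinate covariance is the through-plane (normal)
axis; it is sign-fixed to point cranially so stack offsets have an
unambiguous above/below meaning. The fit requires at least 10 voxels;
smaller labels raise a level-skipped error carrying the level id. The
in-plane basis is completed with the patient antero-posterior axis
projected into the plane (second axis), so the AP diameter is measured
along an anatomically meaningful direction even in a tilted plane; the
first axis is the orthogonal complement. If the plane is orthogonal to AP
(pathological input), the left-right axis is projected instead.

**Slice stack.** The volume is resampled into 41 planes at 0.5 mm steps
spanning mid-disc ± 10 mm — a 2 cm range that covers a healthy disc and
reaches the endplates of degenerate ones. Intensities are interpolated
trilinearly; the canal mask by nearest neighbour (mask fractions have no
defined meaning). In-plane sampling is isotropic at the same 0.5 mm pitch
over the canal's projected bounding box plus a 10 mm margin; samples
outside the volume are zero-padded and logged. The 41-plane count follows
from the constructive definition (mid-slice plus 20 on each side); note
41 × 0.5 mm sample centres span exactly the stated 2 cm.

**Per-plane metrics.**

* CSA = canal-mask pixel count × pixel area. Empty masks yield 0 but the
  plane is flagged invalid rather than measured, so a segmentation gap can
  never masquerade as total stenosis.
* APD = (max − min) of mask-pixel centres projected on the in-plane AP
  axis, plus one pixel spacing (unbiased for axis-aligned shapes).
  Disconnected mask components contribute to the same extent: the measure
  is the largest possible AP distance.
* FSL = arithmetic mean of the intensities under the mask. Lower values
  mean CSF effacement.

**Caudal exclusion.** Planes whose centre lies strictly within 15 mm of the
most caudal canal voxel — measured along the patient cranio-caudal axis —
are discarded; the dural sac tapers physiologically there. The boundary is
exclusive: a plane at exactly 15.0 mm is kept. Applying the rule along the
patient axis (not the canal centreline) is a deliberate simplification;
the two differ by < cos(tilt) ≈ a few percent for lumbar canal tilts.

**Most stenotic plane.** Valid planes are ranked ascending per metric with
mean ranks on ties, and the plane minimising the CSA+APD+FSL rank sum is
selected. FSL ranks ascending like the areas because severity tracks CSF
obliteration. Rank-sum ties break toward smaller CSA, then the more caudal
offset — deterministic and severity-biased. Only the winning plane's
metrics are kept.

**Reference and ratios.** The reference is a single mid-vertebral plane at
the centroid of the cranially adjacent vertebra, with normal equal to the
renormalised mean of the two neighbouring disc normals (the spherical
bisector; a single neighbour passes through unchanged). Ratios are level
value / reference value. Levels without a usable reference — e.g. T12-L1
when T12 is absent from the mask, or a reference plane falling in the
caudal exclusion zone — keep absolute metrics but carry null ratios and
are excluded from classifier training rather than imputed.

## Classifiers

Features are the six metrics; labels the ordinal severity grades (0 none,
1 mild, 2 moderate, 3 severe) or their binarisation (2–3 = stenosis).
Hyperparameters are fixed constants of the two modes: multiclass 208 trees
/ depth 46 / 1 sample per leaf with stratified tenfold CV; binary 29 trees
/ depth 72 / 23 samples per leaf with plain tenfold CV (both 90-10
splits). Forest internals beyond these (bootstrap, feature subsampling)
follow scikit-learn defaults and are recorded in the model manifest. All
randomness is seeded (default 0; per-fold forests use seed + fold index).
Performance is always computed on pooled out-of-fold predictions; folds
are by IVD level, matching the stated design (a patient-grouped variant
would be a different estimand and is not implemented). The ablation suite
reruns CV for nine fixed subsets ("No/Only CSA|APD|FSL", absolute-only,
relative-only, all six).

## Statistics

κw uses quadratic weights w_ij = (i−j)²; it is undefined (error, not 1.0)
when both vectors are a single constant grade. AUC is the Mann-Whitney
normalisation with ties counted half; the ROC keeps *every* achievable
operating point (no convex-hull pruning) because matched operating points
and tie rules must scan the full set. Youden's optimum breaks ties toward
the lower threshold; reader-matched points minimise the distance to the
target on one axis, breaking ties toward higher J. Probability-at-threshold
classification is inclusive (p ≥ t). Confusion matrices reconstructed from
(sensitivity, specificity, class sizes) round TP/TN to whole levels, which
is exactly invertible. Confidence intervals are 95% percentile bootstrap
over IVD levels, B = 1000, seeded; replicates where a metric is undefined
are dropped, with a warning above 5%.

## Synthetic phantom

`generate_study` renders a curved CSF-bright canal (tube of radius 7 mm,
lordotic sine curve of 6 mm amplitude) through seven stacked elliptic
vertebral bodies, with flat-ellipsoid discs (32 × 26 × 7 mm) whose planes
follow the local curve tangent unless explicit tilts are given. Severity
at a level scales the canal's cross-sectional area (Gaussian axial profile,
σ = 4 mm, centred on the disc) by 1 / 0.8 / 0.55 / 0.35 and the CSF signal
by 1 / 0.85 / 0.6 / 0.4 for grades 0–3 — package choices giving clearly
ordered but overlapping severities, not published measurements. Intensities
(CSF 400, disc 200, bone 150, background 100, additive Gaussian noise
SD 10, Rician optional) are arbitrary T2-like units; only FSL ratios are
intensity-scale-free. Voxel pitch defaults to 0.8 mm isotropic. Labels
delineate the generated shapes exactly, so measurement error observed in
tests is attributable to resampling and discretisation alone.

`generate_cohort` draws per-level grades i.i.d. from a severity mix
defaulting to 46.4 / 24.7 / 16.7 / 12.2% — a symptomatic-referral case mix
— and returns phantom specs (rendered on demand) plus the grade table.
`generate_feature_dataset` skips volumetrics and samples the six features
directly from grade-conditional independent Gaussians whose means follow
typical dural-sac morphometry (e.g. CSA 180 → 70 mm², APD 15 → 7 mm from
grade 0 to 3) with adjacent grades separated by roughly one SD per metric.

What the phantom does *not* emulate: real segmentation error and
inter-feature correlation structure, disc herniation morphology, facet or
ligamentous contributions, intensity inhomogeneity, partial-volume CSF.
Passing tests therefore demonstrate the correctness of the geometry,
measurement, selection and statistical machinery and the attainability of
reader-grade performance under a faithful generative signal — not clinical
performance on patient images.

## Problem sizes and numerics

The test suite and the acceptance script use a 600-level feature cohort
for classifier experiments, two-level rendered phantoms for volumetric
end-to-end checks, and 0.5 mm voxel pitch for the tilted-cylinder oracle
suite — sizes at which the geometric discretisation error of a 6 mm-radius
tube stays within ~3% of the analytic section area. Orthonormality of
plane frames is enforced to 1e-6; degenerate inputs (empty masks, single
constant grade vectors, single-class label sets) raise typed errors rather
than returning sentinel values. Feature CSVs round to 4 decimals — already
far below the 0.5 mm sampling resolution.

## Known limitations

* Most-stenotic-plane selection is an order statistic: at grade 0 it
  biases level metrics slightly below the single-plane reference (ratios
  ≈ 0.93–1.0 under noise), which is inherent to the method, not a defect.
* The caudal rule uses the patient axis, not canal arc length.
* Grades are treated as nominal classes by the forests; the ordinal
  structure enters only through the evaluation (κw).
* The phantom's independence of feature noise across metrics makes the
  synthetic grading task easier than correlated real measurements at the
  same marginal SDs; effect sizes were chosen for overlap to compensate.
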