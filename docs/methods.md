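# Methods

## Data model and conventions

A delineation is a 3D boolean voxel grid with strictly positive physical
spacing (mm per voxel along each axis). Coordinates are 0-based voxel
indices; the physical position of a voxel is its index times the spacing
(voxel-centre convention). Only relative distances enter any metric, so no
origin or orientation information is needed; the NIfTI reader records the
affine orientation solely for provenance. 2D inputs are promoted to shape
`(X, Y, 1)`.

A *structure* is a maximal connected component of a mask. The default
connectivity is 26 (vertex-connected): lesions contoured slice-by-slice
frequently touch only diagonally between slices, and face-connectivity (6)
would fragment one lesion into several spurious structures, corrupting
every count-based metric. Connectivity is configurable (6/18/26) and the
component count is monotone non-increasing in connectivity, which the
tests assert. Labels are assigned deterministically in ascending order of
each component's lexicographically smallest voxel, so reports are
reproducible across runs and platforms.

The *boundary* of a mask is the morphological inner boundary: in-mask
voxels with at least one of their six face neighbours out-of-mask, with
voxels beyond the grid edge counting as out-of-mask. This is the standard
voxel-level surface definition; no sub-voxel (marching-cubes) surface is
extracted, so distances are voxel-centre to voxel-centre. At 1 mm grids
the discretisation error is well below the inter-observer variability the
metrics are meant to resolve.

## Patient-wise metrics

Dice is computed on whole-mask voxel counts. When both masks are empty the
ratio is 0/0; the package returns 1.0 (an empty prediction of an empty
truth is correct) but emits a warning and flags the report so cohort
statistics can exclude the case. One mask empty gives Dice 0 with no
warning.

Boundary distances are *directed*: one minimum distance per predicted
boundary voxel to the ground-truth boundary, honouring anisotropic spacing.
A symmetric option (pooling both directions) exists behind
`symmetric_distances` but is off by default — the directed form is the
definitional one here, and directedness is itself informative (the tests
pin an asymmetric pair where the two directions differ). Summaries:

- HD95 — 95th percentile with linear interpolation between closest ranks
  (`numpy.percentile`, `method="linear"`). The percentile convention is
  pinned for bit-reproducibility; nearest-rank differs by at most one
  order-statistic gap.
- ASD — arithmetic mean; MSD — median.

Nearest-neighbour queries use a KD-tree over the reference boundary
points. The test suite checks the tree against an all-pairs O(n·m) brute
force to 1e-9 mm on random mask pairs, and checks translation invariance
and linear scaling with spacing.

## Structure matching and detection metrics

The coverage fraction of a structure is the fraction of *its* voxels
covered by the entire opposite mask — the denominator is always the
queried structure, and the reference is never a single opposing structure.
This makes matching direction-dependent by design: a small predicted blob
inside a large truth structure is a true positive of the prediction
(CFrac 1.0) while the truth structure may still be missed (its own
coverage being small). Threshold 0.5, compared strictly (`>`); both the
value and strictness are configurable. At exactly 0.5 a structure is
therefore *not* detected — the boundary case is ambiguous in common usage,
and the strict reading was chosen and pinned.

From the two directions: PPV = TP_pred/(TP_pred+FP) over predicted
structures, sensitivity = TP_truth/(TP_truth+FN) over truth structures.
True negatives do not exist at the structure level, so neither accuracy
nor specificity is defined. Any ratio with zero denominator is reported as
missing (`null` in JSON, NaN-excluded in cohort means) and flagged —
coercing to 0 or 1 would bias cohort averages in opposite directions.

`Volume_true` / `Volume_false` are the *mean* volumes of detected /
undetected predicted structures. The mean (rather than sum) convention is
a package decision; with a single qualifying structure the two coincide.
Volumes are computed in mm³ and reported in cm³.

## Structure-wise surface distances

HD95/ASD/MSD are recomputed per detected predicted structure, with
distances from that structure's boundary to the *whole* ground-truth
boundary; undetected structures are excluded entirely. Using the whole
truth boundary (rather than only the overlapped truth structure) is the
minimal reading and can only understate, never overstate, the error: the
nearest truth boundary voxel is free to come from any structure. The
choice matters only when truth structures lie close together.

This is the package's central contrast: a prediction equal to the truth
plus one disjoint false blob has structure-wise distances identically zero
while the patient-wise HD95 grows with the blob's offset. The acceptance
suite asserts this exactly, and asserts that deleting the blob equalises
the two views.

Cohort aggregation takes the per-patient mean of structure-wise metrics
first, then the cross-patient mean ± sample standard deviation (ddof 1),
so patients with many nodes do not dominate. The pooling order is
configurable in principle (it is a genuine open choice); per-patient-first
is the default and the one the CLI uses.

## CT windowing

`hu_window` clips CT intensities to `[centre − width/2, centre + width/2]`
and rescales linearly to [0, 1]. Defaults: centre 70 HU, width 200 HU
(range [−30, 170] HU) — a narrow soft-tissue window centred on typical
tumour/node intensities in contrast-enhanced CT. Rescaling to [0, 1] after
clipping (rather than keeping clipped HU) is pinned for determinism of
downstream consumers; the transform is monotone, saturating, and
idempotent after affine re-mapping back to HU, all property-tested.

## Synthetic phantoms

The generator renders multi-ellipsoid phantoms (a voxel is in-mask iff its
centre lies inside any ellipsoid) and perturbs them into controlled error
modes: whole-mask translation, face-connected dilation/erosion, insertion
of a disjoint spherical false structure (placement seeded, with a minimum
clearance enforced via a distance transform), deletion of one labelled
structure, and seeded boundary jitter. Ellipsoids were chosen over
realistic tumour shapes because every expected volume, overlap and
distance then has an analytic or brute-force-checkable value; the default
phantom sizes (radii 4–7 mm on ~1 mm grids, two structures per patient)
are in the range of small head-and-neck nodal volumes. All randomness
derives from explicit integer seeds; identical specs render bit-identically.

What the phantoms do *not* emulate: irregular tumour morphology, contour
raggedness of real CNN output, inter-slice anisotropy artefacts, and
intensity content (no PET/CT simulation). Passing tests therefore
establish the *metrics'* correctness on arbitrary binary masks — which is
the package's job — not any model's clinical performance.

## Numerical and degenerate-input choices

- Distances: exact Euclidean on voxel centres; KD-tree results verified
  against brute force to 1e-9 mm.
- Percentile: linear interpolation, pinned (see above).
- Empty boundary on either side → `EmptyBoundaryError` at the distance
  layer; the report layer converts it to a missing summary plus a flag,
  never a sentinel number.
- Tie-breaks: none needed — minima over distances and strict threshold
  comparison are unambiguous; component labelling order is pinned
  lexicographically.
- Report JSON uses fixed key order and default float repr, so identical
  inputs and configuration give byte-identical output.

## Problem sizes used in the validation suite

Oracle-equivalence checks run 200 random mask pairs at grids up to 10³
(brute force O(n²) stays cheap there); closed-form distance checks use
cubes of edge 20; the contamination phantom is a 56×32×32 grid with two
spheres; the synthetic acceptance cohort has 10 phantom patients. These
sizes keep every analytic or brute-force reference exact while exercising
all code paths; the metrics themselves are linear or n·log n in boundary
size and handle clinical volumes (≈512³) without modification.

## Known limitations

- Voxel-centre distances slightly underestimate sub-voxel surface
  distances for coarse spacing; mesh-based surfaces are out of scope.
- DICOM-RT structure sets are not parsed; convert to NIfTI masks first.
- The coverage-fraction rule matches each structure against the whole
  opposite mask; several small predicted blobs jointly covering one truth
  structure can each be true positives while no single one resembles it.
  This is inherent to the definition, not an implementation artefact.
- Dilation/erosion perturbations use face connectivity only.
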