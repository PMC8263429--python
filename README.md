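# structwise

Patient-wise **and** structure-wise evaluation of multi-structure tumour
delineations against an expert ground truth.

Automatic delineation models for radiotherapy (e.g. CNNs contouring the
gross tumour volume and involved lymph nodes in head-and-neck cancer) are
usually scored with whole-mask metrics: the Dice overlap and surface
distances between the complete predicted mask and the complete ground
truth. A typical patient has *several* disjoint malignant structures — a
primary tumour plus involved nodes — and whole-mask metrics hide exactly
the errors that matter clinically: a missed node barely moves Dice, and a
single small false-positive blob far from the tumour inflates the
Hausdorff distance to tens of millimetres even when every real structure
is contoured perfectly. `structwise` implements a structure-level
framework that separates *detection* quality from *contour* quality.

## Metrics

With `X` the ground-truth mask and `X̂` the prediction (3D binary voxel
grids with physical spacing):

**Patient-wise.**
`Dice = 2|X ∩ X̂| / (|X| + |X̂|)`. For every boundary voxel `i` of the
prediction, `D_i = min_j dist(x̂_i, x_j)` is its Euclidean distance in mm
to the nearest ground-truth boundary voxel; from the multiset `{D_i}`,
**HD95** is the 95th percentile, **ASD** the mean and **MSD** the median.

**Structure-wise.** Each connected component (structure) `X̂_k` of the
prediction is matched to the truth by its *coverage fraction*

    CFrac(X̂_k, X) = |X̂_k ∩ X| / |X̂_k|,

and counts as detected when `CFrac > 0.5` (strict, configurable). From the
two matching directions:

- `PPV = TP_pred / (TP_pred + FP)` — fraction of predicted structures that
  are real;
- `Sensitivity = TP_truth / (TP_truth + FN)` — fraction of true structures
  that were found (a truth structure counts as found when the *whole*
  predicted mask covers more than half of it);
- `Volume_true` / `Volume_false` — mean volume of detected / undetected
  predicted structures (cm³);
- structure-wise HD95/ASD/MSD — computed per *detected* predicted
  structure against the truth boundary, so false positives cannot
  contaminate them.

Ratios with a zero denominator (e.g. PPV for an empty prediction) are
reported as missing and flagged, never coerced to 0 or 1. A CT
preprocessing helper applies the soft-tissue Hounsfield window
(centre 70 HU, width 200 HU → [−30, 170] HU, rescaled to [0, 1]).

## Worked example

The built-in demo constructs a pair where the prediction has three
structures — two overlapping the truth above the coverage threshold, one
disjoint — and the truth has two, of which one is covered above threshold:

```sh
structwise demo
```

prints (abridged):

```json
{
  "patientwise": { "dice": 0.4937, "hd95_mm": 18.0, "asd_mm": 1.528, "msd_mm": 0.0 },
  "detection": {
    "tp_cnn": 2, "fp": 1, "tp_gt": 1, "fn": 1,
    "ppv_cnn": 0.6667, "sens_gt": 0.5,
    "volume_true_cm3": 0.216, "volume_false_cm3": 0.018
  },
  "structurewise": [
    { "label": 1, "cfrac": 0.8, "hd95_mm": 2.0, "asd_mm": 0.441, "msd_mm": 0.0 },
    { "label": 2, "cfrac": 1.0, "hd95_mm": 1.0, "asd_mm": 1.0, "msd_mm": 1.0 }
  ]
}
```

Two of three predicted structures are true positives (PPV = 2/3 ≈ 0.7),
one of two truth structures was found (sensitivity = 0.5), and the false
structure — which drives the patient-wise HD95 to 18 mm — contributes
nothing to the structure-wise distances.

Evaluating real masks and cohorts:

```sh
structwise evaluate --truth gt.nii.gz --pred cnn.nii.gz --out report.json
structwise cohort --pairs manifest.csv --out summary.csv
```

The manifest is a CSV with columns `patient_id, truth, prediction`
(paths relative to the manifest). Cohort aggregation reports mean ± sample
standard deviation per metric, excluding (and counting) patients where a
metric is undefined.

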