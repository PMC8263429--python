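"""Voxel-overlap and structure-detection metrics.

Patient-wise overlap is the Dice score

    Dice(X, X_hat) = |X ∩ X_hat| / (|X|/2 + |X_hat|/2),

computed over whole masks.  Structure detection is decided per connected
component via the coverage fraction

    CFrac(S, R) = |S ∩ R| / |S|,

the fraction of structure S's voxels covered by the opposite mask R.  A
structure with CFrac strictly above the threshold (default 0.5) counts as
detected.  Applying the rule in both directions yields a structure-level
positive predictive value (fraction of predicted structures that are real)
and sensitivity (fraction of true structures that were found) — metrics a
whole-mask Dice cannot express, because small false-positive components
barely move voxel overlap while being clinically important.

Note the deliberate asymmetry of CFrac: the denominator is always the
*queried* structure, and the reference is the entire opposite mask, not
any single opposing structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mask import BinaryMask, Structure, StructureSet, label_components

__all__ = [
    "MatchEntry",
    "MatchTable",
    "DetectionSummary",
    "dice",
    "coverage_fraction",
    "match_structures",
    "detection_summary",
]

DEFAULT_THRESHOLD = 0.5


class EmptyMaskWarning(UserWarning):
    """Raised when a metric is evaluated on two empty masks."""


@dataclass(frozen=True)
class MatchEntry:
    label: int
    cfrac: float
    detected: bool
    volume_mm3: float


@dataclass(frozen=True)
class MatchTable:
    """Per-structure coverage fractions for one matching direction.

    ``direction`` is ``"prediction_vs_truth"`` (each predicted structure
    against the whole truth mask) or ``"truth_vs_prediction"`` (each truth
    structure against the whole predicted mask).
    """

    direction: str
    entries: tuple[MatchEntry, ...]
    threshold: float

    @property
    def n_detected(self) -> int:
        return sum(e.detected for e in self.entries)

    @property
    def n_undetected(self) -> int:
        return len(self.entries) - self.n_detected

    def detected_labels(self) -> list[int]:
        return [e.label for e in self.entries if e.detected]


@dataclass(frozen=True)
class DetectionSummary:
    """Structure-level detection counts and derived rates.

    ``ppv_cnn`` = TP_pred / (TP_pred + FP) over predicted structures;
    ``sens_gt`` = TP_truth / (TP_truth + FN) over ground-truth structures.
    ``volume_true_mm3`` / ``volume_false_mm3`` are the mean volumes of
    detected / undetected predicted structures.  Each quantity is ``None``
    (never 0) when its denominator is zero — with no predicted structures a
    PPV does not exist, and true-negative structures cannot be counted at all.
    """

    tp_cnn: int
    fp: int
    tp_gt: int
    fn: int
    ppv_cnn: float | None
    sens_gt: float | None
    volume_true_mm3: float | None
    volume_false_mm3: float | None


def _as_bool_array(mask: BinaryMask) -> np.ndarray:
    return mask.data


def dice(
    truth: BinaryMask,
    prediction: BinaryMask,
    *,
    both_empty_value: float = 1.0,
) -> float:
    """Dice overlap of two masks on the same grid.

    Symmetric in its arguments and in [0, 1].  When both masks are empty the
    ratio is 0/0; by default 1.0 is returned (a prediction that correctly
    finds nothing is not an error) together with an ``EmptyMaskWarning`` so
    cohort statistics can exclude the case.
    """
    truth.require_same_geometry(prediction)
    a = _as_bool_array(truth)
    b = _as_bool_array(prediction)
    na = int(a.sum())
    nb = int(b.sum())
    if na == 0 and nb == 0:
        warnings.warn(
            "Dice of two empty masks is undefined; returning the configured "
            f"both-empty value {both_empty_value}",
            EmptyMaskWarning,
            stacklevel=2,
        )
        return float(both_empty_value)
    inter = int((a & b).sum())
    return 2.0 * inter / (na + nb)


def coverage_fraction(structure: Structure, reference_mask: BinaryMask) -> float:
    """Fraction of the structure's voxels that lie inside the reference mask."""
    coords = structure.voxel_coords
    shape = np.asarray(reference_mask.shape)
    if (coords < 0).any() or (coords >= shape).any():
        raise ValueError(
            f"structure {structure.label} extends outside the reference grid "
            f"{reference_mask.shape}"
        )
    inside = reference_mask.data[coords[:, 0], coords[:, 1], coords[:, 2]]
    return float(inside.sum()) / coords.shape[0]


def match_structures(
    queried: StructureSet,
    reference: BinaryMask,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    direction: str = "prediction_vs_truth",
    strict: bool = True,
) -> MatchTable:
    """Classify every queried structure as detected or not via CFrac.

    ``detected`` is ``cfrac > threshold`` (strict, the default) or
    ``cfrac >= threshold`` when ``strict=False``.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    queried.source_mask.require_same_geometry(reference)
    entries = []
    for s in queried:
        cf = coverage_fraction(s, reference)
        detected = cf > threshold if strict else cf >= threshold
        entries.append(
            MatchEntry(label=s.label, cfrac=cf, detected=detected, volume_mm3=s.volume_mm3)
        )
    return MatchTable(direction=direction, entries=tuple(entries), threshold=threshold)


def _mean_or_none(values: list[float]) -> float | None:
    return float(np.mean(values)) if values else None


def detection_summary(
    truth: StructureSet | BinaryMask,
    prediction: StructureSet | BinaryMask,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    connectivity: int = 26,
    strict: bool = True,
) -> DetectionSummary:
    """Structure-level TP/FP/FN counts and PPV/sensitivity for one mask pair.

    Predicted structures with CFrac above threshold against the whole truth
    mask are true positives of the prediction (the rest false positives);
    truth structures with CFrac above threshold against the whole predicted
    mask are true positives of the ground truth (the rest false negatives).
    """
    if isinstance(truth, BinaryMask):
        truth = label_components(truth, connectivity)
    if isinstance(prediction, BinaryMask):
        prediction = label_components(prediction, connectivity)
    truth.source_mask.require_same_geometry(prediction.source_mask)

    pred_matches = match_structures(
        prediction, truth.source_mask, threshold,
        direction="prediction_vs_truth", strict=strict,
    )
    truth_matches = match_structures(
        truth, prediction.source_mask, threshold,
        direction="truth_vs_prediction", strict=strict,
    )

    tp_cnn = pred_matches.n_detected
    fp = pred_matches.n_undetected
    tp_gt = truth_matches.n_detected
    fn = truth_matches.n_undetected

    vols_true = [e.volume_mm3 for e in pred_matches.entries if e.detected]
    vols_false = [e.volume_mm3 for e in pred_matches.entries if not e.detected]

    return DetectionSummary(
        tp_cnn=tp_cnn,
        fp=fp,
        tp_gt=tp_gt,
        fn=fn,
        ppv_cnn=tp_cnn / (tp_cnn + fp) if (tp_cnn + fp) > 0 else None,
        sens_gt=tp_gt / (tp_gt + fn) if (tp_gt + fn) > 0 else None,
        volume_true_mm3=_mean_or_none(vols_true),
        volume_false_mm3=_mean_or_none(vols_false),
    )
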