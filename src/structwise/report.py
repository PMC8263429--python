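"""Per-patient evaluation reports and cohort aggregation.

``evaluate_pair`` runs the complete metric panel for one (truth, prediction)
mask pair: patient-wise Dice and surface distances (HD95/ASD/MSD), the
coverage-fraction match tables in both directions, the structure-level
detection summary (PPV, sensitivity, true/false structure volumes) and the
per-structure surface distances for detected predicted structures.

Undefined quantities (empty masks, zero denominators) are reported as
missing values — never coerced to 0 or 1 — and every such case adds a flag
string, so cohort statistics can exclude them and report how many were
excluded.  Report generation is pure: same masks + same configuration give
byte-identical JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mask import BinaryMask, label_components
from .overlap import (
    DetectionSummary,
    MatchTable,
    detection_summary,
    dice,
    match_structures,
)
from .surface import SurfaceSummary, patientwise_surface, structurewise_surface

__all__ = [
    "EvalConfig",
    "StructureResult",
    "EvaluationReport",
    "CohortSummary",
    "evaluate_pair",
    "summarize_cohort",
]

MM3_PER_CM3 = 1000.0


@dataclass(frozen=True)
class EvalConfig:
    """Knobs that every reported number depends on.

    threshold:    coverage fraction above which a structure counts as detected
    strict:       detected iff cfrac > threshold (True) or >= threshold (False)
    connectivity: voxel connectivity defining a structure (6, 18 or 26)
    symmetric_distances: pool prediction->truth and truth->prediction
                  boundary distances instead of the directed default
    """

    threshold: float = 0.5
    strict: bool = True
    connectivity: int = 26
    symmetric_distances: bool = False

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "strict": self.strict,
            "connectivity": self.connectivity,
            "symmetric_distances": self.symmetric_distances,
        }


@dataclass(frozen=True)
class StructureResult:
    """Metrics for one detected predicted structure."""

    label: int
    cfrac: float
    volume_cm3: float
    surface: SurfaceSummary


@dataclass(frozen=True)
class EvaluationReport:
    patient_id: str
    config: EvalConfig
    dice: float | None
    patientwise: SurfaceSummary | None
    detection: DetectionSummary
    prediction_matches: MatchTable
    truth_matches: MatchTable
    structurewise: tuple[StructureResult, ...]
    flags: tuple[str, ...] = field(default_factory=tuple)

    # -- derived conveniences ------------------------------------------------
    @property
    def structurewise_mean(self) -> dict[str, float | None]:
        """Per-patient mean of the structure-wise distance metrics (None if no
        detected structures)."""
        if not self.structurewise:
            return {"hd95_mm": None, "asd_mm": None, "msd_mm": None}
        return {
            key: float(np.mean([getattr(r.surface, key) for r in self.structurewise]))
            for key in ("hd95_mm", "asd_mm", "msd_mm")
        }

    def to_dict(self) -> dict:
        det = self.detection
        return {
            "patient_id": self.patient_id,
            "config": self.config.as_dict(),
            "patientwise": {
                "dice": self.dice,
                "hd95_mm": self.patientwise.hd95_mm if self.patientwise else None,
                "asd_mm": self.patientwise.asd_mm if self.patientwise else None,
                "msd_mm": self.patientwise.msd_mm if self.patientwise else None,
            },
            "detection": {
                "tp_cnn": det.tp_cnn,
                "fp": det.fp,
                "tp_gt": det.tp_gt,
                "fn": det.fn,
                "ppv_cnn": det.ppv_cnn,
                "sens_gt": det.sens_gt,
                "volume_true_cm3": (
                    det.volume_true_mm3 / MM3_PER_CM3
                    if det.volume_true_mm3 is not None else None
                ),
                "volume_false_cm3": (
                    det.volume_false_mm3 / MM3_PER_CM3
                    if det.volume_false_mm3 is not None else None
                ),
            },
            "structurewise": [
                {
                    "label": r.label,
                    "cfrac": r.cfrac,
                    "volume_cm3": r.volume_cm3,
                    "hd95_mm": r.surface.hd95_mm,
                    "asd_mm": r.surface.asd_mm,
                    "msd_mm": r.surface.msd_mm,
                }
                for r in self.structurewise
            ],
            "flags": list(self.flags),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=False)


def evaluate_pair(
    truth: BinaryMask,
    prediction: BinaryMask,
    config: EvalConfig | None = None,
    patient_id: str = "",
) -> EvaluationReport:
    """Compute the full patient-wise + structure-wise metric panel for one pair."""
    config = config or EvalConfig()
    truth.require_same_geometry(prediction)
    flags: list[str] = []

    truth_empty = truth.is_empty
    pred_empty = prediction.is_empty
    if truth_empty:
        flags.append("truth mask is empty")
    if pred_empty:
        flags.append("prediction mask is empty")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # both-empty handled via flags here
        d = dice(truth, prediction)
    if truth_empty and pred_empty:
        flags.append("dice undefined for two empty masks; reported as 1.0")

    truth_set = label_components(truth, config.connectivity)
    pred_set = label_components(prediction, config.connectivity)

    det = detection_summary(
        truth_set, pred_set, config.threshold, strict=config.strict
    )
    if det.ppv_cnn is None:
        flags.append("PPV undefined: no predicted structures")
    if det.sens_gt is None:
        flags.append("sensitivity undefined: no truth structures")

    pred_matches = match_structures(
        pred_set, truth, config.threshold,
        direction="prediction_vs_truth", strict=config.strict,
    ) if not pred_empty else MatchTable(
        direction="prediction_vs_truth", entries=(), threshold=config.threshold
    )
    truth_matches = match_structures(
        truth_set, prediction, config.threshold,
        direction="truth_vs_prediction", strict=config.strict,
    ) if not truth_empty else MatchTable(
        direction="truth_vs_prediction", entries=(), threshold=config.threshold
    )

    if truth_empty or pred_empty:
        pw = None
        flags.append("patient-wise surface distances undefined (empty boundary)")
    else:
        pw = patientwise_surface(
            truth, prediction, symmetric=config.symmetric_distances
        )

    structure_results: list[StructureResult] = []
    if not truth_empty and pred_matches.n_detected:
        by_label = {e.label: e for e in pred_matches.entries}
        for label, summary in structurewise_surface(
            truth, pred_set, pred_matches, symmetric=config.symmetric_distances
        ):
            entry = by_label[label]
            structure_results.append(
                StructureResult(
                    label=label,
                    cfrac=entry.cfrac,
                    volume_cm3=entry.volume_mm3 / MM3_PER_CM3,
                    surface=summary,
                )
            )
    elif not pred_empty and pred_matches.n_detected == 0:
        flags.append("no detected predicted structures; structure-wise distances empty")

    return EvaluationReport(
        patient_id=patient_id,
        config=config,
        dice=d,
        patientwise=pw,
        detection=det,
        prediction_matches=pred_matches,
        truth_matches=truth_matches,
        structurewise=tuple(structure_results),
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# cohort aggregation


#: metrics pooled across patients; structure-wise distances are averaged
#: within each patient first so node-rich patients do not dominate
_PATIENT_METRICS = [
    ("dice", lambda r: r.dice),
    ("patientwise_hd95_mm", lambda r: r.patientwise.hd95_mm if r.patientwise else None),
    ("patientwise_asd_mm", lambda r: r.patientwise.asd_mm if r.patientwise else None),
    ("patientwise_msd_mm", lambda r: r.patientwise.msd_mm if r.patientwise else None),
    ("structurewise_hd95_mm", lambda r: r.structurewise_mean["hd95_mm"]),
    ("structurewise_asd_mm", lambda r: r.structurewise_mean["asd_mm"]),
    ("structurewise_msd_mm", lambda r: r.structurewise_mean["msd_mm"]),
    ("ppv_cnn", lambda r: r.detection.ppv_cnn),
    ("sens_gt", lambda r: r.detection.sens_gt),
    (
        "volume_true_cm3",
        lambda r: (
            r.detection.volume_true_mm3 / MM3_PER_CM3
            if r.detection.volume_true_mm3 is not None else None
        ),
    ),
    (
        "volume_false_cm3",
        lambda r: (
            r.detection.volume_false_mm3 / MM3_PER_CM3
            if r.detection.volume_false_mm3 is not None else None
        ),
    ),
]


@dataclass(frozen=True)
class CohortSummary:
    """Mean +/- sample std per metric over the patients where it is defined."""

    table: pd.DataFrame
    n_patients: int
    n_zero_detected: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6g")


def summarize_cohort(reports: list[EvaluationReport]) -> CohortSummary:
    """Aggregate per-patient reports into cohort mean +/- std per metric.

    Structure-wise distances enter as per-patient means.  Patients where a
    metric is undefined are excluded from that metric's statistics and
    counted in ``n_excluded``; the sample standard deviation (ddof=1) is NaN
    for a single defined value.
    """
    if not reports:
        raise ValueError("cannot summarise an empty cohort")
    rows = []
    for name, getter in _PATIENT_METRICS:
        values = [getter(r) for r in reports]
        defined = np.array([v for v in values if v is not None], dtype=float)
        rows.append(
            {
                "metric": name,
                "mean": float(defined.mean()) if defined.size else np.nan,
                "std": float(defined.std(ddof=1)) if defined.size > 1 else np.nan,
                "n_defined": int(defined.size),
                "n_excluded": len(values) - int(defined.size),
            }
        )
    n_zero = sum(1 for r in reports if r.detection.tp_cnn == 0)
    return CohortSummary(
        table=pd.DataFrame(rows),
        n_patients=len(reports),
        n_zero_detected=n_zero,
    )
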