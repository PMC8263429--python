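"""Boundary-distance metrics: HD95, ASD and MSD, patient-wise and structure-wise.

For every boundary voxel i of the predicted mask, the directed distance

    D_i = min_j dist(x_hat_i, x_j)

is the Euclidean distance in physical mm (voxel-centre convention, honouring
anisotropic spacing) to the nearest ground-truth boundary voxel.  From the
multiset {D_i}:

* HD95 — 95th percentile (linear interpolation between closest ranks):
  severity of the largest delineation errors, robust to single outliers;
* ASD  — arithmetic mean: typical error;
* MSD  — median: typical error, robust to tails.

The set is *directed* (prediction → truth); a symmetric variant pooling
both directions is available behind a flag but is not the default.

Patient-wise summaries use the whole-mask boundaries, so a single false
structure far from the truth inflates HD95 by its full offset even when
every real structure is contoured perfectly.  The structure-wise variant
therefore computes one summary per *detected* predicted structure
(coverage fraction above threshold, see :mod:`structwise.overlap`) against
the truth boundary, excluding undetected structures entirely — separating
contour quality on found structures from detection errors.

Nearest-neighbour queries run on a KD-tree over the reference boundary
points; a brute-force all-pairs oracle lives in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mask import BinaryMask, BoundarySurface, StructureSet, extract_boundary, structure_to_mask
from .overlap import MatchTable

__all__ = [
    "DistanceSet",
    "SurfaceSummary",
    "EmptyBoundaryError",
    "boundary_distances",
    "summarize",
    "patientwise_surface",
    "structurewise_surface",
]


class EmptyBoundaryError(ValueError):
    """Distance computation requested against an empty boundary surface."""


@dataclass(frozen=True)
class DistanceSet:
    """Directed boundary-to-boundary distance multiset, one entry per source voxel."""

    distances: np.ndarray  # shape (n,), mm, all >= 0
    source: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "distances", np.asarray(self.distances, dtype=float))


@dataclass(frozen=True)
class SurfaceSummary:
    """HD95 / ASD / MSD of one distance multiset, in mm."""

    hd95_mm: float
    asd_mm: float
    msd_mm: float
    n_distances: int

    def as_dict(self) -> dict[str, float]:
        return {
            "hd95_mm": self.hd95_mm,
            "asd_mm": self.asd_mm,
            "msd_mm": self.msd_mm,
            "n_distances": self.n_distances,
        }


def boundary_distances(
    source: BoundarySurface,
    reference: BoundarySurface,
    *,
    source_name: str = "mask",
) -> DistanceSet:
    """Minimum physical distance from each source boundary voxel to the reference boundary."""
    if source.is_empty or reference.is_empty:
        raise EmptyBoundaryError(
            "boundary distances are undefined for an empty surface "
            f"(source n={source.n_voxels}, reference n={reference.n_voxels})"
        )
    tree = cKDTree(reference.physical_points)
    dists, _ = tree.query(source.physical_points, k=1)
    return DistanceSet(distances=np.asarray(dists, dtype=float), source=source_name)


def summarize(dset: DistanceSet) -> SurfaceSummary:
    """Reduce a distance multiset to its HD95 / ASD / MSD summary."""
    d = dset.distances
    if d.size == 0:
        raise EmptyBoundaryError("cannot summarise an empty distance multiset")
    return SurfaceSummary(
        hd95_mm=float(np.percentile(d, 95, method="linear")),
        asd_mm=float(np.mean(d)),
        msd_mm=float(np.median(d)),
        n_distances=int(d.size),
    )


def _directed_or_symmetric(
    pred_surface: BoundarySurface,
    truth_surface: BoundarySurface,
    symmetric: bool,
    source_name: str,
) -> DistanceSet:
    forward = boundary_distances(pred_surface, truth_surface, source_name=source_name)
    if not symmetric:
        return forward
    backward = boundary_distances(truth_surface, pred_surface, source_name="truth")
    pooled = np.concatenate([forward.distances, backward.distances])
    return DistanceSet(distances=pooled, source=f"{source_name}+truth (symmetric)")


def patientwise_surface(
    truth: BinaryMask,
    prediction: BinaryMask,
    *,
    symmetric: bool = False,
) -> SurfaceSummary:
    """Whole-mask surface summary; false-positive structures contaminate it by design."""
    truth.require_same_geometry(prediction)
    truth_surface = extract_boundary(truth)
    pred_surface = extract_boundary(prediction)
    dset = _directed_or_symmetric(pred_surface, truth_surface, symmetric, "prediction")
    return summarize(dset)


def structurewise_surface(
    truth: BinaryMask,
    prediction: StructureSet,
    matches: MatchTable,
    *,
    symmetric: bool = False,
) -> list[tuple[int, SurfaceSummary]]:
    """One surface summary per detected predicted structure.

    ``matches`` must be the prediction-direction match table for the same
    structure set (one entry per predicted structure).  Distances run from
    each detected structure's boundary to the whole ground-truth boundary;
    undetected structures contribute nothing.
    """
    if truth.is_empty:
        raise EmptyBoundaryError("structure-wise distances are undefined for an empty truth mask")
    match_labels = {e.label for e in matches.entries}
    if match_labels != set(prediction.labels):
        raise ValueError(
            "match table labels do not correspond to the predicted structure set"
        )
    truth_surface = extract_boundary(truth)
    detected = {e.label for e in matches.entries if e.detected}
    out: list[tuple[int, SurfaceSummary]] = []
    for s in prediction:
        if s.label not in detected:
            continue
        surf = extract_boundary(structure_to_mask(s, prediction.source_mask))
        dset = _directed_or_symmetric(surf, truth_surface, symmetric, f"structure {s.label}")
        out.append((s.label, summarize(dset)))
    return out
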