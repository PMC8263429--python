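"""Synthetic phantom masks with controllable, analytically known error structure.

The generator renders multi-structure "patients" — a handful of ellipsoids on
a voxel grid, standing in for a primary tumour plus involved lymph nodes —
and perturbs them into plausible auto-delineation errors:

* ``translate``       — systematic contour offset,
* ``dilate``/``erode`` — over-/under-segmentation of the boundary,
* ``add_false_structure`` — a false-positive component disjoint from truth,
* ``delete_structure``    — a missed structure (false negative),
* ``boundary_jitter``     — random voxel noise on the surface.

Ellipsoids are used instead of realistic tumour shapes because every volume,
overlap and distance then has an analytic or brute-force-checkable
expectation.  All randomness derives from explicit integer seeds; there is
no global random state, and a fixed spec renders bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .mask import BinaryMask, label_components, structure_to_mask

__all__ = ["PhantomSpec", "Perturbation", "render_phantom", "perturb"]


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a multi-ellipsoid phantom mask.

    ``structures`` holds ``(center_mm, radii_mm)`` pairs in physical
    coordinates; a voxel is in-mask iff its centre lies inside any ellipsoid.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    structures: tuple[tuple[tuple[float, float, float], tuple[float, float, float]], ...] = ()
    seed: int = 0

    def to_config(self) -> str:
        """Serialise as a plain-text key=value config (one structure per line)."""
        lines = [
            f"grid_shape = {' '.join(str(v) for v in self.grid_shape)}",
            f"spacing = {' '.join(repr(v) for v in self.spacing)}",
            f"seed = {self.seed}",
        ]
        for center, radii in self.structures:
            vals = [*center, *radii]
            lines.append("structure = " + " ".join(repr(float(v)) for v in vals))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "PhantomSpec":
        grid_shape = (64, 64, 32)
        spacing = (1.0, 1.0, 1.0)
        seed = 0
        structures = []
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            parts = value.split()
            if key == "grid_shape":
                grid_shape = tuple(int(p) for p in parts)  # type: ignore[assignment]
            elif key == "spacing":
                spacing = tuple(float(p) for p in parts)  # type: ignore[assignment]
            elif key == "seed":
                seed = int(parts[0])
            elif key == "structure":
                nums = [float(p) for p in parts]
                if len(nums) != 6:
                    raise ValueError(f"structure line needs 6 numbers, got {line!r}")
                structures.append((tuple(nums[:3]), tuple(nums[3:])))
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls(
            grid_shape=grid_shape, spacing=spacing,
            structures=tuple(structures), seed=seed,
        )


@dataclass(frozen=True)
class Perturbation:
    """One named corruption of a mask; ``params`` are kind-specific.

    Kinds and their parameters:

    - ``translate``: ``offset_mm`` (3-tuple; rounded to whole voxels)
    - ``dilate`` / ``erode``: ``iterations`` (int, face connectivity)
    - ``add_false_structure``: ``radius_mm``; optional ``center_mm``
      (random disjoint placement when omitted); ``min_gap_mm`` clearance
    - ``delete_structure``: ``label`` (1-based component label)
    - ``boundary_jitter``: ``amplitude`` (probability a boundary voxel flips out)
    """

    kind: str
    params: dict = field(default_factory=dict)


def render_phantom(spec: PhantomSpec) -> BinaryMask:
    """Voxelise the spec's ellipsoids onto its grid."""
    shape = tuple(int(v) for v in spec.grid_shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    data = np.zeros(shape, dtype=bool)
    if spec.structures:
        grids = np.meshgrid(
            *(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij"
        )
        phys = np.stack(grids, axis=-1)  # (nx, ny, nz, 3) voxel-centre mm
        extent = (np.asarray(shape) - 1) * spacing
        for center, radii in spec.structures:
            c = np.asarray(center, dtype=float)
            r = np.asarray(radii, dtype=float)
            if (r <= 0).any():
                raise ValueError(f"ellipsoid radii must be positive, got {tuple(r)}")
            if (c - r < -spacing).any() or (c + r > extent + spacing).any():
                raise ValueError(
                    f"ellipsoid at {tuple(c)} mm with radii {tuple(r)} mm "
                    f"does not fit the grid extent {tuple(extent)} mm"
                )
            data |= (((phys - c) / r) ** 2).sum(axis=-1) <= 1.0
    return BinaryMask(data=data, spacing=tuple(spacing))


def _translate(data: np.ndarray, shift: np.ndarray) -> np.ndarray:
    out = np.zeros_like(data)
    src = []
    dst = []
    for axis, k in enumerate(shift):
        n = data.shape[axis]
        k = int(k)
        if abs(k) >= n:
            return out
        if k >= 0:
            src.append(slice(0, n - k))
            dst.append(slice(k, n))
        else:
            src.append(slice(-k, n))
            dst.append(slice(0, n + k))
    out[tuple(dst)] = data[tuple(src)]
    return out


def _sphere_voxels(shape, spacing, center_mm, radius_mm) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij")
    phys = np.stack(grids, axis=-1)
    return ((phys - np.asarray(center_mm)) ** 2).sum(axis=-1) <= radius_mm**2


def _add_false_structure(mask: BinaryMask, params: dict, rng: np.random.Generator) -> np.ndarray:
    radius = float(params.get("radius_mm", 2.0))
    min_gap = float(params.get("min_gap_mm", 2.0))
    spacing = np.asarray(mask.spacing)
    shape = mask.shape
    extent = (np.asarray(shape) - 1) * spacing

    # clearance map: distance from every voxel to the existing mask
    if mask.data.any():
        dist_to_mask = ndimage.distance_transform_edt(~mask.data, sampling=spacing)
    else:
        dist_to_mask = np.full(shape, np.inf)

    center_mm = params.get("center_mm")
    if center_mm is None:
        candidates = np.argwhere(dist_to_mask > radius + min_gap)
        # keep the blob fully on-grid
        ok = np.ones(len(candidates), dtype=bool)
        for ax in range(3):
            pos = candidates[:, ax] * spacing[ax]
            ok &= (pos - radius >= 0) & (pos + radius <= extent[ax])
        candidates = candidates[ok]
        if len(candidates) == 0:
            raise ValueError("no room for a disjoint false structure on this grid")
        idx = candidates[rng.integers(len(candidates))]
        center_mm = idx * spacing
    blob = _sphere_voxels(shape, spacing, center_mm, radius)
    if (blob & mask.data).any():
        raise ValueError("requested false-structure position overlaps the existing mask")
    return mask.data | blob


def _boundary_jitter(mask: BinaryMask, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    from .mask import extract_boundary

    surface = extract_boundary(mask)
    data = mask.data.copy()
    if surface.is_empty or amplitude <= 0:
        return data
    flips = rng.random(surface.n_voxels) < amplitude
    coords = surface.boundary_coords[flips]
    data[coords[:, 0], coords[:, 1], coords[:, 2]] = False
    return data


def perturb(mask: BinaryMask, p: Perturbation, seed: int = 0) -> BinaryMask:
    """Apply one perturbation; deterministic for fixed (mask, p, seed)."""
    rng = np.random.default_rng(seed)
    face = ndimage.generate_binary_structure(3, 1)
    params = p.params
    if p.kind == "translate":
        offset = np.asarray(params.get("offset_mm", (0.0, 0.0, 0.0)), dtype=float)
        shift = np.rint(offset / np.asarray(mask.spacing)).astype(int)
        data = _translate(mask.data, shift)
    elif p.kind == "dilate":
        data = ndimage.binary_dilation(
            mask.data, structure=face, iterations=int(params.get("iterations", 1))
        )
    elif p.kind == "erode":
        data = ndimage.binary_erosion(
            mask.data, structure=face,
            iterations=int(params.get("iterations", 1)), border_value=0,
        )
    elif p.kind == "add_false_structure":
        data = _add_false_structure(mask, params, rng)
    elif p.kind == "delete_structure":
        label = int(params["label"])
        sset = label_components(mask, int(params.get("connectivity", 26)))
        if label not in sset.labels:
            raise ValueError(f"no structure with label {label} (have {sset.labels})")
        data = mask.data.copy()
        for s in sset:
            if s.label == label:
                sub = structure_to_mask(s, mask)
                data &= ~sub.data
    elif p.kind == "boundary_jitter":
        data = _boundary_jitter(mask, float(params.get("amplitude", 0.1)), rng)
    else:
        raise ValueError(f"unknown perturbation kind {p.kind!r}")
    return BinaryMask(data=data, spacing=mask.spacing)
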