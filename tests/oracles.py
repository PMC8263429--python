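"""Independent brute-force reference implementations used only by the tests.

Everything here works on plain Python sets of voxel coordinate tuples and
O(n^2) loops, deliberately sharing no code path with the package: connected
components via iterative flood fill, overlap metrics via set arithmetic and
boundary distances via all-pairs minimisation.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

NEIGHBOURS = {
    6: [o for o in product((-1, 0, 1), repeat=3) if sum(abs(v) for v in o) == 1],
    18: [o for o in product((-1, 0, 1), repeat=3)
         if 1 <= sum(abs(v) for v in o) <= 2],
    26: [o for o in product((-1, 0, 1), repeat=3) if any(o)],
}


def voxel_set(data: np.ndarray) -> set[tuple[int, int, int]]:
    return {tuple(c) for c in np.argwhere(data)}


def flood_fill_components(data: np.ndarray, connectivity: int) -> list[set]:
    """Connected components by iterative flood fill over a voxel set."""
    remaining = voxel_set(data)
    offsets = NEIGHBOURS[connectivity]
    components = []
    while remaining:
        seed = next(iter(remaining))
        stack = [seed]
        comp = {seed}
        remaining.discard(seed)
        while stack:
            x, y, z = stack.pop()
            for dx, dy, dz in offsets:
                nb = (x + dx, y + dy, z + dz)
                if nb in remaining:
                    remaining.discard(nb)
                    comp.add(nb)
                    stack.append(nb)
        components.append(comp)
    components.sort(key=min)
    return components


def boundary_set(data: np.ndarray) -> set[tuple[int, int, int]]:
    """Inner boundary: in-mask voxels with a face neighbour out-of-mask or off-grid."""
    shape = data.shape
    inside = voxel_set(data)
    out = set()
    for (x, y, z) in inside:
        for dx, dy, dz in NEIGHBOURS[6]:
            nb = (x + dx, y + dy, z + dz)
            off_grid = not all(0 <= nb[i] < shape[i] for i in range(3))
            if off_grid or nb not in inside:
                out.add((x, y, z))
                break
    return out


def dice_sets(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return 2.0 * len(a & b) / (len(a) + len(b))


def cfrac_sets(structure: set, reference: set) -> float:
    return len(structure & reference) / len(structure)


def detection_counts(truth_data: np.ndarray, pred_data: np.ndarray,
                     connectivity: int = 26, threshold: float = 0.5):
    """(tp_pred, fp, tp_truth, fn) by flood fill + set arithmetic."""
    truth_vox = voxel_set(truth_data)
    pred_vox = voxel_set(pred_data)
    tp_pred = fp = tp_truth = fn = 0
    for comp in flood_fill_components(pred_data, connectivity):
        if cfrac_sets(comp, truth_vox) > threshold:
            tp_pred += 1
        else:
            fp += 1
    for comp in flood_fill_components(truth_data, connectivity):
        if cfrac_sets(comp, pred_vox) > threshold:
            tp_truth += 1
        else:
            fn += 1
    return tp_pred, fp, tp_truth, fn


def all_pairs_distances(source: set, reference: set, spacing) -> list[float]:
    """Directed minimum distances by exhaustive O(n*m) search, in mm."""
    sx, sy, sz = spacing
    ref = [(x * sx, y * sy, z * sz) for (x, y, z) in sorted(reference)]
    out = []
    for (x, y, z) in sorted(source):
        px, py, pz = x * sx, y * sy, z * sz
        out.append(min(
            math.sqrt((px - rx) ** 2 + (py - ry) ** 2 + (pz - rz) ** 2)
            for rx, ry, rz in ref
        ))
    return out


def percentile_linear(values: list[float], q: float) -> float:
    """Linear-interpolation percentile computed from first principles."""
    v = sorted(values)
    n = len(v)
    if n == 1:
        return v[0]
    pos = (q / 100.0) * (n - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac
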