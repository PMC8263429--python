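"""Hand-constructed mask pairs with known metric values, for demos and checks."""

from __future__ import annotations

import numpy as np

from .mask import BinaryMask

__all__ = ["detection_example_pair"]


def detection_example_pair(
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[BinaryMask, BinaryMask]:
    """The canonical three-structure detection scenario.

    Returns a (truth, prediction) pair on a 40x40x8 grid where

    * predicted structure 1 overlaps truth structure 1 with coverage 0.8
      (detected), and covers 0.8 of truth structure 1 in return (so truth
      structure 1 is detected too);
    * predicted structure 2 lies entirely inside truth structure 2
      (coverage 1.0, detected) but covers only a small fraction of it, so
      truth structure 2 is missed;
    * predicted structure 3 is disjoint from the truth (a false positive).

    Hence TP_pred = 2, FP = 1 → PPV = 2/3 (0.7 to one significant digit),
    and TP_truth = 1, FN = 1 → sensitivity = 0.5.
    """
    shape = (40, 40, 8)
    truth = np.zeros(shape, dtype=bool)
    pred = np.zeros(shape, dtype=bool)

    # truth structure 1: 10x10x4 box; prediction 1 is the same box shifted
    # +2 along x -> 8/10 of each lies in the other
    truth[2:12, 2:12, 2:6] = True
    pred[4:14, 2:12, 2:6] = True

    # truth structure 2: large 12x12x4 box; prediction 2: small 4x4x2 box
    # fully inside it (covers 32/576 of the truth structure)
    truth[22:34, 22:34, 2:6] = True
    pred[26:30, 26:30, 3:5] = True

    # prediction 3: 3x3x2 box disjoint from every truth structure
    pred[30:33, 2:5, 2:4] = True

    return (
        BinaryMask(data=truth, spacing=spacing),
        BinaryMask(data=pred, spacing=spacing),
    )
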