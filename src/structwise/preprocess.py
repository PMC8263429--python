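"""CT Hounsfield-unit windowing.

Soft tissue — tumours and lymph nodes included — occupies a narrow band of
the Hounsfield scale.  Windowing clips the CT image to
``[center - width/2, center + width/2]`` and rescales linearly to [0, 1],
discarding the dynamic range (air, bone, contrast blooming) that carries no
information about soft-tissue boundaries.  The defaults, centre 70 HU and
width 200 HU (range [-30, 170] HU), target contrast-enhanced head-and-neck
soft tissue; 70 HU is a typical median intensity inside tumour and nodal
volumes on contrast CT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["IntensityVolume", "hu_window", "DEFAULT_CENTER", "DEFAULT_WIDTH"]

DEFAULT_CENTER = 70.0
DEFAULT_WIDTH = 200.0


@dataclass(frozen=True)
class IntensityVolume:
    """A scalar 3D image (CT, in HU) with physical voxel spacing."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim == 2:
            arr = arr[:, :, np.newaxis]
        if arr.ndim != 3:
            raise ValueError(f"intensity volume must be 3D, got shape {arr.shape}")
        object.__setattr__(self, "values", arr)
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be 3 positive components, got {self.spacing!r}")
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


def hu_window(
    volume: IntensityVolume | np.ndarray,
    center: float = DEFAULT_CENTER,
    width: float = DEFAULT_WIDTH,
) -> IntensityVolume | np.ndarray:
    """Clip to the HU window and rescale linearly to [0, 1].

    ``center - width/2`` maps to 0, ``center + width/2`` maps to 1 and values
    outside saturate.  Accepts either an :class:`IntensityVolume` (returned as
    the same type) or a bare array.
    """
    if width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    lo = center - width / 2.0
    hi = center + width / 2.0
    if isinstance(volume, IntensityVolume):
        scaled = (np.clip(volume.values, lo, hi) - lo) / (hi - lo)
        return IntensityVolume(values=scaled, spacing=volume.spacing)
    arr = np.asarray(volume, dtype=float)
    return (np.clip(arr, lo, hi) - lo) / (hi - lo)
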