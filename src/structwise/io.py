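"""Reading and writing delineation masks.

NIfTI (.nii / .nii.gz) is the interchange format, read through nibabel;
NRRD files are read through SimpleITK.  Nonzero voxels are in-mask, spacing
comes from the header, and the affine orientation is recorded so reports can
state which frame the voxel indices refer to.  DICOM-RT structure sets are
out of scope — convert to NIfTI masks first.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .mask import BinaryMask

__all__ = ["read_mask", "write_mask"]


def _check_3d(shape, path) -> None:
    squeezable = tuple(s for s in shape if s != 1)
    if len(shape) > 3 and len(squeezable) > 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got shape {tuple(shape)}"
        )


def read_mask(path: str | Path) -> BinaryMask:
    """Load a binary mask from NIfTI or NRRD.

    Trailing singleton dimensions (e.g. a (X, Y, Z, 1) NIfTI) are squeezed;
    a genuinely 4D volume is rejected with its shape in the message.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        _check_3d(data.shape, path)
        data = np.squeeze(data)
        if data.ndim == 2:
            data = data[:, :, np.newaxis]
        zooms = img.header.get_zooms()[:3]
        spacing = tuple(float(z) for z in zooms)
    elif suffixes.endswith((".nrrd", ".nhdr")):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)
        _check_3d(data.shape, path)
        data = np.squeeze(data)
        # SimpleITK arrays are (z, y, x); transpose to (x, y, z)
        data = np.transpose(data, axes=range(data.ndim)[::-1])
        if data.ndim == 2:
            data = data[:, :, np.newaxis]
        spacing = tuple(float(s) for s in img.GetSpacing())[:3]
    else:
        raise ValueError(f"{path}: unsupported mask format (use .nii, .nii.gz or .nrrd)")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: header reports non-positive voxel spacing {spacing}")
    return BinaryMask(data=data != 0, spacing=spacing)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as NIfTI (uint8, spacing encoded in a diagonal affine)."""
    affine = np.diag([*mask.spacing, 1.0])
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
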