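"""Readers and writers for NIfTI (.nii/.nii.gz) and MetaImage (.mhd/.mha).

SimpleITK does the byte-level work; this layer converts to the package's
axis-aligned :class:`~spectplan.imaging_core.Volume` convention, in which data
axis ``a`` carries spacing component ``a`` (SimpleITK arrays arrive reversed,
z-fastest).  Spacing and origin round-trip exactly.  Oblique orientations are
rejected — resample upstream.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .imaging_core import DisplacementField, LabelMask, Volume


def _check_direction(img: sitk.Image, path) -> None:
    d = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(d, np.eye(3), atol=1e-6):
        raise ValueError(
            f"{path}: only axis-aligned (identity direction) volumes are "
            "supported; resample oblique data upstream")


def read_volume(path) -> Volume:
    img = sitk.ReadImage(str(path))
    _check_direction(img, path)
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3D scalar volume, got ndim={arr.ndim}")
    return Volume(np.ascontiguousarray(arr.transpose(2, 1, 0)),
                  img.GetSpacing(), img.GetOrigin())


def write_volume(vol: Volume, path) -> Path:
    path = Path(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(
        np.asarray(vol.data).transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))
    return path


def read_mask(path) -> LabelMask:
    vol = read_volume(path)
    return LabelMask((vol.data > 0.5).astype(np.uint8), vol.spacing, vol.origin)


def write_mask(mask: LabelMask, path) -> Path:
    return write_volume(Volume(mask.data.astype(np.uint8), mask.spacing,
                               mask.origin), path)


def read_displacement_field(path) -> DisplacementField:
    img = sitk.ReadImage(str(path))
    _check_direction(img, path)
    arr = sitk.GetArrayFromImage(img)  # (z, y, x, 3)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError(f"{path}: expected a 3-component vector volume")
    return DisplacementField(np.ascontiguousarray(arr.transpose(2, 1, 0, 3)),
                             img.GetSpacing(), img.GetOrigin())


def write_displacement_field(fld: DisplacementField, path) -> Path:
    path = Path(path)
    arr = np.ascontiguousarray(fld.data.transpose(2, 1, 0, 3))
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetSpacing(tuple(float(s) for s in fld.spacing))
    img.SetOrigin(tuple(float(o) for o in fld.origin))
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))
    return path
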