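"""NIfTI I/O for volumes and label masks (nibabel-backed).

Spacing is stored on the affine diagonal; label masks round-trip as uint8.
"""

from __future__ import annotations

from pathlib import Path
from typing import Type, Union

import nibabel as nib
import numpy as np

from .core import ArtifactMask, LungMask, RegionMask, Volume

GridLike = Union[Volume, LungMask, ArtifactMask, RegionMask]


def write_volume(obj: GridLike, path: str | Path) -> Path:
    """Write a Volume (float32) or a label mask (uint8) as NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, Volume):
        data = obj.data.astype(np.float32)
    else:
        data = obj.data.astype(np.uint8)
    affine = np.diag(list(obj.spacing) + [1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))
    return path


def _load(path: str | Path):
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with the file name
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise IOError(f"{path}: expected a 3D image, got shape {data.shape}")
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    return data, spacing


def read_volume(path: str | Path, phase_label: str | None = None,
                intensity_domain: str = "HU") -> Volume:
    data, spacing = _load(path)
    return Volume(np.asarray(data, dtype=np.float64), spacing,
                  phase_label, intensity_domain)


def read_mask(path: str | Path, kind: Type[GridLike] = LungMask):
    data, spacing = _load(path)
    return kind(np.asarray(data).astype(np.uint8), spacing)
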