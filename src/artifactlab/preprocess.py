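"""Image pre-processing: HU truncation/normalization, lung-bounding-box
cropping, region masks, and left–right lung separation."""

from __future__ import annotations

import warnings
from typing import List, Tuple

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .core import (
    LABEL_LEFT_LUNG,
    LABEL_RIGHT_LUNG,
    LungMask,
    RegionMask,
    Volume,
    require_same_shape,
)

HU_WINDOW = (-1024.0, 600.0)
#: Normalization divisor: width of the truncation window.
HU_RANGE = HU_WINDOW[1] - HU_WINDOW[0]  # 1624


def truncate_and_normalize(v: Volume) -> Volume:
    """Clip HU to [-1024, 600] and map linearly onto [0, 1]."""
    if v.intensity_domain == "normalized":
        warnings.warn("volume already normalized; no-op", stacklevel=2)
        return v.copy()
    lo, hi = HU_WINDOW
    data = (np.clip(v.data, lo, hi) - lo) / HU_RANGE
    return Volume(data, v.spacing, v.phase_label, intensity_domain="normalized")


def bounding_box(mask: np.ndarray, margin: int = 0) -> Tuple[slice, slice, slice]:
    """Inclusive tight bounding box of nonzero voxels, expanded by margin
    and clamped to the grid; returned as slices."""
    if not mask.any():
        raise ValueError("empty mask has no bounding box")
    slices = []
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        nz = np.nonzero(mask.any(axis=other))[0]
        lo = max(int(nz[0]) - margin, 0)
        hi = min(int(nz[-1]) + margin, mask.shape[axis] - 1)
        slices.append(slice(lo, hi + 1))
    return tuple(slices)


def crop_to_lungs(
    v: Volume, m: LungMask, margin: int = 5
) -> Tuple[Volume, LungMask, Tuple[int, int, int]]:
    """Crop volume and mask to the lung bounding box (+margin).

    Returns the cropped pair and the crop origin (offset) so coordinates
    round-trip back into the original grid.
    """
    require_same_shape(v, m)
    box = bounding_box(m.data > 0, margin)
    offset = tuple(s.start for s in box)
    vc = Volume(v.data[box].copy(), v.spacing, v.phase_label, v.intensity_domain)
    mc = LungMask(m.data[box].copy(), m.spacing)
    return vc, mc, offset


def uncrop(cropped: np.ndarray, full_shape, offset) -> np.ndarray:
    """Re-embed a cropped grid at its offset inside a zero grid."""
    out = np.zeros(full_shape, dtype=cropped.dtype)
    sl = tuple(slice(o, o + s) for o, s in zip(offset, cropped.shape))
    out[sl] = cropped
    return out


def make_region_mask(m: LungMask, dilation_voxels: int = 3) -> RegionMask:
    """Region-based mask MR: both lungs merged and dilated by a ball."""
    binary = m.binary()
    if not binary.any():
        raise ValueError("empty lung mask")
    if dilation_voxels > 0:
        binary = ndimage.binary_dilation(binary, structure=ball(dilation_voxels))
    return RegionMask(binary.astype(np.uint8), m.spacing)


def split_left_right(
    v: Volume, m: LungMask, margin: int = 5
) -> List[Tuple[str, Volume, LungMask, Tuple[int, int, int]]]:
    """Independently crop each lung label to its own bounding box.

    Returns a list of (side, volume, mask, offset); a missing label yields
    only the present side with a warning.
    """
    require_same_shape(v, m)
    out = []
    for side, label in (("left", LABEL_LEFT_LUNG), ("right", LABEL_RIGHT_LUNG)):
        sel = m.data == label
        if not sel.any():
            warnings.warn(f"{side} lung label missing; side skipped", stacklevel=2)
            continue
        box = bounding_box(sel, margin)
        offset = tuple(s.start for s in box)
        mc = np.where(sel[box], label, 0).astype(np.uint8)
        out.append(
            (
                side,
                Volume(v.data[box].copy(), v.spacing, v.phase_label, v.intensity_domain),
                LungMask(mc, m.spacing),
                offset,
            )
        )
    if not out:
        raise ValueError("no lung labels present")
    return out
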