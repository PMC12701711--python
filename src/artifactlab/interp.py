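"""Synthetic interpolation artifact generator.

Interpolation artifacts arise when a 4DCT reconstruction lacks projection
data for a couch position and fills the gap by linearly interpolating
between the nearest valid axial slices. The generator reproduces this
exactly: interior slices of a chosen interval [z0, z1] are replaced by

    I^_z = ((z1 - z)/(z1 - z0)) * I_z0 + ((z - z0)/(z1 - z0)) * I_z1

and the ground-truth mask MINT labels every slice of the final interval,
endpoints included. Interval start/end indices are Gaussian-perturbed so
artifact lengths vary naturally; placement is unrestricted axially.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .core import LABEL_INTERPOLATION, ArtifactMask, Volume


@dataclass(frozen=True)
class Interval:
    """Contiguous inclusive axial slice range with >= 1 interior slice."""

    z_start: int
    z_end: int

    def __post_init__(self):
        if self.z_end < self.z_start + 2:
            raise ValueError(
                f"interval [{self.z_start}, {self.z_end}] has no interior slice"
            )

    @property
    def length(self) -> int:
        return self.z_end - self.z_start + 1

    def slices(self) -> range:
        return range(self.z_start, self.z_end + 1)

    def interior(self) -> range:
        return range(self.z_start + 1, self.z_end)

    def contains(self, other: "Interval") -> bool:
        return self.z_start <= other.z_start and other.z_end <= self.z_end


@dataclass(frozen=True)
class InterpParams:
    h: int = 8            # initial interval length (slices)
    n_intervals: int = 1  # NINT
    sigma_g: float = 1.0  # endpoint perturbation sd (slices)
    seed: int = 0

    def validate(self) -> None:
        if self.h < 3:
            raise ValueError("h must be >= 3 (one interior slice minimum)")
        if self.n_intervals < 0:
            raise ValueError("n_intervals must be >= 0")
        if self.sigma_g < 0:
            raise ValueError("sigma_g must be >= 0")


def interpolate_interval(v: Volume, iv: Interval) -> Volume:
    """Linearly interpolate interior slices between the interval endpoints."""
    if iv.z_start < 0 or iv.z_end >= v.n_slices:
        raise ValueError(f"interval {iv} out of bounds for {v.n_slices} slices")
    data = v.data.copy()
    z0, z1 = iv.z_start, iv.z_end
    span = z1 - z0
    for z in iv.interior():
        a = (z1 - z) / span
        data[:, :, z] = a * v.data[:, :, z0] + (1.0 - a) * v.data[:, :, z1]
    return Volume(data, v.spacing, v.phase_label, v.intensity_domain)


def merge_intervals(intervals: List[Interval]) -> List[Interval]:
    """Merge overlapping or abutting intervals into maximal runs."""
    if not intervals:
        return []
    ordered = sorted(intervals, key=lambda iv: (iv.z_start, iv.z_end))
    merged = [ordered[0]]
    for iv in ordered[1:]:
        last = merged[-1]
        if iv.z_start <= last.z_end + 1:
            merged[-1] = Interval(last.z_start, max(last.z_end, iv.z_end))
        else:
            merged.append(iv)
    return merged


def perturb_intervals(
    params: InterpParams, n_slices: int,
    rng: Optional[np.random.Generator] = None,
) -> List[Interval]:
    """Place seed intervals of length h uniformly at random (non-overlapping,
    unrestricted axially), Gaussian-perturb the endpoints, clamp to bounds
    and to length >= 3, and merge any resulting overlaps."""
    params.validate()
    if params.n_intervals == 0:
        return []
    if params.h > n_slices:
        raise ValueError("interval length exceeds volume")
    rng = np.random.default_rng(params.seed) if rng is None else rng

    starts: List[int] = []
    for _ in range(params.n_intervals):
        placed = False
        for _ in range(200):
            s = int(rng.integers(0, n_slices - params.h + 1))
            if all(s + params.h <= t or t + params.h <= s for t in starts):
                starts.append(s)
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place {params.n_intervals} non-overlapping intervals"
            )

    intervals = []
    for s in sorted(starts):
        z0, z1 = s, s + params.h - 1
        if params.sigma_g > 0:
            z0 += int(np.round(rng.normal(0, params.sigma_g)))
            z1 += int(np.round(rng.normal(0, params.sigma_g)))
        z0 = max(0, min(z0, n_slices - 3))
        z1 = max(z0 + 2, min(z1, n_slices - 1))
        intervals.append(Interval(z0, z1))
    return merge_intervals(intervals)


def infuse_interpolation(
    v: Volume, intervals: List[Interval]
) -> tuple[Volume, ArtifactMask]:
    """Apply the interpolation to each interval and emit MINT (label 2 on
    every slice of each interval, endpoints included)."""
    merged = merge_intervals(intervals)
    if len(merged) != len(intervals):
        raise ValueError("intervals overlap; merge them first")
    out = v
    mask = np.zeros(v.shape, dtype=np.uint8)
    for iv in merged:
        if iv.z_end >= v.n_slices:
            raise ValueError(f"interval {iv} out of bounds")
        out = interpolate_interval(out, iv)
        mask[:, :, iv.z_start : iv.z_end + 1] = LABEL_INTERPOLATION
    return out, ArtifactMask(mask, v.spacing)
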