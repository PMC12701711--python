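"""Shared volumetric data model.

All grids use axis order ``(x, y, z)`` with ``z`` the axial (slice) axis and
0-based indices. Intensities are either raw Hounsfield units (HU) or
normalized to [0, 1] (see :func:`artifactlab.preprocess.truncate_and_normalize`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Tuple

import numpy as np

IntensityDomain = Literal["HU", "normalized"]

#: Artifact-mask label values.
LABEL_PHASE_BINNING = 1
LABEL_INTERPOLATION = 2

#: Lung-mask label values.
LABEL_LEFT_LUNG = 1
LABEL_RIGHT_LUNG = 2


def _as_float_grid(data: np.ndarray) -> np.ndarray:
    arr = np.asarray(data, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D grid, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("volume contains non-finite values")
    return arr


@dataclass
class Volume:
    """One 3D intensity grid with physical spacing and an optional phase label."""

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    phase_label: Optional[str] = None
    intensity_domain: IntensityDomain = "HU"

    def __post_init__(self) -> None:
        self.data = _as_float_grid(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"invalid spacing {self.spacing}")
        if self.intensity_domain not in ("HU", "normalized"):
            raise ValueError(f"unknown intensity domain {self.intensity_domain!r}")
        if self.intensity_domain == "normalized":
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValueError(
                    f"normalized volume out of [0,1]: range [{lo}, {hi}]"
                )

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def copy(self, **changes) -> "Volume":
        out = replace(self, **changes)
        if "data" not in changes:
            out.data = self.data.copy()
        return out


@dataclass
class _LabelGrid:
    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {arr.shape}")
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def copy(self):
        return type(self)(self.data.copy(), self.spacing)


@dataclass
class LungMask(_LabelGrid):
    """Label grid: 0 background, 1 left lung, 2 right lung."""

    def binary(self) -> np.ndarray:
        """Both lungs merged into one boolean mask."""
        return self.data > 0

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.data))

    def z_extent(self) -> Tuple[int, int]:
        """Inclusive axial index range occupied by lung voxels."""
        zs = np.nonzero(self.data.any(axis=(0, 1)))[0]
        if zs.size == 0:
            raise ValueError("empty lung mask has no z extent")
        return int(zs[0]), int(zs[-1])


@dataclass
class ArtifactMask(_LabelGrid):
    """Label grid: 0 none, 1 phase-binning (MPB), 2 interpolation (MINT)."""

    def phase_binning(self) -> np.ndarray:
        return self.data == LABEL_PHASE_BINNING

    def interpolation(self) -> np.ndarray:
        return self.data == LABEL_INTERPOLATION

    def any_artifact(self) -> np.ndarray:
        """The combined artifact mask (union of both labels)."""
        return self.data > 0

    @staticmethod
    def combine(pb: "ArtifactMask", interp: "ArtifactMask") -> "ArtifactMask":
        """Union of the two single-type masks; phase-binning wins on overlap."""
        if pb.shape != interp.shape:
            raise ValueError("mask shapes differ")
        data = np.where(pb.data == LABEL_PHASE_BINNING, LABEL_PHASE_BINNING,
                        interp.data)
        return ArtifactMask(data, pb.spacing)


@dataclass
class RegionMask(_LabelGrid):
    """Binary search-region mask MR (dilated lung envelope)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = (self.data > 0).astype(np.uint8)


def require_same_shape(*grids) -> None:
    shapes = {g.shape for g in grids}
    if len(shapes) > 1:
        raise ValueError(f"co-registered grids expected, got shapes {shapes}")


def phase_labels(n_phases: int) -> list[str]:
    """Evenly spaced breathing-phase labels T00..T90 style for n phases."""
    if n_phases < 2:
        raise ValueError("need at least 2 phases")
    return [f"T{(i * 100) // n_phases:02d}" for i in range(n_phases)]
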