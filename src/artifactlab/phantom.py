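"""Seedable multi-phase breathing phantom.

Generates a 10-phase (configurable) series of 3D CT-like volumes: two
ellipsoidal lungs (≈ −800 HU) inside a soft-tissue torso (≈ 40 HU) with a
spine proxy (≈ 500 HU) on an air background (≈ −1000 HU). The diaphragm —
the inferior boundary of each lung — rises sinusoidally from end-inspiration
(T00, maximal lung volume) to end-expiration (T50, minimal) and descends
back by the last phase. Correlated parenchymal texture and i.i.d. voxel
noise are added so that adjacent axial slices are always distinguishable,
which the rule-based interpolation detector relies on.

Paired lung masks (1 = left, 2 = right) follow the diaphragm exactly and
are computed from the noise-free geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import LungMask, Volume, phase_labels

HU_AIR = -1000.0
HU_LUNG = -800.0
HU_SOFT_TISSUE = 40.0
HU_SPINE = 500.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic breathing series.

    diaphragm_amplitude is the peak inferior-cap excursion in voxels over
    the cycle; noise_sd is in HU and must be positive so neighbouring axial
    slices never coincide.
    """

    grid_shape: Tuple[int, int, int] = (96, 96, 96)
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_phases: int = 10
    diaphragm_amplitude: float = 8.0
    deflation: float = 0.15
    noise_sd: float = 20.0
    texture_scale: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 16 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 axes, each >= 16")
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")
        if self.diaphragm_amplitude < 1:
            raise ValueError("diaphragm_amplitude must be >= 1 voxel")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0 (slices must be distinguishable)")
        if not 0 <= self.deflation < 1:
            raise ValueError("deflation must lie in [0, 1)")
        if self.texture_scale <= 0:
            raise ValueError("texture_scale must be > 0")


@dataclass
class PhaseSeries:
    """Ordered phases: list of (label, volume, lung mask) triples."""

    phases: List[Tuple[str, Volume, LungMask]]
    spec: PhantomSpec

    def __iter__(self):
        return iter(self.phases)

    def __len__(self) -> int:
        return len(self.phases)

    def volume(self, label: str) -> Volume:
        for lab, vol, _ in self.phases:
            if lab == label:
                return vol
        raise KeyError(label)

    def lung_mask(self, label: str) -> LungMask:
        for lab, _, mask in self.phases:
            if lab == label:
                return mask
        raise KeyError(label)


def diaphragm_displacement(phase_index: int, n_phases: int, amplitude: float) -> float:
    """Per-phase upward displacement of the lung inferior cap (voxels).

    d(i) = amplitude * (1 - cos(2*pi*i/n)) / 2 — zero at T00, peak at the
    mid-cycle phase, symmetric on the way back.
    """
    return amplitude * (1.0 - np.cos(2.0 * np.pi * phase_index / n_phases)) / 2.0


def noise_free_phase(spec: PhantomSpec, phase_index: int) -> Tuple[np.ndarray, np.ndarray]:
    """Noise-free HU grid and label mask {0,1,2} for one phase.

    Breathing has two coupled effects, both driven by the phase fraction
    f = (1 − cos(2πi/n))/2 ∈ [0, 1]: the diaphragm (lung floor) rises by
    f·amplitude voxels, and the lung semi-axes contract in-plane by
    f·deflation (lungs deflate toward end-expiration), so every axial lung
    slice differs between distant phases, not just the floor band.
    """
    nx, ny, nz = spec.grid_shape
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0

    # Elliptic-cylinder torso occupying most of the in-plane field of view;
    # lungs are confined to an inner ellipse so a soft-tissue chest wall of
    # >= 2 voxels always separates lung from the outside air.
    torso = ((x - cx) / (0.45 * nx)) ** 2 + ((y - cy) / (0.40 * ny)) ** 2 <= 1.0
    torso_inner = (
        ((x - cx) / (0.45 * nx - 2.0)) ** 2 + ((y - cy) / (0.40 * ny - 2.0)) ** 2
        <= 1.0
    )

    # Spine proxy: posterior circular cylinder.
    spine_cy = cy + 0.28 * ny
    spine = (x - cx) ** 2 + (y - spine_cy) ** 2 <= (0.07 * min(nx, ny)) ** 2
    spine &= torso

    d = diaphragm_displacement(phase_index, spec.n_phases, spec.diaphragm_amplitude)
    f = d / spec.diaphragm_amplitude if spec.diaphragm_amplitude else 0.0
    scale = 1.0 - spec.deflation * f

    # Lung ellipsoids, left/right of the midline; z extent covers the
    # central ~70% of the grid at full inspiration.
    z_bot, z_top = 0.15 * nz, 0.85 * nz
    zc = (z_bot + z_top) / 2.0
    rz = (z_top - z_bot) / 2.0
    rx, ry = 0.18 * nx * scale, 0.26 * ny * scale

    grid = np.full(spec.grid_shape, HU_AIR)
    grid[torso] = HU_SOFT_TISSUE
    mask = np.zeros(spec.grid_shape, dtype=np.uint8)
    for label, xoff in ((1, -0.21 * nx), (2, 0.21 * nx)):
        lung = (
            ((x - (cx + xoff)) / rx) ** 2
            + ((y - (cy - 0.05 * ny)) / ry) ** 2
            + ((z - zc) / rz) ** 2
            <= 1.0
        )
        # diaphragm rises by d: lung exists only above the raised floor
        lung_phase = lung & torso_inner & ~spine & (z >= z_bot + d)
        grid[lung_phase] = HU_LUNG
        mask[lung_phase] = label
    grid[spine] = HU_SPINE
    return grid, mask


def generate_phase_series(spec: PhantomSpec) -> PhaseSeries:
    """Generate the full breathing series; deterministic given spec.seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    labels = phase_labels(spec.n_phases)

    phases = []
    for i, label in enumerate(labels):
        grid, mask = noise_free_phase(spec, i)
        # Correlated parenchymal texture at 20% of the noise amplitude,
        # plus i.i.d. voxel noise everywhere.
        texture = gaussian_filter(
            rng.standard_normal(spec.grid_shape), sigma=spec.texture_scale
        )
        tex_sd = texture.std()
        if tex_sd > 0:
            texture *= (0.2 * spec.noise_sd) / tex_sd
        noise = rng.standard_normal(spec.grid_shape) * spec.noise_sd
        vol = Volume(
            grid + texture + noise,
            spacing=spec.spacing,
            phase_label=label,
            intensity_domain="HU",
        )
        phases.append((label, vol, LungMask(mask, spec.spacing)))
    return PhaseSeries(phases, spec)


def phantom_summary(series: PhaseSeries) -> List[dict]:
    """Per-phase lung volume (ml), intensity range, and slice count."""
    out = []
    for label, vol, mask in series:
        n = mask.n_voxels
        rec = {
            "phase": label,
            "lung_volume_ml": n * vol.voxel_volume_mm3 / 1000.0,
            "intensity_min": float(vol.data.min()),
            "intensity_max": float(vol.data.max()),
            "n_slices": vol.n_slices,
            "degenerate": n == 0,
        }
        out.append(rec)
    return out


def write_series(series: PhaseSeries, out_dir: str | Path, case: str = "phantom") -> Path:
    """Write each phase volume/mask as NIfTI plus a JSON manifest."""
    from .io import write_volume

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for label, vol, mask in series:
        img_path = out_dir / f"{case}_{label}_img.nii.gz"
        lung_path = out_dir / f"{case}_{label}_lung.nii.gz"
        write_volume(vol, img_path)
        write_volume(mask, lung_path)
        records.append({"phase": label, "img": img_path.name, "lung": lung_path.name})
    manifest = out_dir / f"{case}_manifest.json"
    manifest.write_text(
        json.dumps({"spec": asdict(series.spec), "phases": records}, indent=2)
    )
    return manifest
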