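"""Synthetic phase-binning artifact generator.

A phase-binning artifact is anatomy from the wrong breathing phase inserted
as a stack of axial slices during 4DCT reconstruction. Given a clean phase
image I and a secondary phase I~ (normalized, co-registered), the generator:

1. places ``n_stacks`` non-overlapping stacks of height ``h`` uniformly at
   random in the inferior half of the lung extent (binary slice profile Mg);
2. feathers Mg along z with a Gaussian of sd ``sigma_g`` — the "artifact
   visibility" parameter — into weights M^g in [0, 1];
3. shifts each stack of I~ in-plane by a random integer offset (couch
   mis-positioning proxy), giving I~g;
4. accepts the draw only if the weighted difference C = M^g ⊙ (I − I~g) is
   majority non-positive — this guarantees the infused stack contains *more*
   tissue (repeated diaphragm) rather than missing tissue;
5. blends I^ = I ⊙ (1 − M^g) + M^g ⊙ I~g;
6. derives the ground-truth mask MPB by thresholding |I − I^| at
   λ = lambda0·sigma_g, morphological closing, and small-component removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.morphology import ball

from .core import (
    LABEL_PHASE_BINNING,
    ArtifactMask,
    LungMask,
    Volume,
    require_same_shape,
)


@dataclass(frozen=True)
class PhaseBinningParams:
    h: int = 8                      # uniform stack height (slices)
    n_stacks: int = 1               # NPB
    sigma_g: float = 1.5            # artifact visibility (slices)
    shift_intensity: int = 2        # si: max in-plane displacement (voxels)
    lambda0: float = 0.05           # λ = lambda0 * sigma_g (normalized units)
    r_close: int = 2                # morphological closing ball radius
    min_component: int = 50         # smallest retained component (voxels)
    max_retries: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.h < 1:
            raise ValueError("h must be >= 1")
        if self.n_stacks < 1:
            raise ValueError("n_stacks must be >= 1")
        if self.sigma_g <= 0:
            raise ValueError("sigma_g must be > 0")
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be > 0")
        if self.shift_intensity < 0:
            raise ValueError("shift_intensity must be >= 0")


@dataclass
class StackMask:
    """Per-slice stack profile: binary Mg and feathered M^g weights."""

    binary_profile: np.ndarray      # (n_slices,) in {0,1}
    feathered_profile: np.ndarray   # (n_slices,) in [0,1]
    stacks: List[Tuple[int, int]]   # (z_start, height)

    @property
    def n_slices(self) -> int:
        return self.binary_profile.size

    def support(self, eps: float = 0.0) -> np.ndarray:
        return np.nonzero(self.feathered_profile > eps)[0]


@dataclass
class AdmissibilityCheck:
    C: np.ndarray
    n_nonpositive: int
    n_nonnegative: int

    @property
    def admissible(self) -> bool:
        return self.n_nonpositive > self.n_nonnegative


@dataclass
class InfusionResult:
    """Outcome of one infusion attempt chain (may be a rejection)."""

    accepted: bool
    volume: Optional[Volume] = None
    artifact_mask: Optional[ArtifactMask] = None
    stack_mask: Optional[StackMask] = None
    n_attempts: int = 0


def _place_stacks(
    rng: np.random.Generator, z_lo: int, z_hi_start: int, h: int, n_stacks: int
) -> List[Tuple[int, int]]:
    """Draw non-overlapping stack starts uniformly in [z_lo, z_hi_start]."""
    if z_hi_start < z_lo:
        raise ValueError("stack does not fit in the allowed axial range")
    starts: List[int] = []
    for _ in range(n_stacks):
        placed = False
        for _ in range(200):
            s = int(rng.integers(z_lo, z_hi_start + 1))
            if all(s + h <= t or t + h <= s for t in starts):
                starts.append(s)
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place {n_stacks} non-overlapping stacks of height {h}"
            )
    return [(s, h) for s in sorted(starts)]


def build_stack_mask(
    n_slices: int, params: PhaseBinningParams, lung_mask: LungMask,
    rng: Optional[np.random.Generator] = None,
) -> StackMask:
    """Place stacks uniformly at random in the inferior half of the lungs.

    Stacks lie entirely within [z_lung_min, z_lung_mid], matching where
    phase-binning artifacts occur clinically (near the diaphragm).
    """
    params.validate()
    rng = np.random.default_rng(params.seed) if rng is None else rng
    z_min, z_max = lung_mask.z_extent()
    z_mid = (z_min + z_max) // 2
    z_hi_start = z_mid - params.h
    stacks = _place_stacks(rng, z_min, z_hi_start, params.h, params.n_stacks)
    profile = np.zeros(n_slices)
    for s, h in stacks:
        profile[s : s + h] = 1.0
    return StackMask(profile, profile.copy(), stacks)


def feather_stack_mask(sm: StackMask, sigma_g: float) -> StackMask:
    """Gaussian-feather the binary profile along z, per stack, renormalized
    so each stack's peak weight is 1 (visibility is not attenuated)."""
    if sigma_g <= 0:
        return StackMask(sm.binary_profile.copy(), sm.binary_profile.copy(),
                         list(sm.stacks))
    feathered = np.zeros_like(sm.binary_profile, dtype=float)
    for s, h in sm.stacks:
        single = np.zeros_like(feathered)
        single[s : s + h] = 1.0
        smoothed = ndimage.gaussian_filter1d(single, sigma=sigma_g, mode="constant")
        peak = smoothed.max()
        if peak > 0:
            smoothed /= peak
        feathered = np.maximum(feathered, smoothed)
    return StackMask(sm.binary_profile.copy(), feathered, list(sm.stacks))


def _shift_slice_block(block: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """In-plane integer shift of a (x, y, z) block with edge replication."""
    px = (max(dx, 0), max(-dx, 0))
    py = (max(dy, 0), max(-dy, 0))
    padded = np.pad(block, (px, py, (0, 0)), mode="edge")
    nx, ny = block.shape[:2]
    return padded[px[1] : px[1] + nx, py[1] : py[1] + ny, :]


def shift_secondary(
    v: Volume, sm: StackMask, si: int, rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> Volume:
    """Shift each stack of the secondary phase in-plane by one integer
    offset pair drawn uniformly from [-si, si]^2 (edge-replicated fill)."""
    if si < 0:
        raise ValueError("shift intensity must be >= 0")
    rng = np.random.default_rng(seed) if rng is None else rng
    data = v.data.copy()
    for s, h in sm.stacks:
        dx, dy = (int(rng.integers(-si, si + 1)) for _ in range(2))
        data[:, :, s : s + h] = _shift_slice_block(v.data[:, :, s : s + h], dx, dy)
    return Volume(data, v.spacing, v.phase_label, v.intensity_domain)


def check_admissibility(I: Volume, Ig: Volume, sm: StackMask) -> AdmissibilityCheck:
    """Weighted difference C = M^g ⊙ (I − I~g); the draw is admissible when
    non-positive voxels outnumber non-negative ones (majority negative)."""
    require_same_shape(I, Ig)
    w = sm.feathered_profile[np.newaxis, np.newaxis, :]
    C = w * (I.data - Ig.data)
    return AdmissibilityCheck(
        C, int(np.count_nonzero(C <= 0)), int(np.count_nonzero(C >= 0))
    )


def blend(I: Volume, Ig: Volume, sm: StackMask) -> Volume:
    """I^ = I ⊙ (1 − M^g) + M^g ⊙ I~g, weights broadcast per axial slice."""
    require_same_shape(I, Ig)
    w = sm.feathered_profile[np.newaxis, np.newaxis, :]
    data = I.data * (1.0 - w) + w * Ig.data
    return Volume(data, I.spacing, I.phase_label, I.intensity_domain)


def derive_pb_mask(
    I: Volume, Ihat: Volume, params: PhaseBinningParams
) -> ArtifactMask:
    """Ground-truth MPB: threshold |I − I^| at λ = lambda0·sigma_g, close,
    and drop connected components smaller than min_component."""
    require_same_shape(I, Ihat)
    lam = params.lambda0 * params.sigma_g
    if lam >= 1.0:
        raise ValueError(f"threshold λ={lam} >= 1 would produce an empty mask")
    binary = np.abs(I.data - Ihat.data) > lam
    if params.r_close > 0 and binary.any():
        binary = ndimage.binary_closing(binary, structure=ball(params.r_close))
    if params.min_component > 1 and binary.any():
        labeled = cc_label(binary, connectivity=1)
        counts = np.bincount(labeled.ravel())
        keep = counts >= params.min_component
        keep[0] = False
        binary = keep[labeled]
    return ArtifactMask(
        np.where(binary, LABEL_PHASE_BINNING, 0).astype(np.uint8), I.spacing
    )


def infuse_phase_binning(
    I: Volume,
    I_secondary: Volume,
    lung: LungMask,
    params: PhaseBinningParams,
    rng: Optional[np.random.Generator] = None,
) -> InfusionResult:
    """Full pipeline: place → feather → shift → admissibility → blend → mask.

    On admissibility failure the stack placement and shift are redrawn up to
    ``params.max_retries`` times; exhausting retries returns a rejection
    result (the caller may try another secondary phase).
    """
    params.validate()
    if I.intensity_domain != "normalized" or I_secondary.intensity_domain != "normalized":
        raise ValueError("both volumes must be normalized")
    require_same_shape(I, I_secondary)
    rng = np.random.default_rng(params.seed) if rng is None else rng

    attempts = 0
    for _ in range(max(params.max_retries, 1)):
        attempts += 1
        sm = build_stack_mask(I.n_slices, params, lung, rng=rng)
        sm = feather_stack_mask(sm, params.sigma_g)
        Ig = shift_secondary(I_secondary, sm, params.shift_intensity, rng=rng)
        if check_admissibility(I, Ig, sm).admissible:
            Ihat = blend(I, Ig, sm)
            mask = derive_pb_mask(I, Ihat, params)
            return InfusionResult(True, Ihat, mask, sm, attempts)
    return InfusionResult(False, n_attempts=attempts)
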