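"""Rule-based interpolation-artifact detector.

The detector artificially re-interpolates every short sliding interval of
axial slices (lengths 3 and 4 by default) and compares the simulation with
the original image. A genuinely interpolated interval reproduces itself —
the maximum voxel-wise difference over its interior slices is (near) zero —
while normal anatomy plus noise leaves a difference well above threshold.
Candidates below a per-segment threshold are consolidated by a
non-containment rule and a final merge of overlapping/abutting intervals,
which recovers long artifacts from their short subintervals.

Thresholds are fit from labeled data by minimizing the mean Dice loss of
slice-level detections per axial segment, within bounds (0.2, 0.3), via
grid search or bounded Brent; k-fold cross-validation reports held-out
Dice per fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

from .core import ArtifactMask, Volume
from .interp import Interval, interpolate_interval, merge_intervals
from .metrics import dice_from_counts

DEFAULT_LENGTHS = (3, 4)


@dataclass
class ThresholdProfile:
    n_segments: int = 10
    thresholds: Optional[List[float]] = None
    bounds: Tuple[float, float] = (0.2, 0.3)

    def __post_init__(self):
        if self.thresholds is None:
            mid = sum(self.bounds) / 2.0
            self.thresholds = [mid] * self.n_segments
        if len(self.thresholds) != self.n_segments:
            raise ValueError("need one threshold per segment")
        if any(not 0.0 < p < 1.0 for p in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1)")

    @classmethod
    def uniform(cls, p: float, n_segments: int = 10,
                bounds: Tuple[float, float] = (0.2, 0.3)) -> "ThresholdProfile":
        return cls(n_segments, [p] * n_segments, bounds)


@dataclass
class CandidateInterval:
    interval: Interval
    max_diff: float
    segment: int


@dataclass
class DetectionResult:
    intervals: List[Interval]
    candidates: List[CandidateInterval]
    slice_flags: np.ndarray
    profile: ThresholdProfile

    @property
    def detected_slices(self) -> np.ndarray:
        return np.nonzero(self.slice_flags)[0]


@dataclass
class LabeledVolume:
    """A volume paired with its ground-truth interpolated-slice flags."""

    volume: Volume
    truth_slices: np.ndarray  # (n_slices,) bool

    @classmethod
    def from_mask(cls, volume: Volume, mask: ArtifactMask) -> "LabeledVolume":
        flags = (mask.data == 2).any(axis=(0, 1))
        return cls(volume, flags)


def interval_difference(v: Volume, iv: Interval) -> float:
    """Max abs difference between simulated and original interior slices."""
    simulated = interpolate_interval(v, iv)
    z0, z1 = iv.z_start + 1, iv.z_end  # interior only
    return float(
        np.abs(simulated.data[:, :, z0:z1] - v.data[:, :, z0:z1]).max()
    )


def segment_of(z: int, n_slices: int, n_segments: int) -> int:
    """Axial segment index: floor(z * Ns / n_slices), clamped to Ns − 1."""
    if not 0 <= z < n_slices:
        raise ValueError(f"slice {z} outside [0, {n_slices})")
    return min(z * n_segments // n_slices, n_segments - 1)


def iter_windows(n_slices: int, lengths: Iterable[int]) -> Iterable[Interval]:
    for length in sorted(lengths):
        for z0 in range(n_slices - length + 1):
            yield Interval(z0, z0 + length - 1)


def scan_intervals(
    v: Volume,
    profile: ThresholdProfile,
    lengths: Sequence[int] = DEFAULT_LENGTHS,
) -> List[CandidateInterval]:
    """Slide every interval of each length over z; keep those whose
    difference falls strictly below the threshold of the segment containing
    the interval's center slice. Evaluation order never affects the output."""
    n = v.n_slices
    candidates = []
    for iv in iter_windows(n, lengths):
        center = (iv.z_start + iv.z_end) // 2
        seg = segment_of(center, n, profile.n_segments)
        d = interval_difference(v, iv)
        if d < profile.thresholds[seg]:
            candidates.append(CandidateInterval(iv, d, seg))
    return candidates


def consolidate(intervals: List[Interval]) -> List[Interval]:
    """Drop intervals fully contained in another, then merge overlapping or
    abutting intervals into maximal runs."""
    kept = [
        iv for iv in intervals
        if not any(o is not iv and o.contains(iv) and o != iv for o in intervals)
    ]
    # exact duplicates: keep one
    kept = list(dict.fromkeys(kept))
    return merge_intervals(kept)


def detect(
    v: Volume,
    profile: ThresholdProfile,
    lengths: Sequence[int] = DEFAULT_LENGTHS,
) -> DetectionResult:
    """Scan at the given lengths, consolidate, and flag detected slices."""
    if v.intensity_domain != "normalized":
        raise ValueError("detector expects a normalized volume")
    candidates = scan_intervals(v, profile, lengths)
    final = consolidate([c.interval for c in candidates])
    flags = np.zeros(v.n_slices, dtype=bool)
    for iv in final:
        flags[iv.z_start : iv.z_end + 1] = True
    return DetectionResult(final, candidates, flags, profile)


# ---------------------------------------------------------------------------
# threshold fitting

def _segment_bounds(seg: int, n_slices: int, n_segments: int) -> Tuple[int, int]:
    """Half-open slice range [lo, hi) of one axial segment."""
    lo = int(np.ceil(seg * n_slices / n_segments))
    hi = int(np.ceil((seg + 1) * n_slices / n_segments))
    # align with segment_of's floor rule
    while lo > 0 and segment_of(lo - 1, n_slices, n_segments) == seg:
        lo -= 1
    while hi < n_slices and segment_of(hi, n_slices, n_segments) == seg:
        hi += 1
    return lo, hi


def _segment_dice(case: LabeledVolume, segment: int, p: float,
                  n_segments: int,
                  lengths: Sequence[int] = DEFAULT_LENGTHS,
                  cache: Optional[dict] = None) -> Optional[float]:
    """Slice-level Dice of detection at threshold p, scored over one
    segment's slices, or None if the segment holds no ground truth.

    The trial threshold is applied to every candidate window (a truth
    interval may straddle a segment boundary and is only recoverable from
    windows centered in the neighbouring segment); the per-segment scalar
    objective comes from restricting the *scoring* to the segment's slices.
    """
    v = case.volume
    n = v.n_slices
    lo, hi = _segment_bounds(segment, n, n_segments)
    truth = case.truth_slices[lo:hi]
    if not truth.any():
        return None
    key = id(case)
    if cache is not None and key in cache:
        diffs = cache[key]
    else:
        diffs = [
            (iv, interval_difference(v, iv))
            for iv in iter_windows(n, lengths)
        ]
        if cache is not None:
            cache[key] = diffs
    cands = [iv for iv, d in diffs if d < p]
    final = merge_intervals(consolidate(cands))
    flags = np.zeros(n, dtype=bool)
    for iv in final:
        flags[iv.z_start : iv.z_end + 1] = True
    det = flags[lo:hi]
    tp = int(np.count_nonzero(det & truth))
    fp = int(np.count_nonzero(det & ~truth))
    fn = int(np.count_nonzero(~det & truth))
    return dice_from_counts(tp, fp, fn)


def dice_for_threshold(
    cases: Sequence[LabeledVolume], segment: int, p: float,
    n_segments: int = 10, cache: Optional[dict] = None,
) -> float:
    """Mean slice-level Dice over cases with ground truth in the segment."""
    scores = [
        s for case in cases
        if (s := _segment_dice(case, segment, p, n_segments, cache=cache))
        is not None
    ]
    if not scores:
        raise ValueError(f"no case has ground truth in segment {segment}")
    return float(np.mean(scores))


@dataclass(frozen=True)
class FitConfig:
    n_folds: int = 10
    optimizer: str = "grid"   # or "brent"
    grid_step: float = 0.002

    def validate(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.optimizer not in ("grid", "brent"):
            raise ValueError("optimizer must be 'grid' or 'brent'")


@dataclass
class FitResult:
    profile: ThresholdProfile
    fold_dice: List[float]
    segment_loss: List[float]


def _fit_one_segment(cases, segment, cfg, template, cache) -> Optional[Tuple[float, float]]:
    lo, hi = template.bounds

    def loss(p: float) -> float:
        try:
            return 1.0 - dice_for_threshold(
                cases, segment, p, template.n_segments, cache=cache
            )
        except ValueError:
            return np.nan

    if np.isnan(loss((lo + hi) / 2.0)):
        return None
    if cfg.optimizer == "grid":
        grid = np.arange(lo + cfg.grid_step, hi, cfg.grid_step)
        losses = [loss(p) for p in grid]
        i = int(np.argmin(losses))
        return float(grid[i]), float(losses[i])
    res = minimize_scalar(loss, bounds=(lo, hi), method="bounded")
    return float(res.x), float(res.fun)


def fit_thresholds(
    cases: Sequence[LabeledVolume],
    cfg: FitConfig = FitConfig(),
    template: Optional[ThresholdProfile] = None,
) -> FitResult:
    """Fit per-segment thresholds by minimizing mean Dice loss in bounds.

    Unpopulated segments fall back to the mean of the fitted segment
    thresholds (or the bounds midpoint when nothing fits). Cross-validation
    uses contiguous case folds; the final profile is fit on all cases.
    """
    cfg.validate()
    template = template or ThresholdProfile()
    cache: dict = {}

    def fit_all(subset) -> Tuple[List[float], List[float]]:
        fitted: List[Optional[float]] = []
        losses: List[float] = []
        for seg in range(template.n_segments):
            res = _fit_one_segment(subset, seg, cfg, template, cache)
            if res is None:
                fitted.append(None)
                losses.append(np.nan)
            else:
                fitted.append(res[0])
                losses.append(res[1])
        known = [p for p in fitted if p is not None]
        fallback = float(np.mean(known)) if known else sum(template.bounds) / 2.0
        return [p if p is not None else fallback for p in fitted], losses

    # cross-validation: held-out mean Dice per fold
    n_folds = min(cfg.n_folds, len(cases))
    fold_dice: List[float] = []
    if n_folds >= 2:
        idx = np.array_split(np.arange(len(cases)), n_folds)
        for fold in idx:
            if fold.size == 0:
                continue
            train = [c for i, c in enumerate(cases) if i not in set(fold.tolist())]
            test = [cases[i] for i in fold]
            if not train:
                continue
            ths, _ = fit_all(train)
            prof = ThresholdProfile(template.n_segments, ths, template.bounds)
            scores = []
            for seg in range(template.n_segments):
                try:
                    scores.append(
                        dice_for_threshold(test, seg, ths[seg],
                                           template.n_segments, cache=cache)
                    )
                except ValueError:
                    continue
            if scores:
                fold_dice.append(float(np.mean(scores)))

    final_ths, losses = fit_all(list(cases))
    profile = ThresholdProfile(template.n_segments, final_ths, template.bounds)
    return FitResult(profile, fold_dice, losses)
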