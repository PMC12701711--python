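"""Detection and correction metrics.

Dice, multi-level confusion counts (voxel → slice → stack → region
inference), weighted averages, Youden's J, the overfitting index ϕ, and a
mesh-based boundary-smoothness ratio β = S/V with triangle areas computed
via Heron's formula.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes

from .core import ArtifactMask


# ---------------------------------------------------------------------------
# overlap metrics

def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice coefficient 2TP/(2TP+FP+FN); 1.0 when both masks are empty."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    tp = np.count_nonzero(pred & truth)
    denom = 2 * tp + np.count_nonzero(pred & ~truth) + np.count_nonzero(~pred & truth)
    if denom == 0:
        return 1.0
    return 2.0 * tp / denom


def dice_from_counts(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2.0 * tp / denom


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int
    level: str = "voxel"

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return 1.0 if d == 0 else self.tp / d

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return 1.0 if d == 0 else self.tn / d

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.fn + self.tn
        return 1.0 if total == 0 else (self.tp + self.tn) / total

    @property
    def dice(self) -> float:
        return dice_from_counts(self.tp, self.fp, self.fn)

    @property
    def youden_j(self) -> float:
        return youden_j(self.sensitivity, self.specificity)


def _positive_slices(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    return mask.reshape(-1, mask.shape[2]).sum(axis=0) >= min_voxels


def _runs(flags: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs of consecutive True entries as inclusive (start, end)."""
    runs = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(flags) - 1))
    return runs


def _boxes(mask: np.ndarray) -> List[Tuple[Tuple[int, int], ...]]:
    labeled, n = ndimage.label(mask)
    boxes = []
    for sl in ndimage.find_objects(labeled):
        boxes.append(tuple((s.start, s.stop - 1) for s in sl))
    return boxes


def _box_iou(a, b) -> float:
    inter = 1.0
    vol_a = vol_b = 1.0
    for (alo, ahi), (blo, bhi) in zip(a, b):
        lo, hi = max(alo, blo), min(ahi, bhi)
        if hi < lo:
            return 0.0
        inter *= hi - lo + 1
        vol_a *= ahi - alo + 1
        vol_b *= bhi - blo + 1
    return inter / (vol_a + vol_b - inter)


def infer_level(
    pred: ArtifactMask | np.ndarray,
    truth: ArtifactMask | np.ndarray,
    level: str = "voxel",
    min_voxels: int = 1,
    stack_coverage: float = 0.5,
    region_iou: float = 0.25,
) -> ConfusionCounts:
    """Aggregate voxel-level masks to a coarser unit and count TP/FP/FN/TN.

    slice: a slice is positive when it holds >= min_voxels labeled voxels
    (same rule for both masks). stack: maximal runs of positive truth slices;
    a truth stack is TP when >= stack_coverage of its slices are predicted
    positive, a predicted stack is FP when it overlaps no truth stack.
    region: connected components -> axis-aligned boxes; a truth box is TP
    when some predicted box reaches IoU >= region_iou, a predicted box is FP
    when it overlaps no truth box; no TN is defined at region level.
    """
    p = (pred.data if isinstance(pred, ArtifactMask) else np.asarray(pred)) > 0
    t = (truth.data if isinstance(truth, ArtifactMask) else np.asarray(truth)) > 0
    if p.shape != t.shape:
        raise ValueError("shape mismatch")

    if level == "voxel":
        tp = int(np.count_nonzero(p & t))
        fp = int(np.count_nonzero(p & ~t))
        fn = int(np.count_nonzero(~p & t))
        tn = int(np.count_nonzero(~p & ~t))
        return ConfusionCounts(tp, fp, fn, tn, level)

    if level == "slice":
        ps = _positive_slices(p, min_voxels)
        ts = _positive_slices(t, min_voxels)
        tp = int(np.count_nonzero(ps & ts))
        fp = int(np.count_nonzero(ps & ~ts))
        fn = int(np.count_nonzero(~ps & ts))
        tn = int(np.count_nonzero(~ps & ~ts))
        return ConfusionCounts(tp, fp, fn, tn, level)

    if level == "stack":
        ps = _positive_slices(p, min_voxels)
        ts = _positive_slices(t, min_voxels)
        truth_stacks = _runs(ts)
        pred_stacks = _runs(ps)
        tp = fn = 0
        for s, e in truth_stacks:
            cov = np.count_nonzero(ps[s : e + 1]) / (e - s + 1)
            if cov >= stack_coverage:
                tp += 1
            else:
                fn += 1
        fp = sum(
            1 for s, e in pred_stacks
            if not np.any(ts[s : e + 1])
        )
        # TN: negative truth gaps (incl. ends) with no predicted stack
        neg_runs = _runs(~ts)
        tn = sum(1 for s, e in neg_runs if not np.any(ps[s : e + 1]))
        return ConfusionCounts(tp, fp, fn, tn, level)

    if level == "region":
        truth_boxes = _boxes(t)
        pred_boxes = _boxes(p)
        tp = sum(
            1 for tb in truth_boxes
            if any(_box_iou(tb, pb) >= region_iou for pb in pred_boxes)
        )
        fn = len(truth_boxes) - tp
        fp = sum(
            1 for pb in pred_boxes
            if all(_box_iou(tb, pb) == 0.0 for tb in truth_boxes)
        )
        return ConfusionCounts(tp, fp, fn, 0, level)

    raise ValueError(f"unknown level {level!r}")


def weighted_average(values: Sequence[float], weights: Sequence[float]) -> float:
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total == 0:
        raise ValueError("weights sum to zero")
    return float((v * w).sum() / total)


def youden_j(sensitivity: float, specificity: float) -> float:
    """J = sensitivity + specificity − 1; 1 perfect, 0 chance, −1 worst."""
    return sensitivity + specificity - 1.0


@dataclass
class OverfitIndex:
    dl_train: float
    dl_test: float

    @property
    def phi(self) -> float:
        denom = self.dl_train + self.dl_test
        if denom == 0:
            raise ValueError("ϕ undefined when both Dice losses are zero")
        return (self.dl_train - self.dl_test) / denom + 1.0

    @property
    def verdict(self) -> str:
        p = self.phi
        if p >= 1.0:
            return "generalizable"
        if p > 0.85:
            return "acceptable"
        return "overfit"


def overfit_index(dl_train: float, dl_test: float) -> OverfitIndex:
    """Overfitting index ϕ = (DL_train − DL_test)/(DL_train + DL_test) + 1.

    Bounded in [0, 2]; ϕ < 1 implies over-fitting to the training set,
    ϕ < 0.85 typically severe.
    """
    for v in (dl_train, dl_test):
        if not 0.0 <= v <= 1.0:
            raise ValueError("Dice losses must lie in [0, 1]")
    idx = OverfitIndex(dl_train, dl_test)
    idx.phi  # raises on the (0, 0) degenerate point
    return idx


# ---------------------------------------------------------------------------
# boundary smoothness

def heron_area(a: float, b: float, c: float) -> float:
    """Area of a triangle from its side lengths."""
    s = (a + b + c) / 2.0
    val = s * (s - a) * (s - b) * (s - c)
    return float(np.sqrt(max(val, 0.0)))


def mesh_surface_area_heron(verts: np.ndarray, faces: np.ndarray) -> float:
    """Total surface area of a triangle mesh, per-triangle Heron's formula."""
    tri = verts[faces]  # (T, 3, 3)
    a = np.linalg.norm(tri[:, 0] - tri[:, 1], axis=1)
    b = np.linalg.norm(tri[:, 1] - tri[:, 2], axis=1)
    c = np.linalg.norm(tri[:, 2] - tri[:, 0], axis=1)
    s = (a + b + c) / 2.0
    val = np.clip(s * (s - a) * (s - b) * (s - c), 0.0, None)
    return float(np.sqrt(val).sum())


@dataclass
class SmoothnessResult:
    surface_area: float       # mm^2
    volume: float             # mm^3
    mesh_triangle_count: int

    @property
    def beta(self) -> float:
        return self.surface_area / self.volume


def boundary_smoothness(
    mask: np.ndarray,
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0),
    bbox: Optional[Tuple[slice, slice, slice]] = None,
) -> SmoothnessResult:
    """β = S/V of a binary mask, optionally restricted to a bounding box.

    The isosurface is triangulated by marching cubes at level 0.5 (the mask
    is zero-padded by one voxel so the surface closes at the grid edge) and
    S is summed from per-triangle Heron areas in physical units.
    """
    m = np.asarray(mask) > 0
    if bbox is not None:
        m = m[bbox]
    if not m.any():
        raise ValueError("empty mask within bounding box")
    padded = np.pad(m.astype(np.float64), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=spacing)
    area = mesh_surface_area_heron(verts, faces)
    volume = float(np.count_nonzero(m)) * float(np.prod(spacing))
    return SmoothnessResult(area, volume, len(faces))
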