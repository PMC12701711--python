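"""Artifact-omics: per-component shape features and group comparisons.

Each connected artifact component above a size floor yields a morphological
feature vector (volume, bounding-box volume, solidity, extent, equivalent
diameter, PCA-derived axis lengths and their elongation ratios, flatness,
sphericity, compactness). Treating these as measurable phenotypes, two
datasets of components are compared feature-by-feature with a two-sided
Mann–Whitney U test (difference) and TOST equivalence testing within
±0.2 pooled-SD bounds after z-scoring, with Benjamini–Hochberg FDR across
features applied separately to each test family.

Axis lengths use the ellipsoid convention: length = 4·√eigenvalue of the
voxel-coordinate covariance (a uniform-density ellipsoid with semi-axis a
has coordinate variance a²/4 along that axis, so 4·√var recovers 2a).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import QhullError
from skimage.measure import label as cc_label
from skimage.measure import marching_cubes, regionprops
from statsmodels.stats.multitest import multipletests

from .core import ArtifactMask
from .metrics import mesh_surface_area_heron


@dataclass
class OmicsFeatureVector:
    volume: float
    bbox_volume: float
    solidity: float
    extent: float
    equivalent_diameter: float
    major_axis_length: float
    intermediate_axis_length: float
    minor_axis_length: float
    elongation_major_minor: float
    elongation_major_intermediate: float
    elongation_intermediate_minor: float
    flatness: float
    sphericity: float
    compactness: float

    @classmethod
    def feature_names(cls) -> List[str]:
        return [f.name for f in fields(cls)]


def _pca_axis_lengths(coords: np.ndarray) -> np.ndarray:
    """Descending ellipsoid axis lengths (4·√eigenvalue) from voxel coords."""
    centered = coords - coords.mean(axis=0)
    cov = np.cov(centered.T)
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    return 4.0 * np.sqrt(eigvals)


def _component_surface_area(component: np.ndarray) -> float:
    padded = np.pad(component.astype(np.float64), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5)
    return mesh_surface_area_heron(verts, faces)


def extract_features(
    art: ArtifactMask | np.ndarray,
    label: int = 1,
    min_volume: int = 64,
) -> List[OmicsFeatureVector]:
    """Feature vectors for every connected component of the given label with
    at least ``min_volume`` voxels. Components smaller than 4 voxels are
    always skipped (degenerate PCA)."""
    data = art.data if isinstance(art, ArtifactMask) else np.asarray(art)
    binary = data == label if label else data > 0
    if not binary.any():
        raise ValueError(f"mask holds no voxels with label {label}")
    labeled = cc_label(binary, connectivity=1)
    out: List[OmicsFeatureVector] = []
    for prop in regionprops(labeled):
        v = int(prop.area)
        if v < max(min_volume, 4):
            continue
        coords = prop.coords.astype(float)
        bbox_v = float(np.prod([
            prop.bbox[i + 3] - prop.bbox[i] for i in range(3)
        ]))
        try:
            solidity = float(prop.solidity)  # voxel-count / convex-image count
        except (QhullError, ValueError):     # flat component: hull degenerates
            solidity = 1.0
        axes = _pca_axis_lengths(coords)
        major, inter, minor = (float(a) for a in axes)
        eps = 1e-12
        component = labeled == prop.label
        area = _component_surface_area(component)
        eq_d = (6.0 * v / np.pi) ** (1.0 / 3.0)
        out.append(OmicsFeatureVector(
            volume=float(v),
            bbox_volume=bbox_v,
            solidity=min(solidity, 1.0),
            extent=v / bbox_v,
            equivalent_diameter=float(eq_d),
            major_axis_length=major,
            intermediate_axis_length=inter,
            minor_axis_length=minor,
            elongation_major_minor=major / max(minor, eps),
            elongation_major_intermediate=major / max(inter, eps),
            elongation_intermediate_minor=inter / max(minor, eps),
            flatness=minor / max(major, eps),
            sphericity=np.pi ** (1.0 / 3.0) * (6.0 * v) ** (2.0 / 3.0) / area,
            compactness=v / area ** 1.5,
        ))
    return out


def features_to_frame(features: Sequence[OmicsFeatureVector]) -> pd.DataFrame:
    return pd.DataFrame([vars(f) for f in features])


# ---------------------------------------------------------------------------
# group comparison

@dataclass
class GroupComparison:
    feature: str
    u_p: float
    tost_p_lower: float
    tost_p_upper: float
    u_q: float = np.nan
    tost_q: float = np.nan
    verdict: str = "inconclusive"

    @property
    def tost_p(self) -> float:
        return max(self.tost_p_lower, self.tost_p_upper)


def _tost_welch(a: np.ndarray, b: np.ndarray, bound: float) -> tuple[float, float]:
    """Two one-sided Welch t-tests against ±bound on the mean difference."""
    p_lower = stats.ttest_ind(a + bound, b, equal_var=False,
                              alternative="greater").pvalue
    p_upper = stats.ttest_ind(a - bound, b, equal_var=False,
                              alternative="less").pvalue
    return float(p_lower), float(p_upper)


def compare_groups(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    eq_bound: float = 0.2,
    alpha: float = 0.05,
) -> List[GroupComparison]:
    """Feature-wise difference (Mann–Whitney U) and equivalence (TOST)
    testing between two component-feature tables.

    Features are z-scored on the pooled sample so the ±eq_bound equivalence
    margin is in pooled-SD units. BH-FDR is applied across features,
    separately to the U p-values and the TOST p-values. Verdicts:
    ``equivalent`` (TOST passes, U does not reject), ``different`` (U
    rejects, TOST fails), ``both`` (statistically different yet practically
    equivalent), else ``inconclusive``. Constant features are skipped.
    """
    common = [c for c in group_a.columns if c in group_b.columns]
    results: List[GroupComparison] = []
    for feat in common:
        a = np.asarray(group_a[feat], dtype=float)
        b = np.asarray(group_b[feat], dtype=float)
        if len(a) < 3 or len(b) < 3:
            raise ValueError(f"need >= 3 observations per group for {feat}")
        pooled = np.concatenate([a, b])
        sd = pooled.std(ddof=1)
        if sd == 0:
            warnings.warn(f"feature {feat!r} is constant; skipped", stacklevel=2)
            continue
        az = (a - pooled.mean()) / sd
        bz = (b - pooled.mean()) / sd
        u_p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        p_lo, p_hi = _tost_welch(az, bz, eq_bound)
        results.append(GroupComparison(feat, u_p, p_lo, p_hi))

    if not results:
        return results
    u_q = multipletests([r.u_p for r in results], method="fdr_bh")[1]
    tost_q = multipletests([r.tost_p for r in results], method="fdr_bh")[1]
    for r, uq, tq in zip(results, u_q, tost_q):
        r.u_q, r.tost_q = float(uq), float(tq)
        different = r.u_q < alpha
        equivalent = r.tost_q < alpha
        if different and equivalent:
            r.verdict = "both"
        elif equivalent:
            r.verdict = "equivalent"
        elif different:
            r.verdict = "different"
        else:
            r.verdict = "inconclusive"
    return results


def comparisons_to_frame(results: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([
        {"feature": r.feature, "u_p": r.u_p, "u_q": r.u_q,
         "tost_p_lower": r.tost_p_lower, "tost_p_upper": r.tost_p_upper,
         "tost_q": r.tost_q, "verdict": r.verdict}
        for r in results
    ])


def paired_spearman(feat_a: Sequence[float], feat_b: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p-value."""
    a = np.asarray(feat_a, dtype=float)
    b = np.asarray(feat_b, dtype=float)
    if a.size != b.size or a.size < 4:
        raise ValueError("need equal-length vectors with >= 4 entries")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("Spearman correlation undefined for constant input")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)
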