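"""Synthetic dataset assembly.

Clean phase series act as templates: each template is cycled through the
(h, NPB) stack combinations Nc times, every cycle with a freshly drawn
artifact visibility σg, secondary phase (per a pairing criterion), stack
positions, and an optional batch of interpolation intervals. Clean cases
held out as "untouched" become artifact-free negatives for testing.

Also hosts the foreground-oversampling decay schedule
R(e) = R_target + (R_initial − R_target)·exp(−k·(e − e_start)), a training
utility reported here as a standalone function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import ArtifactMask, LungMask, Volume, phase_labels
from .interp import InterpParams, infuse_interpolation, perturb_intervals
from .phantom import PhaseSeries
from .phasebin import PhaseBinningParams, infuse_phase_binning
from .preprocess import make_region_mask, truncate_and_normalize

TEN_PHASES = phase_labels(10)


@dataclass(frozen=True)
class CombinationSpec:
    """Allowed (stack height, max phase-binning stacks, max interpolation
    intervals) triples; defaults give the canonical seven (h, NPB) pairs."""

    entries: Tuple[Tuple[int, int, int], ...] = ((4, 4, 8), (8, 2, 4), (16, 1, 2))

    def validate(self) -> None:
        heights = [e[0] for e in self.entries]
        if len(set(heights)) != len(heights):
            raise ValueError("stack heights must be distinct")
        if any(npb < 1 or nint < 1 for _, npb, nint in self.entries):
            raise ValueError("maxima must be >= 1")

    def nint_max(self, h: int) -> int:
        for hh, _, nint in self.entries:
            if hh == h:
                return nint
        raise KeyError(h)


def enumerate_combinations(spec: CombinationSpec) -> List[Tuple[int, int]]:
    """All (h, NPB) pairs with 1 <= NPB <= NPB_max(h), ascending h then NPB."""
    spec.validate()
    return [
        (h, n)
        for h, npb_max, _ in sorted(spec.entries)
        for n in range(1, npb_max + 1)
    ]


def choose_secondary_phase(
    phase: str, pairing: str, rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> str:
    """Pick the secondary phase I~ for a given primary phase.

    opposite: the directly opposite phase (index + 5 mod 10).
    opposite_nbhd: uniform over the opposite phase ± 2 neighbours.
    random: uniform over the 9 other phases.
    """
    if phase not in TEN_PHASES:
        raise ValueError(f"unknown phase label {phase!r}")
    rng = np.random.default_rng(seed) if rng is None else rng
    i = TEN_PHASES.index(phase)
    opp = (i + 5) % 10
    if pairing == "opposite":
        return TEN_PHASES[opp]
    if pairing == "opposite_nbhd":
        return TEN_PHASES[(opp + int(rng.integers(-2, 3))) % 10]
    if pairing == "random":
        others = [p for p in TEN_PHASES if p != phase]
        return others[int(rng.integers(0, 9))]
    raise ValueError(f"unknown pairing criterion {pairing!r}")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class SplitAssignment:
    train_templates: List[int]
    test_templates: List[int]
    untouched: List[int]


@dataclass(frozen=True)
class BuildConfig:
    pairing: str = "opposite_nbhd"
    nc_train: int = 4
    nc_test: int = 1
    template_split: float = 0.85
    train_split: float = 0.85
    p_zero_interp: float = 0.3
    sigma_g_range: Tuple[float, float] = (0.5, 3.0)
    # zero by default: the phantom torso is phase-static, so an in-plane
    # shift would imprint a chest-wall ring into MPB that dwarfs the
    # diaphragm artifact; set > 0 for data with genuine inter-phase motion
    shift_intensity: int = 0
    lambda0: float = 0.05
    min_component: int = 50
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.template_split < 1 and 0 < self.train_split < 1):
            raise ValueError("split fractions must lie in (0, 1)")
        if self.nc_train < self.nc_test or self.nc_test < 1:
            raise ValueError("need nc_train >= nc_test >= 1")
        if not 0 <= self.p_zero_interp <= 1:
            raise ValueError("p_zero_interp must lie in [0, 1]")
        if self.pairing not in ("opposite", "opposite_nbhd", "random"):
            raise ValueError(f"unknown pairing {self.pairing!r}")


def split_templates(n_clean: int, cfg: BuildConfig,
                    rng: Optional[np.random.Generator] = None) -> SplitAssignment:
    """Two-stage partition: templates vs untouched (0.85/0.15), then the
    templates into train/test (0.85/0.15). Round-half-up at each stage;
    untouched cases are test-only negatives never seen in training."""
    if n_clean < 3:
        raise ValueError("need at least 3 clean cases")
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    order = rng.permutation(n_clean)
    n_templates = _round_half_up(n_clean * cfg.template_split)
    templates, untouched = order[:n_templates], order[n_templates:]
    n_train = _round_half_up(n_templates * cfg.train_split)
    return SplitAssignment(
        sorted(int(i) for i in templates[:n_train]),
        sorted(int(i) for i in templates[n_train:]),
        sorted(int(i) for i in untouched),
    )


@dataclass
class CaseRecord:
    case_id: str
    split: str                    # train | test | untouched
    template_index: int
    primary_phase: str
    secondary_phase: Optional[str]
    h: Optional[int]
    n_pb: Optional[int]
    n_int: int
    sigma_g: Optional[float]
    volume: Volume
    artifact_mask: ArtifactMask
    lung_mask: LungMask
    region_mask: object
    rejected_pb: bool = False

    @property
    def artifact_volume_pct(self) -> float:
        """Lung volume affected by artifacts (%): artifact ∩ lung / lung."""
        lung = self.lung_mask.data > 0
        n_lung = max(int(lung.sum()), 1)
        affected = int(np.count_nonzero((self.artifact_mask.data > 0) & lung))
        return 100.0 * affected / n_lung

    @property
    def artifact_slices(self) -> int:
        return int(self.artifact_mask.any_artifact().any(axis=(0, 1)).sum())


@dataclass
class DatasetManifest:
    cases: List[CaseRecord]
    config: BuildConfig
    combinations: List[Tuple[int, int]]
    n_rejections: int

    def summary(self) -> pd.DataFrame:
        """Per-split mean artifact volume % and affected slices, with 95% CI
        half-widths (normal approximation)."""
        rows = []
        for split in ("train", "test", "untouched"):
            sub = [c for c in self.cases if c.split == split]
            if not sub:
                continue
            vol = np.array([c.artifact_volume_pct for c in sub])
            sli = np.array([c.artifact_slices for c in sub], dtype=float)
            n = len(sub)
            ci = 1.96 / np.sqrt(n) if n > 1 else 0.0
            rows.append({
                "split": split,
                "n_cases": n,
                "avg_volume_pct": vol.mean(),
                "ci95_volume_pct": ci * vol.std(ddof=1) if n > 1 else 0.0,
                "avg_slices": sli.mean(),
                "ci95_slices": ci * sli.std(ddof=1) if n > 1 else 0.0,
            })
        return pd.DataFrame(rows)


def _normalized_series(series: PhaseSeries) -> dict:
    out = {}
    for label, vol, mask in series:
        v = vol if vol.intensity_domain == "normalized" else truncate_and_normalize(vol)
        out[label] = (v, mask)
    return out


def build_dataset(
    series_list: Sequence[PhaseSeries],
    cfg: BuildConfig = BuildConfig(),
    comb: CombinationSpec = CombinationSpec(),
) -> DatasetManifest:
    """Assemble a synthetic dataset from clean template series.

    For each train/test template and each (h, NPB) combination, nc_train or
    nc_test cases are generated: σg is drawn log-uniformly, the secondary
    phase follows the pairing criterion, phase-binning infusion may reject
    (retried internally; a terminal rejection is logged and the case is
    emitted without a PB artifact only if interpolation applies, else
    skipped), and interpolation intervals are added with probability
    1 − p_zero_interp. Untouched series become artifact-free cases.
    """
    cfg.validate()
    comb.validate()
    rng = np.random.default_rng(cfg.seed)
    combos = enumerate_combinations(comb)
    split = split_templates(len(series_list), cfg, rng=rng)

    cases: List[CaseRecord] = []
    n_rejections = 0

    def emit_template_cases(tpl_idx: int, split_tag: str, n_cycles: int):
        nonlocal n_rejections
        series = series_list[tpl_idx]
        phases = _normalized_series(series)
        labels = [lab for lab, _, _ in series]
        for cycle in range(n_cycles):
            for h, npb in combos:
                primary = labels[int(rng.integers(0, len(labels)))]
                vol, lung = phases[primary]
                lo, hi = cfg.sigma_g_range
                sigma_g = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                if len(labels) == 10:
                    secondary = choose_secondary_phase(primary, cfg.pairing, rng=rng)
                else:  # short series (e.g. 2-phase phantoms): any other phase
                    others = [l for l in labels if l != primary]
                    secondary = others[int(rng.integers(0, len(others)))]
                sec_vol, _ = phases[secondary]
                pb_params = PhaseBinningParams(
                    h=h, n_stacks=npb, sigma_g=sigma_g,
                    shift_intensity=cfg.shift_intensity,
                    lambda0=cfg.lambda0, min_component=cfg.min_component,
                )
                result = infuse_phase_binning(vol, sec_vol, lung, pb_params, rng=rng)
                if not result.accepted:
                    n_rejections += 1
                    continue
                out_vol, pb_mask = result.volume, result.artifact_mask
                n_int = 0
                if rng.uniform() > cfg.p_zero_interp:
                    n_int = int(rng.integers(1, comb.nint_max(h) + 1))
                if n_int > 0:
                    ip = InterpParams(h=max(h, 3), n_intervals=n_int,
                                      sigma_g=sigma_g)
                    try:
                        intervals = perturb_intervals(ip, out_vol.n_slices, rng=rng)
                        out_vol, int_mask = infuse_interpolation(out_vol, intervals)
                        mask = ArtifactMask.combine(pb_mask, int_mask)
                    except ValueError:
                        n_int = 0
                        mask = pb_mask
                else:
                    mask = pb_mask
                cases.append(CaseRecord(
                    case_id=f"tpl{tpl_idx}_{split_tag}_c{cycle}_h{h}_n{npb}",
                    split=split_tag, template_index=tpl_idx,
                    primary_phase=primary, secondary_phase=secondary,
                    h=h, n_pb=npb, n_int=n_int, sigma_g=sigma_g,
                    volume=out_vol, artifact_mask=mask, lung_mask=lung,
                    region_mask=make_region_mask(lung),
                ))

    for idx in split.train_templates:
        emit_template_cases(idx, "train", cfg.nc_train)
    for idx in split.test_templates:
        emit_template_cases(idx, "test", cfg.nc_test)
    for idx in split.untouched:
        series = series_list[idx]
        phases = _normalized_series(series)
        label = next(iter(phases))
        vol, lung = phases[label]
        cases.append(CaseRecord(
            case_id=f"tpl{idx}_untouched", split="untouched",
            template_index=idx, primary_phase=label, secondary_phase=None,
            h=None, n_pb=None, n_int=0, sigma_g=None,
            volume=vol,
            artifact_mask=ArtifactMask(np.zeros(vol.shape, np.uint8), vol.spacing),
            lung_mask=lung, region_mask=make_region_mask(lung),
        ))
    return DatasetManifest(cases, cfg, combos, n_rejections)


# ---------------------------------------------------------------------------
# foreground-oversampling schedule

@dataclass(frozen=True)
class OversamplingSchedule:
    r_initial: float = 0.8
    r_target: float = 0.4
    e_start: int = 5
    decay_k: float = 0.1

    def validate(self) -> None:
        if not self.r_initial >= self.r_target > 0:
            raise ValueError("need r_initial >= r_target > 0")
        if self.decay_k <= 0:
            raise ValueError("decay constant must be > 0")


def oversampling_rate(e: int | float, s: OversamplingSchedule) -> float:
    """R(e): r_initial before e_start, exponential decay toward r_target after.

    R(e) = r_target + (r_initial − r_target)·exp(−k·(e − e_start)).
    """
    s.validate()
    if e < 0:
        raise ValueError("epoch must be >= 0")
    if e < s.e_start:
        return s.r_initial
    return s.r_target + (s.r_initial - s.r_target) * math.exp(
        -s.decay_k * (e - s.e_start)
    )
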