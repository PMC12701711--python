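# Methods

This note records the models, parameter choices, and numerical decisions
behind `artifactlab`, and what the test suite does and does not establish.

## Phantom

The phantom is an analytic torso: an elliptic-cylinder soft-tissue body
(≈ 40 HU) on an air background (≈ −1000 HU), a posterior spine cylinder
(≈ 500 HU), and two lung ellipsoids (≈ −800 HU). Breathing is parameterized
by the phase fraction `f(i) = (1 − cos(2πi/n))/2`, zero at T00 and one at
the mid-cycle phase, driving two coupled effects:

- the **diaphragm** (lung floor) rises by `f · diaphragm_amplitude` voxels
  (default 8), and
- the lung semi-axes contract in-plane by `f · deflation` (default 0.15),
  so *every* axial lung slice differs between distant phases, not just the
  floor band. Without this, a mis-binned stack placed away from the floor
  would carry no visible artifact at all, which no real 4DCT exhibits.

The lungs are confined to an inner torso ellipse two voxels inside the body
outline, so an intensity-based segmenter always sees a closed chest wall.
Texture is Gaussian-filtered white noise rescaled to 20% of `noise_sd`,
plus i.i.d. voxel noise of sd `noise_sd` (default 20 HU, a plausible
clinical noise level). A strictly positive `noise_sd` is required: the
rule-based detector depends on adjacent slices being distinguishable, and
with 20 HU noise the minimum slice-to-slice max-difference on the
normalized scale is ≈ 0.05 inside the lungs and ≈ 0.01 in pure-air slices
(HU clipping at −1024 halves the noise there) — both far above the 1e−3
epsilon threshold.

Masks are computed from the noise-free geometry, so they follow the
diaphragm exactly. Defaults (96×96×96 voxels at 1 mm) are a free choice;
tests run 24–32 voxel in-plane grids for speed.

## Phase-binning generator

Stacks of height `h` are placed uniformly at random, non-overlapping,
within the inferior half of the lung z-extent. The binary slice profile is
feathered per stack with a 1-D Gaussian (sd `sigma_g`, the artifact
visibility) and renormalized to peak 1 — feathering widens a stack's
support without attenuating its center, so large `sigma_g` gives larger,
edge-faded artifacts rather than uniformly fainter ones. The secondary
phase is shifted in-plane per stack by an integer offset uniform in
`[−si, si]²` with edge replication. A draw is accepted only when the
weighted difference `C = M^g ⊙ (I − I~g)` is majority non-positive
(zero-valued voxels count on both sides of the inequality, exactly as the
condition is written, which makes self-pairing with zero shift always
inadmissible). The ground-truth mask thresholds `|I − I^|` at
`λ = λ₀·σg` (λ₀ = 0.05 normalized units), then applies a ball-closing of
radius 2 and drops connected components under 50 voxels. λ₀ and the
morphology radii are configuration, not claimed constants.

**Shift caveat.** The phantom torso is phase-static, so any nonzero `si`
imprints a chest-wall ring into the difference image that dwarfs the
diaphragm artifact and — once "corrected" with a lung-like fill value —
dissolves the chest wall. Dataset building and the correction cohort
therefore default to `si = 0`; the shift remains available for data with
genuine inter-phase body motion.

## Interpolation generator and detector

Interpolation artifacts are exact linear slice interpolation between the
interval endpoints; the mask labels every slice of the interval, endpoints
included. Interval endpoints are perturbed by `round(N(0, σg))`, clamped to
keep at least one interior slice; overlapping intervals merge.

The detector re-simulates the artifact over every sliding window of length
3 and 4 and flags windows whose interior max-absolute difference falls
strictly below the threshold of the segment containing the window's center
slice (the axial range is divided into `Ns = 10` equal segments).
Candidates are consolidated by dropping contained intervals and merging
overlapping or abutting ones — consecutive subintervals of one long
artifact reunite into the full interval, which is why testing only lengths
3–4 recovers the same slice set as an exhaustive all-length search (this
equivalence is asserted against a brute-force oracle in the tests). Because
generator and detector share the same interpolation formula, epsilon
thresholds give perfect slice-level detection on generated data; on real
scanners this holds only insofar as the vendor interpolation is linear.

Threshold fitting minimizes the mean slice-level Dice loss per segment
within bounds (0.2, 0.3), by default on a 0.002 grid (bounded Brent is the
alternative). During fitting the trial threshold is applied to every
candidate window and only the *scoring* is restricted to the segment's
slices: a ground-truth interval straddling a segment boundary is only
recoverable with help from windows centered in the neighbouring segment,
and penalizing that irrecoverable tail would bias every threshold. The
"separated world" used to validate fitting needs the clean-interval noise
floor above the 0.3 upper bound: the per-voxel difference sd for a clean
window is `noise_sd/1624 · √1.5`, and its in-plane maximum over ≥ 1024
voxels concentrates near 3σ, so `noise_sd = 200 HU` on 32×32 slices puts
the floor near 0.45. This was fixed by that arithmetic before the tests
were run, not tuned to them.

## Correction

Phase-binning voxels are replaced by the mean lung intensity in a 5-voxel
dilation shell around the artifact (artifact voxels excluded; global lung
mean as fallback). Interpolation voxels are never corrected — every voxel
of a smeared interval is wrong, and no constant fill can restore it.

Since no deep-learning segmenter is in scope, downstream lung masks for
evaluation come from a deliberately simple intensity-threshold segmenter
(air-like = normalized < 0.35): 6-connected components, border-touching
components discarded as outside-body air, small components dropped, and a
one-voxel opening beforehand so a pinhole breach of the chest wall cannot
fuse lung with background (the removed boundary layer is restored by a
single constrained dilation). Evaluation is restricted to the artifact
bounding box plus 3 voxels: Dice of affected/corrected masks against the
clean mask, boundary smoothness β = S/V of each (β is `nan` for a mask
wiped out inside the box; such cases are excluded from the Spearman
pairing), Wilcoxon signed-rank across a cohort, Spearman ρ between clean
and corrected β.

## Metrics

β uses marching cubes at level 0.5 on the zero-padded mask with spacing
applied, and sums per-triangle areas via Heron's formula. On a digital ball
of radius 15 voxels this lands within 10% of the analytic 3/r (the
voxelized isosurface slightly overestimates area). Slice/stack/region
inference from voxel masks uses: slice positive at ≥ 1 labeled voxel;
truth stacks (maximal positive runs) count as detected at ≥ 50% slice
coverage; region boxes (per connected component) match at IoU ≥ 0.25, with
no true-negative defined at region level. These aggregation rules are
configuration choices. The overfitting index
`ϕ = (DL_tr − DL_te)/(DL_tr + DL_te) + 1` is undefined at (0, 0) and
raises there.

## Artifact-omics

Per connected component (≥ 64 voxels; < 4 voxels is degenerate for PCA):
volume, bounding-box volume, solidity (voxel count over convex-image voxel
count), extent, equivalent diameter `(6V/π)^{1/3}`, PCA axis lengths with
the ellipsoid convention `length = 4·√eigenvalue` (a uniform ellipsoid with
semi-axis a has coordinate variance a²/4), elongation ratios, flatness,
`sphericity = π^{1/3}(6V)^{2/3}/A`, and `compactness = V/A^{3/2}` with A
the Heron-mesh surface area. Group comparison z-scores each feature on the
pooled sample, runs a two-sided Mann–Whitney U test and a TOST with ±0.2
pooled-SD bounds as two one-sided Welch t-tests, and applies
Benjamini–Hochberg FDR across features separately per test family.
Verdicts: *equivalent* (TOST passes, U does not reject), *different* (U
rejects, TOST fails), *both* (statistically different yet practically
equivalent — possible and meaningful), else *inconclusive*.

## What a green suite establishes — and what it does not

The phantom is a stated world: geometric lungs, stationary torso, Gaussian
noise, and artifact generators that share their forward model with the
detector. Green tests establish internal consistency (formula-level
oracles, determinism, perfect self-detection, direction-of-effect for the
correction) — they do not establish clinical detection rates, which in the
original setting depend on trained segmentation models and real scanner
data. Clinical quantities reported elsewhere (e.g. detection accuracies of
deep models, absolute Dice-improvement fractions) are out of scope here and
are not asserted by any test.

## Known limitations

- No airways, vasculature, tumors, or deformable inter-phase motion in the
  phantom; left/right lungs are mirror-symmetric.
- The intensity-threshold segmenter is a stand-in for a real lung
  segmenter and is only as robust as its opening radius against wall
  breaches.
- Interpolation detection assumes vendor interpolation is voxel-wise
  linear along z.
- Dataset summary statistics (artifact volume %, affected slices) are
  computed over small phantom grids and are not comparable in magnitude to
  clinical cohorts.
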