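# Methods

This note documents the models, conventions and design choices behind
`lungquant`, in the spirit of a package's statistical/methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## CT segmentation

**Region growing.** The lung is extracted as the face-connected
(6-connectivity) component of voxels in the HU window [-1000, -150]
containing a bronchus seed. 6-connectivity is the conservative "magic wand"
behaviour: it cannot jump diagonal gaps, which keeps the grow from leaking
through thin soft-tissue walls. The oracle tests (brute-force BFS flood
fill) pin this choice; changing connectivity is an API-visible behaviour
change, not a tuning knob.

**Refinement.** Morphological clean-up runs in the fixed order
dilation (grow_r) → erosion (shrink_r) → 3D hole filling → smoothing
(closing then opening, smooth_r), all with the 6-neighbour unit ball
iterated r times. Defaults are grow_r = shrink_r = smooth_r = 1 with hole
filling on. The grow/shrink pair is a closing: it seals one-voxel pinholes
in the lung surface before hole filling, which is what lets interior
consolidations (out of the grow window because they are dense) be recovered
as filled cavities. Hole filling removes exactly the complement cavities not
connected to the grid boundary, so open structures such as the
conducting-airway lumen — which reaches the mediastinum — stay open.

**Airway measurement.** The conducting-airway lumen is grown from the same
trachea seed restricted to the lung mask and HU ≤ -920 (near-pure air; the
alveolar parenchyma is brighter because of partial-volume mixing). Each
lumen voxel's inscribed-sphere diameter is `(2·EDT − 1) · voxel_edge`, with
EDT the Euclidean distance transform in voxel units. EDT measures
centre-to-centre distance to the nearest background voxel; subtracting one
voxel converts it to a lumen width, so a single-voxel tube measures exactly
one voxel edge and the per-voxel diameter can never fall below it. At 35 µm
the discretization uncertainty of this convention is about one voxel edge,
which the tests treat as the tolerance on analytic cylinder fixtures.

**Branch-level exclusion.** The >200 µm size exclusion operates on branches,
not voxels: the lumen skeleton (scikit-image 3D skeletonization) is split at
junction voxels (more than two 26-connected skeleton neighbours), each branch
segment carries the maximum per-voxel diameter along its medial axis, every
lumen voxel inherits the value of its nearest medial voxel at least two
voxel edges wide (skeleton fragments inside one-voxel noise pockets are not
representative axes), and whole branches above the cutoff are removed. The
branch maximum is the stable statistic: a branch does not flicker in and out
of exclusion along its taper. Because noise-attached air pockets can still
split the skeleton into short segments near a bronchus mouth, the removal
set additionally includes every lumen voxel covered by a maximal inscribed
ball wider than the cutoff; for tubular lumina this is equivalent to
whole-branch removal but independent of skeleton topology.

**Left/right split.** After airway exclusion the lungs normally separate
into distinct components, assigned to sides by centroid position relative to
the carina's sagittal plane. The carina is the deepest skeleton junction
near the airway tree's sagittal centre; junctions from small air pockets
attached to the lumen are rejected, with the median airway x position as
fallback. If the lungs remain bridged, a user-supplied world-coordinate
plane partitions voxels by side; with no plane the split fails explicitly
rather than guessing.

## Densitometry

Histograms cover [-1000, 1000] HU in 2001 one-HU bins; raw volume values are
preserved and clamping to the domain happens only at binning (nearest
integer, ties to even). The aerated/tissue threshold is the pooled weighted
mean of a wild-type cohort's histograms, rounded to the nearest integer HU
(ties away from zero). Pooling is voxel-weighted (bin-wise count sum) by
default because it is invariant to how one animal's histogram is split
across files; mouse-weighted pooling (mean of per-animal means) and a
histogram-mode variant are available — in a healthy cohort the mode and the
pooled mean coincide to within a few HU, and a warning-level disagreement
between them is worth inspecting in real data.

The threshold bin itself counts as **tissue**: the threshold represents the
air/alveolar-epithelium interface density, and the interface belongs to the
epithelial side. This boundary convention is fixed and documented; outcomes
are monotone in the threshold, so a sensitivity analysis (e.g. re-running at
a different threshold) preserves group orderings unless distributions cross.

CTDI integrates D(z)/(N·T) over [-50, +50] mm by the trapezoid rule on the
supplied samples, interpolating the interval endpoints; no dose-profile
model is fitted.

## Histomorphometry

The classifier is a full Gaussian discriminant in RGB space: per category a
mean vector, a 3×3 covariance regularized by ε = 10⁻³ on the 0–255 scale,
and a prior (equal by default). A pixel takes the category with maximal
posterior density; exact ties resolve in the fixed order Blue > Pink >
White, and indistinguishable training sets trigger a warning. A "box" mode
(per-channel min/max ranges per category, nearest-mean fallback for
uncovered or multiply-covered pixels) is provided for fidelity to
range-based implementations; the Gaussian mode is primary. Training
requires ≥ 15 pixels per category, warning at exactly 15.

Sections whose total labelled area falls below a configurable minimum
(default 15 mm²) are flagged excluded, never silently dropped. The literal
15 µm² reading of the protocol threshold — smaller than a single pixel at
slide-scanner resolution — is selectable but treated as an apparent typo.
Per-animal aggregation over the three levels uses the unweighted mean of
absolute areas, while fractions are recomputed from summed areas rather than
averaged, so larger sections contribute proportionally to composition.

## Statistics

Values are rank-transformed (ties share the average rank) before the
two-way genotype × age ANOVA with interaction, fitted by OLS and tested
with Type II sums of squares (Type III with sum-to-zero contrasts by flag;
the distinction matters only for unbalanced cells). A constant response
returns F = 0 for every effect by convention. Tukey HSD runs on the ranks
across all genotype-by-age cells. Within-timepoint genotype comparisons are
pooled-variance t-tests on within-timepoint ranks (Welch by flag), declared
significant at α/k with α = 0.05, k = 4 timepoints. Spearman ρ is the
Pearson correlation of tie-averaged ranks; its p-value is an exact
permutation probability for n ≤ 9 and the Student-t approximation
t = ρ√((n−2)/(1−ρ²)) otherwise.

## Phantoms

**CT.** A 60×80×80 grid of 35 µm voxels (≈ 1.9 mm³ of lung — a scaled-down
chest chosen so the full grid of recovery checks runs in seconds per
phantom; the geometry, not the scale, is what the pipeline sees). It
contains a soft-tissue body (40 ± 15 HU), two ellipsoidal lungs whose
parenchyma mixes alveolar air (-850 ± 60 HU) with an alveolar-interface
"wall" class at a configurable fraction (default 0.30), a trachea of
configurable diameter (default 300 µm) bifurcating into one bronchus per
lung with a soft-tissue bronchial wall (30 ± 15 HU, 105 µm thick), and
ellipsoidal infiltrate lesions (-50 ± 40 HU) rejection-sampled strictly
inside the lung until a requested volume fraction is covered.

Two generator choices are deliberate. First, the wall spectrum is centred
at -200 HU (sd 25) rather than exactly on the -256 HU interface value: the
air and wall classes still straddle the threshold, but centring the class on
the threshold would make the generator's own tissue bookkeeping undefined
(half the wall would flip sides at any noise level), and a partial-volume
air/epithelium mixture is physically less dense than the -150 HU edge of
the segmentation window. Second, lesions keep a two-voxel parenchyma
margin: a one-voxel shell around a lesion cluster is a staircase surface
that is not reliably face-connected, so the region grow could never claim
it and hole filling could not close the cavity — a discretization artifact,
not a property of the method being tested. The rendered volume is clipped
to [-1000, 1000] HU, the histogram domain.

Truth masks are the realized (post-sampling) class assignments, so
recovery comparisons are exact bookkeeping, not expectations. What the
phantom does **not** model: scanner noise texture and beam hardening,
respiratory motion, anatomically realistic airway trees beyond one
bifurcation, lobar fissures, and gravity-dependent density gradients.
Passing recovery tests therefore demonstrates correctness of the
segmentation/densitometry machinery, not robustness to scanner physics.

**H&E.** A 160×160 slide with an elliptical lung ROI: pink tissue patches
on white background, blue nuclei inside tissue, optional white vessel
lumens flagged in the truth for reclassification tests. Shape painting is
topped up by individual pixel flips so the realized Blue/Pink/White counts
hit the target fractions (default 0.10/0.40/0.50) exactly before
per-channel Gaussian noise (default sd 8). Class colours (Blue (70,70,160),
Pink (225,150,170), White (245,245,245)) approximate hematoxylin, eosin and
background under standard illumination. Not modelled: stain variation
across scanners, chromatic aberration, tissue folds, out-of-focus blur.

**Cohort.** Each animal carries a latent bivariate-normal pair with Pearson
correlation r = 2·sin(π·ρ/6), the inverse of the normal-theory Spearman
map, so the population Spearman correlation of the CT/histology pair equals
ρ exactly. Genotype and age shifts (defaults: a 2-SD TNF-Tg excess, no age
slope — the cross-sectional design's dominant pattern) are added to both
modalities before mapping to physical scales (mm³, µm²), which leaves all
rank statistics untouched. Calibration checks of the Spearman estimator run
with the shifts at zero, because shared group shifts add correlation on top
of ρ and would change the estimand.

## Numerical conventions

- Voxel indices are 0-based (z, y, x); world position = index × voxel edge.
- Threshold rounding: nearest integer HU, ties away from zero.
- Histogram binning: nearest integer, ties to even (IEEE rounding).
- Covariance regularization ε = 10⁻³ (0–255 RGB scale).
- Spearman exact-permutation cutoff: n ≤ 9 (enumeration of n! orderings).
- Empty masks, all-excluded sections, constant margins and failed splits
  raise or return explicit statuses; nothing degenerates silently.

## Known limitations

- No lobe-level anatomy beyond left/right; no vessel segmentation.
- No beam-hardening/scatter correction or HU recalibration.
- No stain deconvolution or cross-scanner colour normalization; the
  classifier operates on raw RGB, as the workflow it reimplements did.
- The published-cohort reproduction check requires the source study's
  supplementary workbook, which is not redistributed here; without it that
  check reports failure by design (see README).
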