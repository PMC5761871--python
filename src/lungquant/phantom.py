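"""Synthetic micro-CT volumes, H&E-like slides and cohorts with ground truth.

The CT phantom emulates the density structure of a mouse chest scan at
35 um isotropic resolution: a soft-tissue body background, two ellipsoidal
lung fields whose voxels mix near-pure alveolar air (~ -850 HU) with an
alveolar-interface ("wall") spectrum, a branching conducting airway of
controllable diameter with a soft-tissue bronchial wall, and ellipsoidal
inflammatory-infiltrate lesions (~ -50 HU) placed until a requested volume
fraction of the lung is covered. The air and wall class means straddle the
-256 HU air/epithelium interface density, so aerated/tissue threshold
behaviour is exercised meaningfully. The wall spectrum is centred at
-200 HU (sd 25): more than two standard deviations above that threshold —
centring it on the threshold would leave the generator's own tissue-fraction
bookkeeping undefined, half the wall flipping sides at any noise level —
and more than two standard deviations below the -150 HU upper edge of the
segmentation window, since a partial-volume air/epithelium mixture is
strictly less dense than pure soft tissue.

The H&E phantom paints pink tissue patches, blue nuclei and optional empty
vessel lumens on a white background inside an elliptical lung ROI, hitting
requested Blue/Pink/White area fractions exactly before per-channel
Gaussian noise is added.

The cohort generator draws per-animal CT/histology outcome pairs whose
rank correlation is controlled exactly (bivariate normal with Pearson
r = 2 sin(pi * rho_s / 6), the inverse of the normal-theory Spearman map),
with configurable genotype and age shifts shared by both modalities.

All generators are deterministic given their ``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .cohort_stats import DEFAULT_AGES, GENOTYPES, PairedOutcomes
from .histomorphometry import LABEL_CODES, RgbSlide, RoiMask, TrainingSet
from .volume import CtVolume

__all__ = [
    "CtPhantomSpec",
    "HePhantomSpec",
    "CtGroundTruth",
    "HeGroundTruth",
    "generate_ct_phantom",
    "generate_he_phantom",
    "generate_cohort",
    "training_set_from_truth",
]


# ---------------------------------------------------------------------------
# CT phantom
# ---------------------------------------------------------------------------

@dataclass
class CtPhantomSpec:
    """Parameters of the synthetic chest CT volume (HU in [-1000, 1000])."""

    grid_shape: tuple[int, int, int] = (60, 80, 80)
    voxel_edge_um: float = 35.0
    body_hu_mean: float = 40.0
    body_hu_sd: float = 15.0
    lung_air_hu_mean: float = -850.0
    lung_air_hu_sd: float = 60.0
    alveolar_wall_fraction: float = 0.30
    wall_hu_mean: float = -200.0
    wall_hu_sd: float = 25.0
    lesion_fraction: float = 0.0
    lesion_hu_mean: float = -50.0
    lesion_hu_sd: float = 40.0
    airway_diameter_um: float = 300.0
    airway_lumen_hu_mean: float = -980.0
    airway_lumen_hu_sd: float = 10.0
    airway_wall_hu_mean: float = 30.0
    airway_wall_hu_sd: float = 15.0
    airway_wall_thickness_um: float = 105.0
    background_hu: float = -1000.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lesion_fraction < 1.0:
            raise ValueError("lesion_fraction must lie in [0, 1)")
        if not 0.0 <= self.alveolar_wall_fraction <= 1.0:
            raise ValueError("alveolar_wall_fraction must lie in [0, 1]")
        for name in ("body_hu_mean", "lung_air_hu_mean", "wall_hu_mean",
                     "lesion_hu_mean", "airway_lumen_hu_mean", "airway_wall_hu_mean"):
            v = getattr(self, name)
            if not -1000.0 <= v <= 1000.0:
                raise ValueError(f"{name}={v} outside [-1000, 1000] HU")
        if self.airway_diameter_um <= 0:
            raise ValueError("airway_diameter_um must be positive")

    def with_noise_scale(self, scale: float) -> "CtPhantomSpec":
        """Copy of the spec with every HU standard deviation multiplied by *scale*."""
        return replace(
            self,
            body_hu_sd=self.body_hu_sd * scale,
            lung_air_hu_sd=self.lung_air_hu_sd * scale,
            wall_hu_sd=self.wall_hu_sd * scale,
            lesion_hu_sd=self.lesion_hu_sd * scale,
            airway_lumen_hu_sd=self.airway_lumen_hu_sd * scale,
            airway_wall_hu_sd=self.airway_wall_hu_sd * scale,
        )


@dataclass
class CtGroundTruth:
    """Realized class masks and bookkeeping volumes of a CT phantom."""

    lung: np.ndarray          # gas-exchanging lung (airway lumen/wall excluded)
    airway: np.ndarray        # conducting-airway lumen
    airway_wall: np.ndarray   # bronchial wall (soft tissue)
    lesion: np.ndarray
    wall: np.ndarray          # alveolar-interface voxels (incl. lesions? no: walls only)
    air: np.ndarray
    left_lung: np.ndarray
    right_lung: np.ndarray
    voxel_edge_um: float
    trachea_seed: tuple[int, int, int] = (0, 0, 0)

    @property
    def lung_voxels(self) -> int:
        return int(self.lung.sum())

    @property
    def tissue_voxels(self) -> int:
        return int(self.wall.sum() + self.lesion.sum())

    @property
    def aerated_voxels(self) -> int:
        return int(self.air.sum())

    @property
    def tissue_fraction(self) -> float:
        return self.tissue_voxels / self.lung_voxels

    @property
    def lung_mm3(self) -> float:
        return self.lung_voxels * (self.voxel_edge_um / 1000.0) ** 3


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _cylinder_between(shape, p0, p1, radius) -> np.ndarray:
    """Voxels whose center lies within *radius* of the segment p0-p1."""
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1).astype(float)
    p0 = np.asarray(p0, float)
    d = np.asarray(p1, float) - p0
    seg_len2 = float(d @ d)
    t = np.clip(((pts - p0) @ d) / seg_len2, 0.0, 1.0) if seg_len2 > 0 else 0.0
    closest = p0 + t[..., None] * d
    dist2 = np.sum((pts - closest) ** 2, axis=-1)
    return dist2 <= radius * radius


def generate_ct_phantom(spec: CtPhantomSpec) -> tuple[CtVolume, CtGroundTruth]:
    """Build the synthetic chest volume and its ground truth.

    Deterministic given ``spec.rng_seed``. The conducting airway is a
    vertical trachea bifurcating at a carina into one main bronchus per
    lung; its lumen is near -1000 HU and its wall is soft tissue, so a
    threshold-window region grow traverses the lumen into both lungs but
    cannot leak through the bronchial wall. Lesions are rejection-sampled
    ellipsoids kept strictly interior to the lung (so the segmentation
    hole-filling step can recover them) until at least
    ``lesion_fraction`` of the lung volume is covered.
    """
    rng = np.random.default_rng(spec.rng_seed)
    Z, Y, X = spec.grid_shape
    shape = spec.grid_shape
    vx = spec.voxel_edge_um

    body = _ellipsoid_mask(shape, (Z / 2, Y / 2, X / 2), (Z, 0.46 * Y, 0.46 * X))
    lung_centers = [(0.55 * Z, 0.54 * Y, 0.28 * X), (0.55 * Z, 0.54 * Y, 0.72 * X)]
    lung_axes = (0.32 * Z, 0.27 * Y, 0.155 * X)
    left_ell = _ellipsoid_mask(shape, lung_centers[0], lung_axes)
    right_ell = _ellipsoid_mask(shape, lung_centers[1], lung_axes)
    lungs_ell = left_ell | right_ell

    # conducting airway: trachea along z at the midline, then one bronchus
    # per lung ending inside the lung field
    r_lumen = spec.airway_diameter_um / vx / 2.0
    r_branch = 0.9 * r_lumen
    wall_t = spec.airway_wall_thickness_um / vx
    carina = (0.42 * Z, 0.50 * Y, 0.50 * X)
    top = (max(2.0, 0.05 * Z), 0.50 * Y, 0.50 * X)
    lumen = _cylinder_between(shape, top, carina, r_lumen)
    outer = _cylinder_between(shape, top, carina, r_lumen + wall_t)
    for c in lung_centers:
        tip = np.asarray((c[0], c[1] - 0.02 * Y, c[2]), float)
        # the lumen pokes past the bronchial-wall capsule so the airway opens
        # into the parenchyma instead of being sealed by its own wall
        direction = tip - np.asarray(carina, float)
        direction /= np.linalg.norm(direction)
        tip_open = tip + direction * (wall_t + r_branch + 2.0)
        lumen |= _cylinder_between(shape, carina, tip_open, r_branch)
        outer |= _cylinder_between(shape, carina, tip, r_branch + wall_t)
    airway_wall = outer & ~lumen

    lung = lungs_ell & ~lumen & ~airway_wall
    left = left_ell & lung
    right = right_ell & lung & ~left

    # lesions: ellipsoidal blobs fully inside the eroded lung
    lesion = np.zeros(shape, dtype=bool)
    target = int(round(spec.lesion_fraction * lung.sum()))
    if target > 0:
        # a 2-voxel parenchyma margin keeps every lesion cluster enclosed by a
        # face-connected shell of lung voxels, so the segmentation's
        # hole-filling step can always recover it (a 1-voxel staircase shell
        # is not reliably 6-connected)
        placeable = ndimage.binary_erosion(
            lung, structure=ndimage.generate_binary_structure(3, 1), iterations=2
        )
        placeable_idx = np.argwhere(placeable)
        deficit = target
        for _ in range(20000):
            if deficit <= 0:
                break
            a_max = float(np.clip(deficit ** (1 / 3), 1.5, 6.0))
            axes = rng.uniform(1.5, max(1.6, a_max), size=3)
            center = placeable_idx[rng.integers(len(placeable_idx))]
            blob = _ellipsoid_mask(shape, center, axes)
            if not (blob & ~placeable).any():
                new = blob & ~lesion
                lesion |= blob
                deficit -= int(new.sum())

    # alveolar interface voxels among the remaining lung air
    parenchyma = lung & ~lesion
    wall = parenchyma & (rng.random(shape) < spec.alveolar_wall_fraction)
    air = parenchyma & ~wall

    hu = np.full(shape, spec.background_hu, dtype=float)
    n = lambda m, s: rng.normal(m, s, size=shape) if s > 0 else np.full(shape, float(m))
    hu[body] = n(spec.body_hu_mean, spec.body_hu_sd)[body]
    hu[air] = n(spec.lung_air_hu_mean, spec.lung_air_hu_sd)[air]
    hu[wall] = n(spec.wall_hu_mean, spec.wall_hu_sd)[wall]
    hu[lesion] = n(spec.lesion_hu_mean, spec.lesion_hu_sd)[lesion]
    hu[airway_wall] = n(spec.airway_wall_hu_mean, spec.airway_wall_hu_sd)[airway_wall]
    hu[lumen] = n(spec.airway_lumen_hu_mean, spec.airway_lumen_hu_sd)[lumen]
    # keep the rendered volume on the histogram domain; noise must not push
    # air below -1000 HU (which would fall outside the region-grow window)
    np.clip(hu, -1000.0, 1000.0, out=hu)

    seed_z = int(round((top[0] + carina[0]) / 2))
    trachea_seed = (seed_z, int(round(0.50 * Y)), int(round(0.50 * X)))
    truth = CtGroundTruth(
        lung=lung, airway=lumen, airway_wall=airway_wall, lesion=lesion,
        wall=wall, air=air, left_lung=left, right_lung=right,
        voxel_edge_um=vx, trachea_seed=trachea_seed,
    )
    return CtVolume(hu, vx), truth


# ---------------------------------------------------------------------------
# H&E phantom
# ---------------------------------------------------------------------------

@dataclass
class HePhantomSpec:
    """Parameters of the synthetic H&E slide (RGB in [0, 255])."""

    image_shape: tuple[int, int] = (160, 160)
    pixel_area_um2: float = 1.0
    blue_fraction: float = 0.10
    pink_fraction: float = 0.40
    white_fraction: float = 0.50
    blue_rgb: tuple[float, float, float] = (70.0, 70.0, 160.0)
    pink_rgb: tuple[float, float, float] = (225.0, 150.0, 170.0)
    white_rgb: tuple[float, float, float] = (245.0, 245.0, 245.0)
    n_vessels: int = 0
    vessel_radius_px: float = 4.0
    noise_sd: float = 8.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.blue_fraction, self.pink_fraction, self.white_fraction)
        if any(f < 0 or f > 1 for f in fr):
            raise ValueError("target fractions must lie in [0, 1]")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"target fractions must sum to 1 (got {sum(fr):.4f})")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def class_rgb(self) -> dict[str, np.ndarray]:
        return {
            "Blue": np.asarray(self.blue_rgb, float),
            "Pink": np.asarray(self.pink_rgb, float),
            "White": np.asarray(self.white_rgb, float),
        }


@dataclass
class HeGroundTruth:
    """True label map (0 outside ROI, 1/2/3 = Blue/Pink/White) and bookkeeping."""

    labels: np.ndarray
    vessel: np.ndarray  # lumens painted White but flagged for reclassification
    fractions: dict[str, float]

    @property
    def tissue_fraction(self) -> float:
        return self.fractions["Blue"] + self.fractions["Pink"]


def _disk_indices(shape, center, radius, rng, elongation=1.0, inside=None):
    r0 = radius * elongation
    yy, xx = np.ogrid[0:shape[0], 0:shape[1]]
    m = ((yy - center[0]) / r0) ** 2 + ((xx - center[1]) / radius) ** 2 <= 1.0
    if inside is not None:
        m &= inside
    return m


def generate_he_phantom(spec: HePhantomSpec) -> tuple[RgbSlide, RoiMask, HeGroundTruth]:
    """Build the synthetic H&E slide, its elliptical lung ROI and ground truth.

    Inside the ROI the generator lays down elliptical pink tissue patches on
    a white background, carves optional white vessel lumens (flagged in the
    truth for reclassification tests), seeds blue nuclei inside the tissue,
    and finally flips individual pixels so the realized Blue/Pink/White
    counts hit the target fractions exactly before noise. Per-channel
    Gaussian noise of ``noise_sd`` is then added to the rendered colors.
    """
    rng = np.random.default_rng(spec.rng_seed)
    H, W = spec.image_shape
    yy, xx = np.ogrid[0:H, 0:W]
    roi = ((yy - H / 2) / (0.47 * H)) ** 2 + ((xx - W / 2) / (0.47 * W)) ** 2 <= 1.0
    n_roi = int(roi.sum())
    labels = np.zeros((H, W), dtype=np.uint8)
    labels[roi] = LABEL_CODES["White"]

    targets = {
        "Blue": int(round(spec.blue_fraction * n_roi)),
        "Pink": int(round(spec.pink_fraction * n_roi)),
    }
    tissue_target = targets["Blue"] + targets["Pink"]

    def count(cat: str) -> int:
        return int((labels == LABEL_CODES[cat]).sum())

    # 1. pink tissue patches
    for _ in range(5000):
        deficit = tissue_target - count("Pink")
        if deficit <= 0:
            break
        r = float(np.clip(math.sqrt(max(deficit, 1) / math.pi), 2.0, 0.15 * min(H, W)))
        c = (rng.uniform(0.1 * H, 0.9 * H), rng.uniform(0.1 * W, 0.9 * W))
        patch = _disk_indices((H, W), c, r, rng, rng.uniform(0.6, 1.6), inside=roi)
        labels[patch & (labels == LABEL_CODES["White"])] = LABEL_CODES["Pink"]

    # 2. vessel lumens: white holes inside tissue, flagged in the truth
    vessel = np.zeros((H, W), dtype=bool)
    pink_code = LABEL_CODES["Pink"]
    for _ in range(spec.n_vessels):
        pink_idx = np.argwhere(labels == pink_code)
        if len(pink_idx) == 0:
            break
        c = pink_idx[rng.integers(len(pink_idx))]
        lum = _disk_indices((H, W), c, spec.vessel_radius_px, rng, inside=roi)
        lum &= labels == pink_code
        labels[lum] = LABEL_CODES["White"]
        vessel |= lum

    # 3. blue nuclei inside pink tissue
    for _ in range(20000):
        deficit = targets["Blue"] - count("Blue")
        if deficit <= 0:
            break
        pink_idx = np.argwhere(labels == pink_code)
        if len(pink_idx) == 0:
            break
        c = pink_idx[rng.integers(len(pink_idx))]
        r = float(np.clip(math.sqrt(max(deficit, 1) / math.pi), 1.0, 3.0))
        nuc = _disk_indices((H, W), c, r, rng, inside=roi)
        labels[nuc & (labels == pink_code)] = LABEL_CODES["Blue"]

    # 4. exact top-up by individual pixel flips (order: fix Blue, then Pink)
    def flip(from_cat: str, to_cat: str, k: int) -> None:
        # vessel lumens are protected: their White labels carry meaning
        idx = np.argwhere(roi & (labels == LABEL_CODES[from_cat]) & ~vessel)
        if k > len(idx):
            raise ValueError(
                f"unreachable target fractions: need {k} more {to_cat!r} pixels "
                f"but only {len(idx)} {from_cat!r} pixels remain"
            )
        pick = idx[rng.choice(len(idx), size=k, replace=False)]
        labels[tuple(pick.T)] = LABEL_CODES[to_cat]

    d_blue = targets["Blue"] - count("Blue")
    if d_blue > 0:
        flip("Pink", "Blue", d_blue)
    elif d_blue < 0:
        flip("Blue", "Pink", -d_blue)
    d_pink = targets["Pink"] - count("Pink")
    if d_pink > 0:
        flip("White", "Pink", d_pink)
    elif d_pink < 0:
        flip("Pink", "White", -d_pink)

    # render
    rgb = np.zeros((H, W, 3), dtype=float)
    for cat, code in LABEL_CODES.items():
        rgb[labels == code] = spec.class_rgb[cat]
    rgb[~roi] = spec.class_rgb["White"]
    if spec.noise_sd > 0:
        rgb += rng.normal(0.0, spec.noise_sd, size=rgb.shape)
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    fractions = {
        cat: count(cat) / n_roi for cat in ("Blue", "Pink", "White")
    }
    slide = RgbSlide(rgb, spec.pixel_area_um2)
    return slide, RoiMask(roi), HeGroundTruth(labels, vessel, fractions)


def training_set_from_truth(
    slide: RgbSlide,
    truth: HeGroundTruth,
    n_per_category: int = 50,
    rng_seed: int = 0,
) -> TrainingSet:
    """Sample training pixels per category from a phantom's true label map.

    Stands in for the manual pixel-picking step of the real workflow.
    """
    rng = np.random.default_rng(rng_seed)
    pixels = {}
    for cat, code in LABEL_CODES.items():
        idx = np.argwhere(truth.labels == code)
        if len(idx) == 0:
            raise ValueError(f"phantom has no {cat!r} pixels to sample")
        pick = idx[rng.choice(len(idx), size=min(n_per_category, len(idx)), replace=False)]
        pixels[cat] = slide.pixels[tuple(pick.T)].astype(float)
    return TrainingSet(pixels)


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

def generate_cohort(
    n_per_cell: int = 5,
    rho_true: float = 0.82,
    genotype_effect_sd: float = 2.0,
    age_effect_sd: float = 0.0,
    ages: Sequence[float] = DEFAULT_AGES,
    rng_seed: int = 0,
    n_total: int | None = None,
) -> tuple[pd.DataFrame, PairedOutcomes]:
    """Draw per-animal CT tissue volume and histology tissue area pairs.

    Each animal carries a latent pair ``(z_ct, z_histo)`` from a bivariate
    standard normal with Pearson correlation ``r = 2 sin(pi * rho_true / 6)``
    so that the population Spearman correlation of the pair equals
    ``rho_true`` exactly. Genotype (TNF-Tg tissue excess, in latent SD units)
    and per-month age shifts are added to both modalities, emulating the
    shared inflammation burden of the study design; the values are then
    mapped to physical scales (mm^3 and um^2), which leaves rank statistics
    untouched. ``n_total`` (e.g. 43 animals) overrides the cell-based count
    by assigning animals to cells round-robin.

    Returns a tidy cohort table with outcomes ``ct_tissue_mm3`` and
    ``histo_tissue_um2`` (left lung), plus the corresponding
    :class:`PairedOutcomes`.
    """
    if not -1.0 <= rho_true <= 1.0:
        raise ValueError("rho_true must lie in [-1, 1]")
    if n_per_cell < 2 and n_total is None:
        raise ValueError("n_per_cell must be >= 2")
    rng = np.random.default_rng(rng_seed)
    r = 2.0 * math.sin(math.pi * rho_true / 6.0)
    cells = [(g, a) for g in GENOTYPES for a in ages]
    if n_total is None:
        assignment = [cell for cell in cells for _ in range(n_per_cell)]
    else:
        assignment = [cells[i % len(cells)] for i in range(n_total)]
    n = len(assignment)
    z1 = rng.standard_normal(n)
    if abs(r) >= 1.0:  # degenerate: perfectly (anti)correlated latents
        z2 = math.copysign(1.0, r) * z1
    else:
        z2 = r * z1 + math.sqrt(1.0 - r * r) * rng.standard_normal(n)
    z = np.stack([z1, z2], axis=1)
    rows = []
    ct_vals = np.empty(n)
    histo_vals = np.empty(n)
    ids = np.array([f"M{i:03d}" for i in range(n)])
    for i, (genotype, age) in enumerate(assignment):
        shift = genotype_effect_sd * (genotype == "TNF-Tg") + age_effect_sd * (age - ages[0])
        ct = 180.0 + 40.0 * (shift + z[i, 0])
        histo = (35.0 + 8.0 * (shift + z[i, 1])) * 1e6
        ct_vals[i], histo_vals[i] = ct, histo
        rows.append((ids[i], genotype, age, "ct_tissue_mm3", ct))
        rows.append((ids[i], genotype, age, "histo_tissue_um2", histo))
    table = pd.DataFrame(
        rows, columns=["animal_id", "genotype", "age_months", "outcome", "value"]
    )
    return table, PairedOutcomes(ids, ct_vals, histo_vals)
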