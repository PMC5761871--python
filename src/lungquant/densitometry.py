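"""Histogram densitometry of segmented lungs and CT dose-index helpers.

A segmented lung is summarized by its intensity histogram over the domain
[-1000, 1000] HU at 1-HU bin width (2001 bins). The histogram's weighted mean

    x_bar = sum_i(w_i * x_i) / sum_i(w_i)

(w_i = bin count, x_i = bin HU) pooled over a healthy wild-type cohort
defines the aerated/tissue partition threshold: voxels below it are aerated
(air-dominated), voxels at or above it are tissue (cells, matrix, blood,
edema). The threshold bin itself represents the air/alveolar-epithelium
interface density and is assigned to tissue.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptyHistogramError
from .volume import CtVolume, SegmentationMask

__all__ = [
    "HU_MIN",
    "HU_MAX",
    "N_BINS",
    "IntensityHistogram",
    "VolumeOutcomes",
    "DoseProfile",
    "build_histogram",
    "weighted_mean",
    "pooled_histogram",
    "derive_threshold",
    "partition_volumes",
    "ctdi",
    "ctdi_w",
]

HU_MIN = -1000
HU_MAX = 1000
N_BINS = HU_MAX - HU_MIN + 1  # 2001 one-HU-wide bins, centred on integers


@dataclass
class IntensityHistogram:
    """Voxel counts per 1-HU bin over [-1000, 1000] HU."""

    counts: np.ndarray
    source_label: str = "whole_lung"
    bin_hu: np.ndarray = field(
        default_factory=lambda: np.arange(HU_MIN, HU_MAX + 1), repr=False
    )

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} bins, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be non-negative")
        self.counts = self.counts.astype(np.int64)
        self.bin_hu = np.arange(HU_MIN, HU_MAX + 1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "IntensityHistogram") -> "IntensityHistogram":
        return IntensityHistogram(self.counts + other.counts, self.source_label)


@dataclass
class VolumeOutcomes:
    """Densitometric outcomes for one lung segment at one threshold."""

    weighted_mean_hu: float
    threshold_hu: int
    total_voxels: int
    aerated_voxels: int
    tissue_voxels: int
    total_mm3: float
    aerated_mm3: float
    tissue_mm3: float
    aerated_fraction: float
    tissue_fraction: float
    source_label: str = "whole_lung"


@dataclass
class DoseProfile:
    """A sampled axial radiation dose profile D(z) for CTDI integration."""

    z_mm: np.ndarray
    dose: np.ndarray
    n_slices: int
    section_thickness_mm: float

    def __post_init__(self) -> None:
        self.z_mm = np.asarray(self.z_mm, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        if self.z_mm.shape != self.dose.shape or self.z_mm.ndim != 1:
            raise ValueError("z_mm and dose must be congruent 1D arrays")
        if np.any(np.diff(self.z_mm) <= 0):
            raise ValueError("z positions must be strictly increasing")
        if not np.all(np.isfinite(self.dose)) or np.any(self.dose < 0):
            raise ValueError("doses must be finite and non-negative")
        if self.n_slices <= 0 or self.section_thickness_mm <= 0:
            raise ValueError("n_slices and section_thickness_mm must be positive")


def build_histogram(
    volume: CtVolume, mask: SegmentationMask, source_label: str | None = None
) -> IntensityHistogram:
    """Histogram the masked voxels into 1-HU bins on [-1000, 1000].

    HU values outside the domain are clamped to its edges; real-valued HU is
    assigned to the nearest integer bin (ties toward even, IEEE rounding).
    An empty mask yields an all-zero histogram with a warning.
    """
    if volume.shape != mask.shape:
        raise ValueError("volume and mask must be congruent")
    values = volume.intensities[mask.voxels]
    label = source_label or mask.label
    if values.size == 0:
        warnings.warn(f"empty mask {label!r}: all-zero histogram", stacklevel=2)
        return IntensityHistogram(np.zeros(N_BINS, dtype=np.int64), label)
    binned = np.clip(np.rint(values).astype(np.int64), HU_MIN, HU_MAX)
    counts = np.bincount(binned - HU_MIN, minlength=N_BINS)
    return IntensityHistogram(counts, label)


def weighted_mean(hist: IntensityHistogram) -> float:
    """Count-weighted mean HU of a histogram: sum(w_i x_i) / sum(w_i)."""
    total = hist.total
    if total == 0:
        raise EmptyHistogramError("weighted mean undefined for all-zero counts")
    return float(np.dot(hist.counts, hist.bin_hu) / total)


def pooled_histogram(histograms: Iterable[IntensityHistogram]) -> IntensityHistogram:
    """Bin-wise sum of several histograms (voxel-weighted pooling)."""
    histograms = list(histograms)
    if not histograms:
        raise ValueError("need at least one histogram to pool")
    counts = np.sum([h.counts for h in histograms], axis=0)
    return IntensityHistogram(counts, "whole_lung")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def derive_threshold(
    wt_histograms: Sequence[IntensityHistogram],
    method: str = "weighted_mean",
    pooling: str = "voxel",
) -> int:
    """Derive the aerated/tissue threshold from a wild-type cohort.

    Default (``method="weighted_mean"``, ``pooling="voxel"``): sum all WT
    histograms bin-wise and round the pooled weighted mean HU to the nearest
    integer (ties away from zero). ``pooling="mouse"`` averages per-mouse
    weighted means instead (each animal weighted equally).
    ``method="mode"`` returns the most abundant pooled bin — the density of
    the air/epithelium interface, which in a healthy lung coincides with the
    pooled mean to within a few HU.
    """
    if not wt_histograms:
        raise ValueError("need at least one wild-type histogram")
    if method not in ("weighted_mean", "mode"):
        raise ValueError(f"unknown method {method!r}")
    pooled = pooled_histogram(wt_histograms)
    if pooled.total == 0:
        raise EmptyHistogramError("cannot derive a threshold from empty histograms")
    if method == "mode":
        return int(pooled.bin_hu[int(np.argmax(pooled.counts))])
    if pooling == "voxel":
        return _round_half_away(weighted_mean(pooled))
    if pooling == "mouse":
        means = [weighted_mean(h) for h in wt_histograms]
        return _round_half_away(float(np.mean(means)))
    raise ValueError(f"unknown pooling {pooling!r}")


def partition_volumes(
    hist: IntensityHistogram,
    threshold_hu: int,
    voxel_edge_um: float,
) -> VolumeOutcomes:
    """Partition a histogram into aerated (< threshold) and tissue (>= threshold).

    Fills every outcome field: voxel counts, physical volumes
    (``voxels * (edge_um/1000)^3`` mm^3) and fractions normalized by the total.
    """
    if not (HU_MIN <= threshold_hu <= HU_MAX):
        raise ValueError(f"threshold {threshold_hu} outside [{HU_MIN}, {HU_MAX}]")
    if voxel_edge_um <= 0:
        raise ValueError("voxel_edge_um must be positive")
    below = hist.bin_hu < threshold_hu
    aerated = int(hist.counts[below].sum())
    tissue = int(hist.counts[~below].sum())
    total = aerated + tissue
    vx_mm3 = (voxel_edge_um / 1000.0) ** 3
    mean = weighted_mean(hist) if total else float("nan")
    return VolumeOutcomes(
        weighted_mean_hu=mean,
        threshold_hu=int(threshold_hu),
        total_voxels=total,
        aerated_voxels=aerated,
        tissue_voxels=tissue,
        total_mm3=total * vx_mm3,
        aerated_mm3=aerated * vx_mm3,
        tissue_mm3=tissue * vx_mm3,
        aerated_fraction=aerated / total if total else 0.0,
        tissue_fraction=tissue / total if total else 0.0,
        source_label=hist.source_label,
    )


def ctdi(profile: DoseProfile, z_lo_mm: float = -50.0, z_hi_mm: float = 50.0) -> float:
    """CT dose index: integral of D(z) / (N * T) over [-50, +50] mm.

    Trapezoid rule on the supplied samples, with the endpoints interpolated
    if they fall between samples. The profile must cover the full interval.
    """
    z, d = profile.z_mm, profile.dose
    if z[0] > z_lo_mm or z[-1] < z_hi_mm:
        raise ValueError(
            f"dose profile [{z[0]}, {z[-1]}] mm does not cover [{z_lo_mm}, {z_hi_mm}] mm"
        )
    inside = (z > z_lo_mm) & (z < z_hi_mm)
    zz = np.concatenate([[z_lo_mm], z[inside], [z_hi_mm]])
    dd = np.concatenate([[np.interp(z_lo_mm, z, d)], d[inside], [np.interp(z_hi_mm, z, d)]])
    integral = np.trapezoid(dd, zz)
    return float(integral / (profile.n_slices * profile.section_thickness_mm))


def ctdi_w(ctdi_center: float, ctdi_peripheral: float) -> float:
    """Weighted CT dose index: 1/3 * center + 2/3 * peripheral."""
    if ctdi_center < 0 or ctdi_peripheral < 0:
        raise ValueError("CTDI components must be non-negative")
    return ctdi_center / 3.0 + 2.0 * ctdi_peripheral / 3.0
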