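"""Core voxel-grid containers for chest micro-CT data.

Conventions used throughout the package:

* axes are ``(z, y, x)`` with ``z`` the cranio-caudal slice index,
  ``y`` the row and ``x`` the column;
* voxel indices are 0-based; a voxel's world position is its index times
  the (isotropic) voxel edge length;
* intensities are Hounsfield units (air = -1000, water = 0). Raw values are
  kept as stored; clamping to the histogram domain [-1000, 1000] HU happens
  only when histograms are built.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CtVolume", "SegmentationMask", "AirwaySegment", "MASK_LABELS"]

#: Labels a SegmentationMask may carry.
MASK_LABELS = (
    "whole_lung",
    "airway",
    "left_lung",
    "right_lung",
    "aerated",
    "tissue",
)


@dataclass
class CtVolume:
    """A 3D scalar grid of HU intensities with isotropic voxels.

    Parameters
    ----------
    intensities
        3D array of Hounsfield units, axes ``(z, y, x)``.
    voxel_edge_um
        Edge length of the isotropic voxel in micrometres (the study design
        this package targets uses 35 um in-vivo voxels).
    """

    intensities: np.ndarray
    voxel_edge_um: float

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"intensities must be 3D (z, y, x); got {self.intensities.ndim}D"
            )
        if any(s < 1 for s in self.intensities.shape):
            raise ValueError("all three dimensions must be >= 1")
        if not (float(self.voxel_edge_um) > 0):
            raise ValueError("voxel_edge_um must be positive")
        self.voxel_edge_um = float(self.voxel_edge_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in cubic millimetres."""
        return (self.voxel_edge_um / 1000.0) ** 3

    def in_bounds(self, index: tuple[int, int, int]) -> bool:
        return all(0 <= i < s for i, s in zip(index, self.shape))


@dataclass
class SegmentationMask:
    """A boolean voxel mask congruent with its source :class:`CtVolume`."""

    voxels: np.ndarray
    label: str = "whole_lung"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.label not in MASK_LABELS:
            raise ValueError(f"unknown mask label {self.label!r}; one of {MASK_LABELS}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    def __bool__(self) -> bool:  # truthiness = non-empty
        return bool(self.voxels.any())


@dataclass
class AirwaySegment:
    """Conducting-airway lumen voxels with per-voxel inscribed-sphere diameters.

    ``local_diameter_um`` holds, for every airway voxel, the diameter of the
    largest sphere centred there that fits inside the lumen, in micrometres;
    voxels outside the airway hold 0.
    """

    voxels: np.ndarray
    local_diameter_um: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        self.local_diameter_um = np.asarray(self.local_diameter_um, dtype=float)
        if self.voxels.shape != self.local_diameter_um.shape:
            raise ValueError("voxels and local_diameter_um must be congruent")

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())
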