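"""Lung extraction from chest micro-CT volumes.

The segmentation strategy mirrors the semi-automated workflow used for
murine inflammatory lung disease: a threshold-constrained seeded region grow
("magic wand") from a bronchus seed over the HU window [-1000, -150],
morphological refinement (grow / shrink / fill holes / smooth), removal of
conducting airways wider than a diameter cutoff (200 um by default), and a
left/right split driven by the airway carina.

All region growing and hole filling uses 6-connectivity (face neighbours);
this conservative growth is what a magic-wand style tool does and is the
connectivity the test oracles fix.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from .errors import DataError, SeedOutOfBoundsError, SplitFailedError
from .volume import AirwaySegment, CtVolume, SegmentationMask

__all__ = [
    "seeded_region_grow",
    "refine_mask",
    "extract_airways",
    "exclude_large_airways",
    "split_left_right",
    "branch_diameter_map",
]

#: Face-connectivity structuring element shared by all morphology here.
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def _check_seed(volume: CtVolume, seed: tuple[int, int, int]) -> tuple[int, int, int]:
    seed = tuple(int(i) for i in seed)  # type: ignore[assignment]
    if len(seed) != 3 or not volume.in_bounds(seed):
        raise SeedOutOfBoundsError(
            f"seed {seed} outside volume of shape {volume.shape}"
        )
    if not np.isfinite(volume.intensities[seed]):
        raise DataError(f"non-finite HU value at seed {seed}")
    return seed


def seeded_region_grow(
    volume: CtVolume,
    seed: tuple[int, int, int],
    low_hu: float,
    high_hu: float,
    label: str = "whole_lung",
) -> SegmentationMask:
    """Grow the face-connected component of in-window voxels containing *seed*.

    Returns the set of voxels ``v`` with ``low_hu <= HU(v) <= high_hu`` that
    are 6-connected to the seed; an empty mask if the seed itself is out of
    the HU window.

    Raises
    ------
    SeedOutOfBoundsError
        If the seed lies outside the grid.
    DataError
        If the HU value at the seed is not finite, or ``low_hu > high_hu``.
    """
    seed = _check_seed(volume, seed)
    if low_hu > high_hu:
        raise DataError(f"low_hu ({low_hu}) must be <= high_hu ({high_hu})")
    hu = volume.intensities
    in_range = (hu >= low_hu) & (hu <= high_hu) & np.isfinite(hu)
    if not in_range[seed]:
        return SegmentationMask(np.zeros(volume.shape, dtype=bool), label)
    labels, _ = ndimage.label(in_range, structure=_STRUCT6)
    return SegmentationMask(labels == labels[seed], label)


def refine_mask(
    mask: SegmentationMask,
    grow_r: int = 1,
    shrink_r: int = 1,
    fill_holes: bool = True,
    smooth_r: int = 1,
) -> SegmentationMask:
    """Morphological clean-up: dilate, erode, fill cavities, then smooth.

    The steps run in the fixed order grow -> shrink -> fill -> smooth.
    Dilation/erosion use the face-connected (6-neighbour) unit ball iterated
    ``grow_r`` / ``shrink_r`` times; smoothing is a closing followed by an
    opening, each iterated ``smooth_r`` times; hole filling removes cavities
    of the mask complement that do not reach the grid boundary.

    An empty result is permitted (e.g. a small mask eroded away) and simply
    returned.
    """
    if grow_r < 0 or shrink_r < 0 or smooth_r < 0:
        raise ValueError("structuring radii must be non-negative")
    out = mask.voxels.copy()
    if grow_r:
        out = ndimage.binary_dilation(out, structure=_STRUCT6, iterations=grow_r)
    if shrink_r:
        out = ndimage.binary_erosion(out, structure=_STRUCT6, iterations=shrink_r)
    if fill_holes:
        out = ndimage.binary_fill_holes(out, structure=_STRUCT6)
    if smooth_r:
        out = ndimage.binary_closing(out, structure=_STRUCT6, iterations=smooth_r)
        out = ndimage.binary_opening(out, structure=_STRUCT6, iterations=smooth_r)
    return SegmentationMask(out, mask.label)


def extract_airways(
    volume: CtVolume,
    lung: SegmentationMask,
    trachea_seed: tuple[int, int, int],
    air_hu_max: float = -850.0,
) -> AirwaySegment:
    """Segment the conducting-airway lumen and measure its local diameter.

    Grows from the trachea seed through voxels that are inside the lung mask
    and at most ``air_hu_max`` HU (near-pure air — the lumen is markedly
    darker than the partial-volume alveolar parenchyma). Each airway voxel
    gets the diameter of the largest inscribed sphere centred on it:
    ``(2 * EDT - 1) * voxel_edge_um`` where EDT is the Euclidean
    distance-to-background transform in voxel units. The ``- 1`` converts the
    centre-to-centre distance into a lumen diameter so a one-voxel tube
    measures exactly one voxel edge.
    """
    seed = _check_seed(volume, trachea_seed)
    if not lung.voxels[seed]:
        raise DataError(f"trachea seed {seed} is outside the lung mask")
    if volume.intensities[seed] > air_hu_max:
        raise DataError(
            f"trachea seed HU {volume.intensities[seed]} exceeds air_hu_max {air_hu_max}"
        )
    candidate = lung.voxels & (volume.intensities <= air_hu_max)
    labels, _ = ndimage.label(candidate, structure=_STRUCT6)
    lumen = labels == labels[seed]
    edt = ndimage.distance_transform_edt(lumen)
    diam = np.where(lumen, (2.0 * edt - 1.0) * volume.voxel_edge_um, 0.0)
    return AirwaySegment(lumen, diam)


def branch_diameter_map(airways: AirwaySegment) -> np.ndarray:
    """Assign every airway voxel the maximum diameter of its branch.

    The lumen is skeletonized; skeleton voxels with more than two skeleton
    neighbours (26-connectivity) are junctions, and removing them splits the
    skeleton into branch segments. Each segment carries the maximum local
    diameter along its medial axis, and every lumen voxel inherits the value
    of its nearest skeleton voxel (junction voxels keep their own local
    diameter). A lumen too small to skeletonize is treated as a single branch
    at its maximum local diameter.
    """
    lumen = airways.voxels
    out = np.zeros_like(airways.local_diameter_um)
    if not lumen.any():
        return out
    skel = skeletonize(lumen)
    # keep only medial voxels at least two voxel edges wide: skeleton
    # fragments inside single-voxel noise pockets attached to the lumen
    # otherwise capture nearby true-lumen voxels and dilute their branch
    voxel_edge = airways.local_diameter_um[lumen].min() if lumen.any() else 1.0
    core = skel & (airways.local_diameter_um >= 2.0 * voxel_edge)
    if core.any():
        skel = core
    skel_idx = np.argwhere(skel)
    if len(skel_idx) == 0:
        out[lumen] = airways.local_diameter_um[lumen].max()
        return out
    # neighbour count on the skeleton (26-conn), minus self
    nb = ndimage.convolve(skel.astype(np.int8), np.ones((3, 3, 3), np.int8), mode="constant")
    junctions = skel & (nb - 1 > 2)
    segments, nseg = ndimage.label(skel & ~junctions, structure=np.ones((3, 3, 3), bool))
    skel_branch_diam = np.where(skel, airways.local_diameter_um, 0.0)
    if nseg:
        seg_max = ndimage.maximum(
            airways.local_diameter_um, labels=segments, index=np.arange(1, nseg + 1)
        )
        seg_max = np.concatenate([[0.0], np.atleast_1d(seg_max)])
        on_segment = segments > 0
        skel_branch_diam[on_segment] = seg_max[segments[on_segment]]
    tree = cKDTree(skel_idx)
    lumen_idx = np.argwhere(lumen)
    _, nearest = tree.query(lumen_idx, k=1)
    nearest_skel = skel_idx[nearest]
    out[tuple(lumen_idx.T)] = skel_branch_diam[tuple(nearest_skel.T)]
    return out


def _wide_lumen_cover(airways: AirwaySegment, diameter_cutoff_um: float) -> np.ndarray:
    """Lumen voxels covered by a maximal inscribed ball wider than the cutoff.

    Every voxel of a tube wider than the cutoff lies inside the maximal ball
    of some medial voxel, so this cover removes wide branches in full —
    including their terminal taper at the mouth — without depending on
    skeleton topology.
    """
    lumen = airways.voxels
    wide = lumen & (airways.local_diameter_um > diameter_cutoff_um)
    cover = np.zeros_like(lumen)
    if not wide.any():
        return cover
    voxel_edge = airways.local_diameter_um[lumen].min()
    radius_vox = (airways.local_diameter_um / voxel_edge + 1.0) / 2.0  # EDT units
    radii = np.ceil(radius_vox[wide]).astype(int)
    for r in np.unique(radii):
        group = wide & (np.ceil(radius_vox) == r)
        zz, yy, xx = np.ogrid[-r:r + 1, -r:r + 1, -r:r + 1]
        ball = zz ** 2 + yy ** 2 + xx ** 2 <= r * r
        cover |= ndimage.binary_dilation(group, structure=ball)
    return cover & lumen


def exclude_large_airways(
    lung: SegmentationMask,
    airways: AirwaySegment,
    diameter_cutoff_um: float = 200.0,
) -> SegmentationMask:
    """Remove conducting-airway branches wider than the cutoff from the lung.

    A branch is removed as a whole when the maximum inscribed-sphere diameter
    along its medial axis exceeds ``diameter_cutoff_um``; additionally every
    lumen voxel covered by an inscribed ball wider than the cutoff is removed,
    which keeps the decision stable where noise-attached air pockets distort
    the skeleton. Narrower airway voxels stay in the lung mask (they are part
    of the gas-exchanging periphery at the working resolution). Never adds
    voxels.
    """
    if lung.shape != airways.voxels.shape:
        raise ValueError("lung mask and airway segment must be congruent")
    branch_diam = branch_diameter_map(airways)
    remove = airways.voxels & (branch_diam > diameter_cutoff_um)
    if diameter_cutoff_um <= 0:
        remove |= airways.voxels
    else:
        remove |= _wide_lumen_cover(airways, diameter_cutoff_um)
    return SegmentationMask(lung.voxels & ~remove, lung.label)


def _carina_plane_x(airways: AirwaySegment) -> float:
    """Sagittal (x) position of the carina, estimated from the airway tree.

    The carina is the deepest (largest-z) skeleton junction lying near the
    tree's sagittal centre; spurious junctions from small air pockets
    attached to the lumen are ignored, and with no usable junction the
    median x of the airway voxels (the trachea dominates the count) is used.
    """
    lumen = airways.voxels
    if not lumen.any():
        raise SplitFailedError("empty airway segment; cannot locate the carina")
    xs = np.argwhere(lumen)[:, 2]
    median_x = float(np.median(xs))
    half_span = max(1.0, 0.25 * float(np.ptp(xs)))
    skel = skeletonize(lumen)
    if skel.any():
        nb = ndimage.convolve(
            skel.astype(np.int8), np.ones((3, 3, 3), np.int8), mode="constant"
        )
        junctions = np.argwhere(skel & (nb - 1 > 2))
        central = junctions[np.abs(junctions[:, 2] - median_x) <= half_span]
        if len(central):
            deepest = central[np.argmax(central[:, 0])]
            return float(deepest[2])
    return median_x


def split_left_right(
    lung: SegmentationMask,
    airways: AirwaySegment,
    split_plane: tuple[tuple[float, float, float], tuple[float, float, float]] | None = None,
    voxel_edge_um: float = 1.0,
) -> tuple[SegmentationMask, SegmentationMask]:
    """Split a lung mask into left and right sides.

    Primary strategy: 6-connected component labelling of the (airway-excluded)
    lung, assigning each component to a side by the sign of its centroid's x
    offset from the carina's sagittal plane (lower x = left, in the package's
    (z, y, x) convention). If the lungs remain a single connected component a
    user-supplied ``split_plane`` — ``(point_um, normal)`` in world
    micrometres — partitions voxels by plane side instead.

    Raises
    ------
    SplitFailedError
        Single unseparable component and no user plane.
    """
    labels, ncomp = ndimage.label(lung.voxels, structure=_STRUCT6)
    left = np.zeros(lung.shape, dtype=bool)
    right = np.zeros(lung.shape, dtype=bool)

    def _plane_side(idx: np.ndarray) -> np.ndarray:
        point, normal = split_plane  # type: ignore[misc]
        world = idx * float(voxel_edge_um)
        return (world - np.asarray(point, float)) @ np.asarray(normal, float)

    if ncomp <= 1:
        if split_plane is None:
            raise SplitFailedError(
                "lung is a single connected component; supply split_plane to partition it"
            )
        idx = np.argwhere(lung.voxels)
        side = _plane_side(idx)
        left[tuple(idx[side < 0].T)] = True
        right[tuple(idx[side >= 0].T)] = True
    elif split_plane is not None:
        for comp in range(1, ncomp + 1):
            comp_mask = labels == comp
            centroid = np.array(ndimage.center_of_mass(comp_mask))
            if float(_plane_side(centroid[None, :])[0]) < 0:
                left |= comp_mask
            else:
                right |= comp_mask
    else:
        carina_x = _carina_plane_x(airways)
        for comp in range(1, ncomp + 1):
            comp_mask = labels == comp
            cx = ndimage.center_of_mass(comp_mask)[2]
            if cx < carina_x:
                left |= comp_mask
            else:
                right |= comp_mask
    return (
        SegmentationMask(left, "left_lung"),
        SegmentationMask(right, "right_lung"),
    )
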