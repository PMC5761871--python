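"""Readers and writers for the pipeline's file formats.

CT volumes come in as DICOM series directories (HU via rescale
slope/intercept) or NIfTI files; masks go out as uint8-label NIfTI.
Histograms round-trip as two-column CSV (hu, count), outcomes as tidy CSV,
label maps as single-channel PNG with the fixed code table
0 = unlabeled, 1 = Blue, 2 = Pink, 3 = White. ROIs are accepted either as a
mask image or as a GeoJSON-style polygon (image coordinates, 0-based,
y-down).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import pydicom

from .densitometry import HU_MIN, HU_MAX, N_BINS, IntensityHistogram, VolumeOutcomes
from .errors import DataError
from .histomorphometry import HistoAreaOutcomes, RgbSlide, RoiMask, TrainingSet
from .volume import CtVolume, SegmentationMask

__all__ = [
    "read_ct",
    "read_nifti",
    "read_dicom_series",
    "write_mask_nifti",
    "write_volume_nifti",
    "read_histogram_csv",
    "write_histogram_csv",
    "outcomes_to_row",
    "write_outcomes_csv",
    "read_slide",
    "read_roi",
    "read_training_csv",
    "write_label_png",
    "histo_outcomes_to_row",
]

_ISO_RTOL = 1e-3


def read_ct(path: str | Path, allow_anisotropic: bool = False) -> CtVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory."""
    path = Path(path)
    if path.is_dir():
        return read_dicom_series(path, allow_anisotropic)
    return read_nifti(path, allow_anisotropic)


def _check_isotropic(spacings_um: Sequence[float], allow: bool) -> float:
    spacings = np.asarray(spacings_um, dtype=float)
    if np.ptp(spacings) > _ISO_RTOL * spacings.mean():
        if not allow:
            raise DataError(
                f"anisotropic voxels {tuple(spacings)} um; pass allow_anisotropic "
                "to take the mean edge length"
            )
    return float(spacings.mean())


def read_nifti(path: str | Path, allow_anisotropic: bool = False) -> CtVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise DataError(f"expected a 3D NIfTI volume, got {data.ndim}D")
    zooms_mm = img.header.get_zooms()[:3]
    edge_um = _check_isotropic([z * 1000.0 for z in zooms_mm], allow_anisotropic)
    # stored (x, y, z) -> package convention (z, y, x)
    return CtVolume(np.transpose(data, (2, 1, 0)), edge_um)


def read_dicom_series(path: str | Path, allow_anisotropic: bool = False) -> CtVolume:
    """Read a single-series DICOM directory into HU.

    Applies ``HU = RescaleSlope * stored + RescaleIntercept`` per slice and
    validates orientation consistency, uniform slice spacing and voxel
    isotropy.
    """
    files = sorted(Path(path).glob("*.dcm")) or sorted(
        p for p in Path(path).iterdir() if p.is_file()
    )
    if not files:
        raise DataError(f"no DICOM files found in {path}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    ref_orient = getattr(slices[0], "ImageOrientationPatient", None)
    for ds in slices:
        if getattr(ds, "ImageOrientationPatient", None) != ref_orient:
            raise DataError("mixed slice orientations in series")
        if not hasattr(ds, "RescaleSlope") or not hasattr(ds, "RescaleIntercept"):
            raise DataError("missing RescaleSlope/RescaleIntercept tags")
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    dz = np.diff(zs)
    if len(dz) and np.ptp(dz) > _ISO_RTOL * abs(dz.mean()):
        raise DataError("inconsistent slice spacing in series")
    hu = np.stack(
        [
            float(ds.RescaleSlope) * ds.pixel_array.astype(float)
            + float(ds.RescaleIntercept)
            for ds in slices
        ]
    )
    px = [float(v) for v in slices[0].PixelSpacing]
    spacing_um = [abs(dz.mean()) * 1000.0 if len(dz) else px[0] * 1000.0,
                  px[0] * 1000.0, px[1] * 1000.0]
    edge_um = _check_isotropic(spacing_um, allow_anisotropic)
    return CtVolume(hu, edge_um)


def _affine(voxel_edge_um: float) -> np.ndarray:
    return np.diag([voxel_edge_um / 1000.0] * 3 + [1.0])


def write_volume_nifti(volume: CtVolume, path: str | Path) -> None:
    data = np.transpose(volume.intensities, (2, 1, 0)).astype(np.float64)
    nib.save(nib.Nifti1Image(data, _affine(volume.voxel_edge_um)), str(path))


def write_mask_nifti(
    mask: SegmentationMask, voxel_edge_um: float, path: str | Path
) -> None:
    data = np.transpose(mask.voxels.astype(np.uint8), (2, 1, 0))
    nib.save(nib.Nifti1Image(data, _affine(voxel_edge_um)), str(path))


# -- histograms and outcomes -------------------------------------------------

def write_histogram_csv(hist: IntensityHistogram, path: str | Path) -> None:
    pd.DataFrame({"hu": hist.bin_hu, "count": hist.counts}).to_csv(path, index=False)


def read_histogram_csv(path: str | Path, source_label: str = "whole_lung") -> IntensityHistogram:
    df = pd.read_csv(path)
    if not {"hu", "count"} <= set(df.columns):
        raise DataError(f"{path}: histogram CSV needs columns 'hu' and 'count'")
    counts = np.zeros(N_BINS, dtype=np.int64)
    hu = df["hu"].to_numpy(dtype=int)
    if hu.min() < HU_MIN or hu.max() > HU_MAX:
        raise DataError(f"{path}: HU bins outside [{HU_MIN}, {HU_MAX}]")
    counts[hu - HU_MIN] = df["count"].to_numpy(dtype=np.int64)
    return IntensityHistogram(counts, source_label)


def outcomes_to_row(outcome: VolumeOutcomes, animal_id: str = "") -> dict:
    return {
        "animal_id": animal_id,
        "segment": outcome.source_label,
        "threshold_hu": outcome.threshold_hu,
        "weighted_mean_hu": outcome.weighted_mean_hu,
        "total_voxels": outcome.total_voxels,
        "aerated_voxels": outcome.aerated_voxels,
        "tissue_voxels": outcome.tissue_voxels,
        "total_mm3": outcome.total_mm3,
        "aerated_mm3": outcome.aerated_mm3,
        "tissue_mm3": outcome.tissue_mm3,
        "aerated_fraction": outcome.aerated_fraction,
        "tissue_fraction": outcome.tissue_fraction,
    }


def write_outcomes_csv(rows: Sequence[dict], path: str | Path) -> None:
    pd.DataFrame(list(rows)).to_csv(path, index=False)


# -- histology ---------------------------------------------------------------

def read_slide(path: str | Path, pixel_area_um2: float, **meta) -> RgbSlide:
    img = iio.imread(str(path))
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[:, :, :3]
    return RgbSlide(img, pixel_area_um2, **meta)


def _polygon_mask(shape: tuple[int, int], vertices: np.ndarray) -> np.ndarray:
    from skimage.draw import polygon2mask

    # vertices arrive as (x, y) image coordinates, y-down; polygon2mask wants (row, col)
    return polygon2mask(shape, vertices[:, ::-1])


def read_roi(path: str | Path, shape: tuple[int, int]) -> RoiMask:
    """Read an ROI: PNG mask (nonzero = inside) or GeoJSON-style polygon."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        obj = json.loads(path.read_text())
        geom = obj.get("geometry", obj)
        coords = geom["coordinates"]
        if geom.get("type", "Polygon") == "Polygon":
            coords = coords[0]
        return RoiMask(_polygon_mask(shape, np.asarray(coords, dtype=float)))
    img = iio.imread(str(path))
    if img.ndim == 3:
        img = img[..., 0]
    if img.shape != shape:
        raise DataError(f"ROI mask shape {img.shape} != slide shape {shape}")
    return RoiMask(img > 0)


def read_training_csv(path: str | Path) -> TrainingSet:
    df = pd.read_csv(path)
    if not {"category", "R", "G", "B"} <= set(df.columns):
        raise DataError(f"{path}: training CSV needs columns category,R,G,B")
    pixels = {
        cat: sub[["R", "G", "B"]].to_numpy(dtype=float)
        for cat, sub in df.groupby("category")
    }
    return TrainingSet(pixels)


def write_label_png(labels: np.ndarray, path: str | Path) -> None:
    iio.imwrite(str(path), labels.astype(np.uint8))


def histo_outcomes_to_row(o: HistoAreaOutcomes) -> dict:
    return {
        "animal_id": o.animal_id,
        "section_id": o.section_id,
        "blue_um2": o.blue_um2,
        "pink_um2": o.pink_um2,
        "white_um2": o.white_um2,
        "total_um2": o.total_um2,
        "tissue_um2": o.tissue_um2,
        "blue_fraction": o.blue_fraction,
        "pink_fraction": o.pink_fraction,
        "white_fraction": o.white_fraction,
        "tissue_fraction": o.tissue_fraction,
        "excluded": o.excluded,
    }
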