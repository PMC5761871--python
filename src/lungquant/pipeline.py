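"""End-to-end orchestration: segment -> quantify -> correlate.

`segment_lung` bundles the segmentation stages (region grow, morphological
refinement, airway extraction, size exclusion, left/right split) into one
call; `run_pipeline` executes whichever of the CT, histology and
correlation stages a `RunConfig` enables, writes every declared output and
a provenance record, and raises `StageError` naming the failing stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import PairedOutcomes, spearman
from .ct_segmentation import (
    exclude_large_airways,
    extract_airways,
    refine_mask,
    seeded_region_grow,
    split_left_right,
)
from .densitometry import build_histogram, derive_threshold, partition_volumes
from .errors import LungQuantError, SplitFailedError
from .histomorphometry import classify_slide, quantify_areas, reclassify_regions, train_classifier
from .io import (
    histo_outcomes_to_row,
    outcomes_to_row,
    read_ct,
    read_roi,
    read_slide,
    read_training_csv,
    write_histogram_csv,
    write_label_png,
    write_mask_nifti,
    write_outcomes_csv,
)
from .volume import AirwaySegment, CtVolume, SegmentationMask

__all__ = ["RunConfig", "SegmentationResult", "StageError", "segment_lung", "run_pipeline"]


class StageError(LungQuantError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class SegmentationResult:
    whole_lung: SegmentationMask          # refined, airways excluded
    pre_exclusion: SegmentationMask       # refined, airways still included
    airways: AirwaySegment
    left_lung: SegmentationMask | None
    right_lung: SegmentationMask | None
    split_status: str                     # "ok" or "split failed: ..."


@dataclass
class RunConfig:
    """Parameters for one pipeline run; CLI flags override file values."""

    ct_path: str | None = None
    seed_zyx: tuple[int, int, int] | None = None
    hu_low: float = -1000.0
    hu_high: float = -150.0
    grow_r: int = 1
    shrink_r: int = 1
    fill_holes: bool = True
    smooth_r: int = 1
    air_hu_max: float = -920.0
    airway_cutoff_um: float = 200.0
    split_plane: tuple[tuple[float, float, float], tuple[float, float, float]] | None = None
    threshold_mode: str = "fixed"   # "fixed" or "auto" (derive from WT histograms)
    threshold_hu: int = -256
    wt_histogram_csvs: list[str] = field(default_factory=list)
    histo_image: str | None = None
    histo_roi: str | None = None
    histo_training_csv: str | None = None
    pixel_area_um2: float = 1.0
    min_total_area_um2: float = 15e6
    reclass_roi: str | None = None
    animal_id: str = ""
    out_dir: str = "lungquant_out"
    rng_seed: int = 0
    allow_anisotropic: bool = False

    @classmethod
    def from_json(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def segment_lung(
    volume: CtVolume,
    seed: tuple[int, int, int],
    hu_low: float = -1000.0,
    hu_high: float = -150.0,
    grow_r: int = 1,
    shrink_r: int = 1,
    fill_holes: bool = True,
    smooth_r: int = 1,
    air_hu_max: float = -920.0,
    airway_cutoff_um: float = 200.0,
    split_plane=None,
) -> SegmentationResult:
    """Run the full segmentation chain from a bronchus seed.

    Region-grows over [hu_low, hu_high], refines morphologically, extracts
    the conducting-airway lumen from the same seed, removes branches wider
    than the cutoff and splits left/right at the carina. A failed split is
    reported in ``split_status`` rather than raised, so single-lung or
    bridged volumes still yield whole-lung outcomes.
    """
    grown = seeded_region_grow(volume, seed, hu_low, hu_high)
    refined = refine_mask(grown, grow_r, shrink_r, fill_holes, smooth_r)
    airways = extract_airways(volume, refined, seed, air_hu_max)
    lung = exclude_large_airways(refined, airways, airway_cutoff_um)
    lung = SegmentationMask(lung.voxels, "whole_lung")
    try:
        left, right = split_left_right(
            lung, airways, split_plane, volume.voxel_edge_um
        )
        status = "ok"
    except SplitFailedError as exc:
        left = right = None
        status = f"split failed: {exc}"
    return SegmentationResult(lung, refined, airways, left, right, status)


def _provenance(config: RunConfig) -> dict:
    cfg = asdict(config)
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    return {
        "package": "lungquant",
        "version": __version__,
        "numpy": np.__version__,
        "config": cfg,
        "config_sha256": digest,
        "rng_seed": config.rng_seed,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write all outputs under ``out_dir``.

    Returns a result bundle (dict) with the provenance record, per-segment
    volume outcomes, histology outcomes and any correlation computed.
    Re-running with an identical config produces byte-identical CSV/JSON.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {"provenance": _provenance(config), "stages": []}

    ct_rows = []
    if config.ct_path is not None:
        try:
            volume = read_ct(config.ct_path, config.allow_anisotropic)
            if config.seed_zyx is None:
                raise ValueError("seed_zyx required for the CT stage")
            seg = segment_lung(
                volume, tuple(config.seed_zyx), config.hu_low, config.hu_high,
                config.grow_r, config.shrink_r, config.fill_holes, config.smooth_r,
                config.air_hu_max, config.airway_cutoff_um, config.split_plane,
            )
            write_mask_nifti(seg.whole_lung, volume.voxel_edge_um, out / "whole_lung.nii.gz")
            airway_mask = SegmentationMask(seg.airways.voxels, "airway")
            write_mask_nifti(airway_mask, volume.voxel_edge_um, out / "airway.nii.gz")
            segments = [seg.whole_lung]
            if seg.left_lung is not None and seg.right_lung is not None:
                segments += [seg.left_lung, seg.right_lung]
                write_mask_nifti(seg.left_lung, volume.voxel_edge_um, out / "left_lung.nii.gz")
                write_mask_nifti(seg.right_lung, volume.voxel_edge_um, out / "right_lung.nii.gz")
            if config.threshold_mode == "auto":
                from .io import read_histogram_csv

                wt = [read_histogram_csv(p) for p in config.wt_histogram_csvs]
                threshold = derive_threshold(wt)
            else:
                threshold = int(config.threshold_hu)
            for mask in segments:
                hist = build_histogram(volume, mask)
                write_histogram_csv(hist, out / f"hist_{mask.label}.csv")
                vo = partition_volumes(hist, threshold, volume.voxel_edge_um)
                ct_rows.append(outcomes_to_row(vo, config.animal_id))
            write_outcomes_csv(ct_rows, out / "ct_outcomes.csv")
            seg_report = {
                "seed_zyx": list(config.seed_zyx),
                "hu_window": [config.hu_low, config.hu_high],
                "threshold_hu": threshold,
                "airway_cutoff_um": config.airway_cutoff_um,
                "split_status": seg.split_status,
                "voxel_counts": {m.label: m.voxel_count for m in segments},
                "airway_voxels": seg.airways.voxel_count,
            }
            (out / "segmentation.json").write_text(json.dumps(seg_report, indent=2))
            bundle["ct_outcomes"] = ct_rows
            bundle["segmentation"] = seg_report
            bundle["stages"].append("ct")
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise StageError("ct", exc) from exc

    histo_rows = []
    if config.histo_image is not None:
        try:
            slide = read_slide(config.histo_image, config.pixel_area_um2,
                               animal_id=config.animal_id)
            roi = read_roi(config.histo_roi, slide.shape)
            training = read_training_csv(config.histo_training_csv)
            clf = train_classifier(training)
            labels = classify_slide(slide, roi, clf)
            if config.reclass_roi:
                regions = read_roi(config.reclass_roi, slide.shape)
                labels, _ = reclassify_regions(labels, regions, "White", "Pink")
            write_label_png(labels, out / "labels.png")
            ho = quantify_areas(labels, config.pixel_area_um2,
                                config.min_total_area_um2,
                                animal_id=config.animal_id)
            histo_rows.append(histo_outcomes_to_row(ho))
            write_outcomes_csv(histo_rows, out / "histo_outcomes.csv")
            bundle["histo_outcomes"] = histo_rows
            bundle["stages"].append("histo")
        except Exception as exc:  # noqa: BLE001
            raise StageError("histo", exc) from exc

    if ct_rows and histo_rows:
        try:
            pairs = PairedOutcomes(
                np.array([config.animal_id]),
                np.array([ct_rows[0]["tissue_mm3"]]),
                np.array([histo_rows[0]["tissue_um2"]]),
            )
            bundle["paired_n"] = pairs.n  # single-run pairing; rho needs a cohort
        except Exception as exc:  # noqa: BLE001
            raise StageError("correlate", exc) from exc

    (out / "provenance.json").write_text(
        json.dumps(bundle["provenance"], indent=2, sort_keys=True, default=str)
    )
    return bundle


def correlate_outcomes(
    ct_csv: str | Path,
    histo_csv: str | Path,
    ct_column: str = "tissue_mm3",
    histo_column: str = "tissue_um2",
    pair_on: str = "animal_id",
) -> dict:
    """Pair per-animal CT and histology outcome CSVs and compute Spearman rho."""
    ct = pd.read_csv(ct_csv)
    histo = pd.read_csv(histo_csv)
    merged = ct.merge(histo, on=pair_on, suffixes=("_ct", "_histo"))
    pairs = PairedOutcomes(
        merged[pair_on].to_numpy(),
        merged[ct_column].to_numpy(dtype=float),
        merged[histo_column].to_numpy(dtype=float),
    )
    res = spearman(pairs)
    return {
        "ct_column": ct_column,
        "histo_column": histo_column,
        "n_pairs": res.n,
        "rho": res.rho,
        "p_value": res.p_value,
        "p_method": res.method,
    }
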