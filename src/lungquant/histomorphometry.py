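"""Automated H&E histomorphometry via Bayesian RGB pixel classification.

Every pixel inside a lung region of interest is assigned to one of three
categories: Blue (hematoxylin-stained nuclei), Pink (eosin-stained
cytoplasm, extracellular matrix and red blood cells) or White (alveolar air
space). The classifier is a Gaussian discriminant trained on a small set of
hand-picked pixels per category (>= 15): each category gets a mean RGB
vector and a full 3x3 covariance (regularized by eps on the diagonal), and a
pixel goes to the category with the highest posterior density. Blue + Pink
sum to total lung tissue area; all areas are also normalized to the ROI
total so shrinkage during histologic processing cancels.

Empty vessel lumens — air-bright because erythrocytes wash out during
processing — can be reclassified from White to Pink over a user-drawn
region, mirroring the manual curation step of the original workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import TrainingError

__all__ = [
    "CATEGORIES",
    "LABEL_CODES",
    "RgbSlide",
    "RoiMask",
    "TrainingSet",
    "PixelClassifier",
    "HistoAreaOutcomes",
    "train_classifier",
    "classify_slide",
    "reclassify_regions",
    "quantify_areas",
    "aggregate_animal",
]

CATEGORIES = ("Blue", "Pink", "White")
#: label-map codes; 0 is reserved for pixels outside the ROI
LABEL_CODES = {"Blue": 1, "Pink": 2, "White": 3}
MIN_TRAINING_PIXELS = 15


@dataclass
class RgbSlide:
    """A 2D RGB image of an H&E-stained lung section."""

    pixels: np.ndarray  # (H, W, 3) uint8-range integers
    pixel_area_um2: float
    section_id: str = ""
    animal_id: str = ""
    level_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be (H, W, 3)")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        if self.pixel_area_um2 <= 0:
            raise ValueError("pixel_area_um2 must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]  # type: ignore[return-value]


@dataclass
class RoiMask:
    """Boolean region-of-interest mask congruent with its slide."""

    inside: np.ndarray

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside, dtype=bool)
        if self.inside.ndim != 2:
            raise ValueError("ROI mask must be 2D")

    @property
    def pixel_count(self) -> int:
        return int(self.inside.sum())


@dataclass
class TrainingSet:
    """Hand-picked training pixels per category, as (n, 3) RGB arrays."""

    pixels: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for cat in CATEGORIES:
            if cat not in self.pixels:
                raise TrainingError(f"training set missing category {cat!r}")
            arr = np.asarray(self.pixels[cat], dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise TrainingError(f"{cat}: training pixels must be (n, 3) RGB")
            clean[cat] = arr
        self.pixels = clean


@dataclass
class PixelClassifier:
    """Per-category Gaussian discriminant in RGB space."""

    means: dict[str, np.ndarray]
    covariances: dict[str, np.ndarray]
    priors: dict[str, float]
    regularization_eps: float = 1e-3
    mode: str = "gaussian"  # or "box": per-channel min/max with nearest-mean fallback
    boxes: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def _log_densities(self, rgb: np.ndarray) -> np.ndarray:
        """Log posterior density (up to a constant) per category, shape (n, 3)."""
        out = np.empty((rgb.shape[0], len(CATEGORIES)))
        for j, cat in enumerate(CATEGORIES):
            cov = self.covariances[cat]
            diff = rgb - self.means[cat]
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0:
                raise np.linalg.LinAlgError(f"covariance for {cat} not positive-definite")
            maha = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(cov), diff)
            out[:, j] = np.log(self.priors[cat]) - 0.5 * (logdet + maha)
        return out

    def predict(self, rgb: np.ndarray) -> np.ndarray:
        """Category codes (1=Blue, 2=Pink, 3=White) for an (n, 3) RGB array.

        Ties break by the fixed category order Blue > Pink > White.
        """
        rgb = np.asarray(rgb, dtype=float)
        if self.mode == "gaussian":
            return np.argmax(self._log_densities(rgb), axis=1).astype(np.uint8) + 1
        # box mode: inside exactly one category's RGB range -> that category;
        # otherwise fall back to the nearest category mean.
        n = rgb.shape[0]
        in_box = np.zeros((n, len(CATEGORIES)), dtype=bool)
        for j, cat in enumerate(CATEGORIES):
            lo, hi = self.boxes[cat]
            in_box[:, j] = np.all((rgb >= lo) & (rgb <= hi), axis=1)
        dist = np.stack(
            [np.linalg.norm(rgb - self.means[cat], axis=1) for cat in CATEGORIES], axis=1
        )
        labels = np.argmin(dist, axis=1)
        single = in_box.sum(axis=1) == 1
        labels[single] = np.argmax(in_box[single], axis=1)
        multi = in_box.sum(axis=1) > 1
        if multi.any():
            masked = np.where(in_box[multi], dist[multi], np.inf)
            labels[multi] = np.argmin(masked, axis=1)
        return labels.astype(np.uint8) + 1


@dataclass
class HistoAreaOutcomes:
    """Per-section (or per-animal) category areas and normalized fractions."""

    blue_um2: float
    pink_um2: float
    white_um2: float
    total_um2: float
    tissue_um2: float
    blue_fraction: float
    pink_fraction: float
    white_fraction: float
    tissue_fraction: float
    excluded: bool = False
    section_id: str = ""
    animal_id: str = ""


def train_classifier(
    training: TrainingSet,
    priors: Mapping[str, float] | None = None,
    regularization_eps: float = 1e-3,
    mode: str = "gaussian",
) -> PixelClassifier:
    """Fit the per-category Gaussian discriminant from training pixels.

    Requires at least 15 pixels per category (warns at exactly 15, the bare
    minimum the protocol allows). Equal priors by default. ``mode="box"``
    additionally records per-channel min/max ranges per category and
    classifies by range membership with a nearest-mean fallback.
    """
    if mode not in ("gaussian", "box"):
        raise ValueError(f"unknown classifier mode {mode!r}")
    means, covs, boxes = {}, {}, {}
    for cat in CATEGORIES:
        arr = training.pixels[cat]
        if len(arr) < MIN_TRAINING_PIXELS:
            raise TrainingError(
                f"category {cat!r} has {len(arr)} training pixels; need >= {MIN_TRAINING_PIXELS}"
            )
        if len(arr) == MIN_TRAINING_PIXELS:
            warnings.warn(
                f"category {cat!r} has exactly {MIN_TRAINING_PIXELS} training pixels "
                "(protocol minimum); consider adding more",
                stacklevel=2,
            )
        means[cat] = arr.mean(axis=0)
        covs[cat] = np.cov(arr, rowvar=False) + regularization_eps * np.eye(3)
        boxes[cat] = (arr.min(axis=0), arr.max(axis=0))
    for a, b in (("Blue", "Pink"), ("Blue", "White"), ("Pink", "White")):
        if np.allclose(means[a], means[b]) and np.allclose(covs[a], covs[b]):
            warnings.warn(
                f"categories {a!r} and {b!r} are indistinguishable; "
                f"ties resolve by fixed order Blue > Pink > White",
                stacklevel=2,
            )
    if priors is None:
        p = {cat: 1.0 / len(CATEGORIES) for cat in CATEGORIES}
    else:
        total = float(sum(priors[c] for c in CATEGORIES))
        if total <= 0:
            raise ValueError("priors must have positive sum")
        p = {cat: float(priors[cat]) / total for cat in CATEGORIES}
    return PixelClassifier(means, covs, p, regularization_eps, mode, boxes)


def classify_slide(
    slide: RgbSlide, roi: RoiMask, clf: PixelClassifier
) -> np.ndarray:
    """Label every ROI pixel (uint8 map: 0 outside ROI, 1=Blue, 2=Pink, 3=White)."""
    if slide.shape != roi.inside.shape:
        raise ValueError("slide and ROI must be congruent")
    if roi.pixel_count == 0:
        raise ValueError("empty ROI: nothing to classify")
    labels = np.zeros(slide.shape, dtype=np.uint8)
    labels[roi.inside] = clf.predict(slide.pixels[roi.inside].reshape(-1, 3))
    return labels


def reclassify_regions(
    labels: np.ndarray,
    regions: RoiMask,
    from_cat: str = "White",
    to_cat: str = "Pink",
) -> tuple[np.ndarray, int]:
    """Relabel ``from_cat`` pixels inside ``regions`` as ``to_cat``.

    Used for empty arterial lumens that classify White but are vascular
    space. Returns the new label map and the number of pixels changed;
    pixels of other categories inside the region are untouched.
    """
    if labels.shape != regions.inside.shape:
        raise ValueError("label map and region mask must be congruent")
    out = labels.copy()
    change = regions.inside & (labels == LABEL_CODES[from_cat])
    out[change] = LABEL_CODES[to_cat]
    return out, int(change.sum())


def quantify_areas(
    labels: np.ndarray,
    pixel_area_um2: float,
    min_total_area_um2: float = 15e6,
    section_id: str = "",
    animal_id: str = "",
) -> HistoAreaOutcomes:
    """Convert a label map into category areas and normalized fractions.

    Sections whose total labelled area falls below ``min_total_area_um2``
    (default 15 mm^2 of lung) are flagged ``excluded`` rather than dropped,
    so downstream aggregation can report them.
    """
    if pixel_area_um2 <= 0:
        raise ValueError("pixel_area_um2 must be positive")
    counts = {cat: int((labels == code).sum()) for cat, code in LABEL_CODES.items()}
    blue = counts["Blue"] * pixel_area_um2
    pink = counts["Pink"] * pixel_area_um2
    white = counts["White"] * pixel_area_um2
    total = blue + pink + white
    frac = (lambda a: a / total) if total > 0 else (lambda a: 0.0)
    return HistoAreaOutcomes(
        blue_um2=blue,
        pink_um2=pink,
        white_um2=white,
        total_um2=total,
        tissue_um2=blue + pink,
        blue_fraction=frac(blue),
        pink_fraction=frac(pink),
        white_fraction=frac(white),
        tissue_fraction=frac(blue + pink),
        excluded=total < min_total_area_um2,
        section_id=section_id,
        animal_id=animal_id,
    )


def aggregate_animal(outcomes: Sequence[HistoAreaOutcomes]) -> HistoAreaOutcomes:
    """Combine the per-section outcomes of one animal.

    Absolute areas are the unweighted mean over included sections; fractions
    are recomputed from the summed areas (not averaged fractions), so larger
    sections contribute proportionally to the composition estimate.
    """
    included = [o for o in outcomes if not o.excluded]
    if not included:
        raise ValueError("all sections excluded; no per-animal aggregate")
    n = len(included)
    blue_sum = sum(o.blue_um2 for o in included)
    pink_sum = sum(o.pink_um2 for o in included)
    white_sum = sum(o.white_um2 for o in included)
    total_sum = blue_sum + pink_sum + white_sum
    frac = (lambda a: a / total_sum) if total_sum > 0 else (lambda a: 0.0)
    return HistoAreaOutcomes(
        blue_um2=blue_sum / n,
        pink_um2=pink_sum / n,
        white_um2=white_sum / n,
        total_um2=total_sum / n,
        tissue_um2=(blue_sum + pink_sum) / n,
        blue_fraction=frac(blue_sum),
        pink_fraction=frac(pink_sum),
        white_fraction=frac(white_sum),
        tissue_fraction=frac(blue_sum + pink_sum),
        excluded=False,
        animal_id=included[0].animal_id,
    )
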