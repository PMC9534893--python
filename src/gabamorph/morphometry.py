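"""Image-based leaf morphometry.

Measures leaf length, width and area from an RGB image of a single leaf
on a light background, following the standard five-step procedure:
(1) threshold segmentation on the grayscale image, (2) binary mask,
(3) noise removal and hole filling, (4) tip and petiole localization,
(5) pixel measurements, converted to centimetres with a px-per-cm
calibration.

Length is the Euclidean two-point distance from the lamina tip to the
petiole intersection along the midrib.  Width is the maximal foreground
extent perpendicular to that axis.  Area is the foreground pixel count.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .exceptions import GeometryError, NoLeafError, ParameterError


@dataclass(frozen=True)
class CalibrationSettings:
    """Pixel-to-centimetre scale of the imaging rig."""

    px_per_cm: float

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ParameterError("px_per_cm must be positive")


@dataclass
class LeafMeasurement:
    """Pixel and calibrated measurements of one leaf.

    ``lli`` is the leaf length index, ``lwi`` the width index and
    ``lai`` the area index; ``*_px`` fields are in pixels / pixel
    counts, the calibrated fields in cm (area in cm^2).
    """

    tip_rc: tuple[int, int]
    petiole_rc: tuple[int, int]
    lli_px: float
    lwi_px: float
    lai_px: int
    lli_cm: float | None = None
    lwi_cm: float | None = None
    lai_cm2: float | None = None


# ---------------------------------------------------------------------------
# steps 1-3: segmentation and cleaning
# ---------------------------------------------------------------------------

def segment_leaf(image: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Threshold the image into a boolean leaf mask.

    The image is converted to grayscale and thresholded with Otsu's
    method unless a fixed ``threshold`` (on the 0-1 gray scale) is
    given.  Foreground polarity is auto-detected from the border: the
    side of the threshold *not* occupied by the border is the leaf.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise NoLeafError("empty image")
    if image.ndim == 3:
        gray = rgb2gray(image)
    else:
        gray = image.astype(float)
        if gray.max() > 1.0:
            gray = gray / 255.0
    if threshold is None:
        if np.ptp(gray) < 1e-6:
            raise NoLeafError("image is uniform; no leaf to segment")
        threshold = threshold_otsu(gray)
        # isodata-style refinement: with strongly quantized histograms
        # (synthetic renders have a handful of gray levels) the raw Otsu
        # bin edge can fall inside a mode; iterate the threshold to the
        # midpoint of the class means, which is stable between modes
        for _ in range(50):
            below = gray[gray <= threshold]
            above = gray[gray > threshold]
            if below.size == 0 or above.size == 0:
                break
            refined = 0.5 * (below.mean() + above.mean())
            if abs(refined - threshold) < 1e-6:
                break
            threshold = refined
    border = np.concatenate([gray[0, :], gray[-1, :], gray[:, 0], gray[:, -1]])
    light_background = np.median(border) > threshold
    mask = gray < threshold if light_background else gray > threshold
    if not mask.any():
        raise NoLeafError("no foreground pixels after thresholding")
    return mask


def clean_mask(
    mask: np.ndarray,
    min_component_px: int = 20,
    fill_holes: bool = True,
) -> np.ndarray:
    """Keep the largest connected component and optionally fill holes.

    Raises :class:`NoLeafError` when every component is smaller than
    ``min_component_px``.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask)
    if n == 0:
        raise NoLeafError("mask has no foreground components")
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    if sizes[largest - 1] < min_component_px:
        raise NoLeafError(
            f"largest component has {int(sizes[largest - 1])} px "
            f"(< min_component_px={min_component_px})"
        )
    cleaned = labels == largest
    if fill_holes:
        cleaned = ndimage.binary_fill_holes(cleaned)
    return cleaned


# ---------------------------------------------------------------------------
# step 4: axis endpoints
# ---------------------------------------------------------------------------

def _principal_axis(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def locate_tip_petiole(
    mask: np.ndarray,
    petiole_opening_radius: int = 4,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Locate the lamina tip and the petiole intersection.

    A morphological opening with a disk of ``petiole_opening_radius``
    suppresses the thin petiole stub; the extreme foreground pixels of
    the opened lamina along its principal axis are the tip and the
    lamina base (the petiole intersection).  Which endpoint is the
    petiole side is decided from where the suppressed thin pixels lie;
    the tip is returned first.  The construction is invariant to image
    rotation up to rasterization error.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 3:
        raise GeometryError("mask has fewer than 3 foreground pixels")
    opened = mask
    if petiole_opening_radius > 0:
        opened = ndimage.binary_opening(mask, structure=disk(petiole_opening_radius))
        if opened.sum() < 3:  # shape thinner than the opening radius
            opened = mask
    coords = np.argwhere(opened).astype(float)
    axis = _principal_axis(coords)
    proj = coords @ axis
    perp = coords @ np.array([-axis[1], axis[0]])
    mid_perp = np.median(perp)

    def _endpoint(extreme_proj, side):
        # among pixels within 1 px of the extreme projection, take the
        # one closest to the midrib so flat/rounded ends do not bias the
        # endpoint off-axis; ties resolve to the more extreme pixel
        cand = np.flatnonzero(side * (proj - extreme_proj) >= -1.0)
        order = np.lexsort((-side * proj[cand], np.abs(perp[cand] - mid_perp)))
        return coords[cand[order[0]]]

    p_lo = _endpoint(proj.min(), side=-1)
    p_hi = _endpoint(proj.max(), side=1)

    residue = mask & ~opened
    petiole_low = None
    if residue.sum() >= 3:
        labels, n = ndimage.label(residue)
        sizes = ndimage.sum_labels(residue, labels, index=np.arange(1, n + 1))
        blob = np.argwhere(labels == int(np.argmax(sizes)) + 1).astype(float)
        blob_proj = blob.mean(axis=0) @ axis
        mid = 0.5 * (proj.min() + proj.max())
        petiole_low = blob_proj < mid

    if petiole_low is None or petiole_low:
        tip, petiole = p_hi, p_lo
    else:
        tip, petiole = p_lo, p_hi
    return (int(tip[0]), int(tip[1])), (int(petiole[0]), int(petiole[1]))


# ---------------------------------------------------------------------------
# step 5: measurements
# ---------------------------------------------------------------------------

def leaf_length(tip: tuple[float, float], petiole: tuple[float, float]) -> float:
    """Euclidean two-point distance between tip and petiole points.

    (The usual distance formula with a *plus* between the squared
    coordinate differences; a minus would be dimensionally meaningless.)
    """
    return float(np.hypot(tip[0] - petiole[0], tip[1] - petiole[1]))


def leaf_width(
    mask: np.ndarray,
    tip: tuple[float, float],
    petiole: tuple[float, float],
) -> float:
    """Maximal lamina width perpendicular to the tip-petiole axis.

    Foreground pixels are projected onto the axis and grouped into 1-px
    slabs; each slab's width is its perpendicular pixel extent
    (max - min + 1) and the leaf width is the maximum over slabs.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 3:
        raise GeometryError("mask has fewer than 3 foreground pixels")
    axis = np.array([tip[0] - petiole[0], tip[1] - petiole[1]], dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise GeometryError("tip and petiole coincide; no axis")
    axis /= norm
    perp = np.array([-axis[1], axis[0]])
    coords = np.argwhere(mask).astype(float)
    along = coords @ axis
    across = coords @ perp
    bins = np.floor(along - along.min()).astype(int)
    width = 0.0
    order = np.argsort(bins, kind="stable")
    bins_sorted = bins[order]
    across_sorted = across[order]
    boundaries = np.flatnonzero(np.diff(bins_sorted)) + 1
    for chunk in np.split(across_sorted, boundaries):
        if chunk.size >= 2:
            width = max(width, chunk.max() - chunk.min() + 1.0)
    if width == 0.0:  # degenerate: single-pixel slabs only
        width = 1.0
    return float(width)


def leaf_area(mask: np.ndarray) -> int:
    """Foreground pixel count of the (cleaned) mask."""
    return int(np.asarray(mask, dtype=bool).sum())


def calibrate(measurement: LeafMeasurement, settings: CalibrationSettings) -> LeafMeasurement:
    """Convert pixel measures to centimetres (area uses the squared scale)."""
    s = settings.px_per_cm
    return replace(
        measurement,
        lli_cm=measurement.lli_px / s,
        lwi_cm=measurement.lwi_px / s,
        lai_cm2=measurement.lai_px / (s * s),
    )


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def measure_leaf(
    image: np.ndarray,
    calibration: CalibrationSettings | None = None,
    threshold: float | None = None,
    min_component_px: int = 20,
    fill_holes: bool = True,
    petiole_opening_radius: int = 4,
) -> LeafMeasurement:
    """Run the full pipeline on one image: segment, clean, locate the
    axis endpoints, measure, and (optionally) calibrate."""
    mask = clean_mask(
        segment_leaf(image, threshold=threshold),
        min_component_px=min_component_px,
        fill_holes=fill_holes,
    )
    tip, petiole = locate_tip_petiole(mask, petiole_opening_radius=petiole_opening_radius)
    meas = LeafMeasurement(
        tip_rc=tip,
        petiole_rc=petiole,
        lli_px=leaf_length(tip, petiole),
        lwi_px=leaf_width(mask, tip, petiole),
        lai_px=leaf_area(mask),
    )
    if calibration is not None:
        meas = calibrate(meas, calibration)
    return meas


def measure_directory(
    directory: str | Path,
    calibration: CalibrationSettings,
    pattern: str = "*.png",
    **kwargs,
) -> pd.DataFrame:
    """Measure every image matching ``pattern`` in ``directory``."""
    import imageio.v3 as iio

    records = []
    for path in sorted(Path(directory).glob(pattern)):
        meas = measure_leaf(iio.imread(path), calibration=calibration, **kwargs)
        records.append(
            {
                "image": path.name,
                "tip_row": meas.tip_rc[0],
                "tip_col": meas.tip_rc[1],
                "petiole_row": meas.petiole_rc[0],
                "petiole_col": meas.petiole_rc[1],
                "LLI_px": meas.lli_px,
                "LWI_px": meas.lwi_px,
                "LAI_px": meas.lai_px,
                "LLI_cm": meas.lli_cm,
                "LWI_cm": meas.lwi_cm,
                "LAI_cm2": meas.lai_cm2,
            }
        )
    return pd.DataFrame(records)
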