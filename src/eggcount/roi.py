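"""Grayscale conversion and Petri-dish region-of-interest detection.

The dish appears as the single large dark, near-circular region on a white
background.  Detection thresholds the frame at the midpoint between the two
dominant intensity modes (white background vs dark medium), keeps the
largest dark connected component that is circular and large enough, and
fills its holes — bright eggs lying on the medium are holes in the dark
region and belong to the dish interior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.ndimage import gaussian_filter1d
from skimage.measure import perimeter as _skimage_perimeter

from .errors import InvalidInputError, PlateNotFoundError

__all__ = [
    "PlateROI",
    "ScaleCalibration",
    "EQUAL_WEIGHTS",
    "LUMINANCE_WEIGHTS",
    "to_grayscale",
    "detect_plate_roi",
    "calibrate_scale",
]

EQUAL_WEIGHTS = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)
LUMINANCE_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class PlateROI:
    """Detected dish region: boolean membership mask plus a circle fit.

    ``center_xy`` is the mask centroid (x, y); ``radius`` is the radius of
    the circle with the mask's area; ``circularity`` is 4π·area/perimeter².
    """

    mask: np.ndarray
    center_xy: tuple[float, float]
    radius: float
    circularity: float

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixel scale derived from a visual mark of known physical length."""

    pixels_per_mm: float
    mark_length_mm: float
    mark_length_px: float


def to_grayscale(image: np.ndarray, channel_weights=EQUAL_WEIGHTS) -> np.ndarray:
    """Convert a color image to 8-bit gray as a rounded weighted channel sum.

    Already-gray (2-D) input is returned unchanged.  The default equal
    weights reproduce an unweighted RGB mean; ``LUMINANCE_WEIGHTS`` gives
    the Rec. 601 luma alternative.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        return image
    if image.ndim != 3 or image.shape[2] < 3:
        raise InvalidInputError(f"expected HxW or HxWx3 image, got shape {image.shape}")
    w = np.asarray(channel_weights, dtype=float)
    if w.shape != (3,) or np.any(w < 0):
        raise InvalidInputError("channel_weights must be three non-negative numbers")
    if abs(w.sum() - 1.0) > 1e-6:
        raise InvalidInputError(f"channel_weights must sum to 1, got {w.sum()!r}")
    gray = image[:, :, 0] * w[0] + image[:, :, 1] * w[1] + image[:, :, 2] * w[2]
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def _bimodal_midpoint(gray: np.ndarray) -> int:
    """Midpoint between the two highest modes of the smoothed full-frame histogram."""
    hist = np.bincount(gray.ravel(), minlength=256).astype(float)
    smooth = gaussian_filter1d(hist, sigma=3.0, mode="nearest")
    interior = smooth[1:-1]
    is_peak = (interior >= smooth[:-2]) & (interior > smooth[2:])
    peaks = np.nonzero(is_peak)[0] + 1
    if smooth[0] > smooth[1]:
        peaks = np.concatenate(([0], peaks))
    if smooth[255] > smooth[254]:
        peaks = np.concatenate((peaks, [255]))
    if len(peaks) < 2:
        raise PlateNotFoundError(
            "full-frame histogram is unimodal: no dark plate mode distinct "
            "from the background was found"
        )
    top_two = peaks[np.argsort(smooth[peaks])][-2:]
    return int(round((top_two.min() + top_two.max()) / 2.0))


def detect_plate_roi(
    gray: np.ndarray,
    dark_threshold: int | None = None,
    min_circularity: float = 0.8,
    min_area_fraction: float = 0.1,
) -> PlateROI:
    """Locate the plate as the largest dark, circular connected region.

    Parameters
    ----------
    gray
        8-bit grayscale frame.
    dark_threshold
        Pixels strictly below this value are "dark".  ``None`` (default)
        sets it automatically to the midpoint between the two dominant
        histogram modes.
    min_circularity
        Minimum 4π·area/perimeter² of the hole-filled candidate; rejects
        shadows and labels.
    min_area_fraction
        Minimum candidate area as a fraction of the frame.

    Raises
    ------
    PlateNotFoundError
        If no candidate passes the filters; the message reports the best
        candidate's circularity and area.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise InvalidInputError("detect_plate_roi expects an 8-bit grayscale image")
    if dark_threshold is None:
        dark_threshold = _bimodal_midpoint(gray)
    dark = gray < dark_threshold
    if not dark.any():
        raise PlateNotFoundError(
            f"no pixels below dark threshold {dark_threshold}; "
            "frame contains no dark region"
        )
    labels, n = ndimage.label(dark, structure=np.ones((3, 3), bool))
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    order = np.argsort(areas)[::-1] + 1
    min_area = min_area_fraction * gray.size
    best = None  # (circularity, area) of the best rejected candidate
    for lab in order:
        cand = ndimage.binary_fill_holes(labels == lab)
        area = float(cand.sum())
        perim = _skimage_perimeter(cand, neighborhood=4)
        circ = 4.0 * np.pi * area / perim**2 if perim > 0 else 0.0
        if best is None or (circ, area) > best:
            best = (circ, area)
        if area >= min_area and circ >= min_circularity:
            ys, xs = np.nonzero(cand)
            center = (float(xs.mean()), float(ys.mean()))
            radius = float(np.sqrt(area / np.pi))
            return PlateROI(mask=cand, center_xy=center, radius=radius, circularity=float(circ))
    raise PlateNotFoundError(
        "no dark region passed the plate filters "
        f"(best candidate: circularity {best[0]:.3f}, area {best[1]:.0f} px²; "
        f"required circularity ≥ {min_circularity}, area ≥ {min_area:.0f} px²)"
    )


def calibrate_scale(mark_length_px: float, mark_length_mm: float) -> ScaleCalibration:
    """Pixel-per-mm scale from a visual mark of known length."""
    if mark_length_px <= 0 or mark_length_mm <= 0:
        raise InvalidInputError("mark lengths must be positive")
    return ScaleCalibration(
        pixels_per_mm=mark_length_px / mark_length_mm,
        mark_length_mm=mark_length_mm,
        mark_length_px=mark_length_px,
    )
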