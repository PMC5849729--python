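"""Binarization inside the ROI and per-particle measurement.

A particle is a maximal connected set of foreground (bright) pixels inside
the dish ROI.  Each particle is reported with six metrics: centroid
position, area (pixel count), perimeter (crack length: count of foreground
pixel edges exposed to the exterior), and the major/minor axes and
orientation of the area-preserving second-moment ellipse fit.

Coordinates are 0-based with x = column, y = row, origin top-left.  The
orientation angle is measured from the +x axis toward +y (counterclockwise
in the row/column frame) and reported in [0, 180).

Ellipse fit: second central moments of the member pixel coordinates, with a
+1/12 per-pixel variance term accounting for the unit-square extent of each
pixel.  The axis *ratio* comes from the moment eigenvalues; both axes are
then scaled so that π·(major/2)·(minor/2) equals the pixel-count area
exactly.  A single-pixel particle degenerates to the unit-area circle
equivalent (major = minor = 2/√π, angle 0) and is flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidInputError
from .roi import PlateROI

__all__ = [
    "ThresholdPolicy",
    "Particle",
    "ParticleTable",
    "otsu_threshold",
    "binarize",
    "label_particles",
    "measure_particle",
    "detect_particles",
]


@dataclass(frozen=True)
class ThresholdPolicy:
    """How to pick the black/white detection threshold.

    ``otsu`` maximizes between-class variance of the intensity histogram
    restricted to ROI pixels; ``fixed`` uses ``fixed_value``.  Foreground is
    always *strictly above* the threshold.
    """

    mode: str = "otsu"
    fixed_value: int | None = None

    def __post_init__(self):
        if self.mode not in ("otsu", "fixed"):
            raise InvalidInputError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "fixed":
            if self.fixed_value is None or not (0 <= self.fixed_value <= 255):
                raise InvalidInputError("fixed mode requires fixed_value in [0, 255]")


@dataclass
class Particle:
    id: int
    centroid_xy: tuple[float, float]
    area: int
    perimeter: float
    major: float
    minor: float
    angle_deg: float
    degenerate: bool = False


@dataclass
class ParticleTable:
    """Measured particles of one image, in raster-scan order (ids from 1)."""

    image_identifier: str
    particles: list[Particle] = field(default_factory=list)
    roi_center_xy: tuple[float, float] = (0.0, 0.0)
    roi_radius: float = 0.0
    threshold_used: int = 0

    def __len__(self) -> int:
        return len(self.particles)

    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.particles], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [p.id for p in self.particles],
                "x": [p.centroid_xy[0] for p in self.particles],
                "y": [p.centroid_xy[1] for p in self.particles],
                "area_px2": [p.area for p in self.particles],
                "perimeter_px": [p.perimeter for p in self.particles],
                "major_px": [p.major for p in self.particles],
                "minor_px": [p.minor for p in self.particles],
                "angle_deg": [p.angle_deg for p in self.particles],
                "degenerate": [p.degenerate for p in self.particles],
            }
        )

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            fh.write(f"# image={self.image_identifier}\n")
            fh.write(f"# threshold_used={self.threshold_used}\n")
            fh.write(
                f"# roi_center_x={self.roi_center_xy[0]:.2f} "
                f"roi_center_y={self.roi_center_xy[1]:.2f} "
                f"roi_radius={self.roi_radius:.2f}\n"
            )
            self.to_dataframe().to_csv(fh, index=False)


def otsu_threshold(values: np.ndarray) -> int:
    """Otsu's threshold over 8-bit values; foreground is strictly above it.

    Scans all 256 candidate thresholds via cumulative histogram sums and
    returns the smallest maximizer of the between-class variance.  If all
    values are equal the common value is returned (empty foreground).
    """
    values = np.asarray(values).ravel()
    if values.size == 0:
        raise InvalidInputError("cannot threshold an empty value set")
    hist = np.bincount(values.astype(np.intp), minlength=256).astype(float)
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(hist)
    total = w0[-1]
    s0 = np.cumsum(hist * levels)
    stot = s0[-1]
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        return int(values[0])
    sigma_b = np.zeros(256)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(w0 > 0, s0 / w0, 0.0)
        mu1 = np.where(w1 > 0, (stot - s0) / w1, 0.0)
    sigma_b[valid] = (w0 * w1 * (mu0 - mu1) ** 2)[valid]
    return int(np.argmax(sigma_b))  # argmax returns the smallest maximizer


def binarize(gray: np.ndarray, roi: PlateROI, policy: ThresholdPolicy = ThresholdPolicy()):
    """Threshold the image inside the ROI.  Returns ``(mask, threshold_used)``."""
    gray = np.asarray(gray)
    if gray.shape != roi.mask.shape:
        raise InvalidInputError("gray image and ROI mask dimensions differ")
    roi_values = gray[roi.mask]
    if roi_values.size == 0:
        raise InvalidInputError("ROI mask is empty")
    if policy.mode == "fixed":
        threshold = int(policy.fixed_value)
    else:
        threshold = otsu_threshold(roi_values)
    return (gray > threshold) & roi.mask, threshold


_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def label_particles(mask: np.ndarray, connectivity: int = 8):
    """Partition foreground pixels into connected components.

    Returns a list of ``(rows, cols)`` index arrays ordered by the
    raster-scan position of each component's first pixel.
    """
    if connectivity not in _STRUCTURES:
        raise InvalidInputError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    if n == 0:
        return []
    by_label = ndimage.value_indices(labels, ignore_value=0)
    flat = labels.ravel()
    present, first = np.unique(flat, return_index=True)
    first_of = dict(zip(present.tolist(), first.tolist()))
    order = sorted((k for k in by_label if k != 0), key=lambda k: first_of[k])
    return [by_label[k] for k in order]


def _crack_perimeter(rows: np.ndarray, cols: np.ndarray) -> int:
    """Exposed pixel-edge count of the component (4-neighbourhood cracks)."""
    r0, c0 = rows.min(), cols.min()
    m = np.zeros((rows.max() - r0 + 1, cols.max() - c0 + 1), dtype=bool)
    m[rows - r0, cols - c0] = True
    adj_h = np.count_nonzero(m[:, 1:] & m[:, :-1])
    adj_v = np.count_nonzero(m[1:, :] & m[:-1, :])
    return 4 * len(rows) - 2 * (adj_h + adj_v)


def measure_particle(pixel_set, particle_id: int = 1) -> Particle:
    """Measure one connected component given as ``(rows, cols)`` arrays."""
    rows, cols = (np.asarray(a, dtype=np.intp) for a in pixel_set)
    n = rows.size
    if n == 0:
        raise InvalidInputError("cannot measure an empty pixel set")
    area = int(n)
    xbar = float(cols.mean())
    ybar = float(rows.mean())
    perim = float(_crack_perimeter(rows, cols))

    dx = cols - xbar
    dy = rows - ybar
    # +1/12: variance of a unit-width pixel about its own center
    mu20 = float(np.mean(dx * dx)) + 1.0 / 12.0
    mu02 = float(np.mean(dy * dy)) + 1.0 / 12.0
    mu11 = float(np.mean(dx * dy))
    half_diff = (mu20 - mu02) / 2.0
    common = math.hypot(half_diff, mu11)
    lam1 = (mu20 + mu02) / 2.0 + common
    lam2 = (mu20 + mu02) / 2.0 - common
    lam2 = max(lam2, 1e-12)
    ratio = math.sqrt(lam1 / lam2)
    minor = 2.0 * math.sqrt(area / (math.pi * ratio))
    major = ratio * minor
    if common < 1e-12:
        angle = 0.0
    else:
        angle = math.degrees(0.5 * math.atan2(2.0 * mu11, mu20 - mu02)) % 180.0
    return Particle(
        id=particle_id,
        centroid_xy=(xbar, ybar),
        area=area,
        perimeter=perim,
        major=major,
        minor=minor,
        angle_deg=angle,
        degenerate=(n == 1),
    )


def detect_particles(
    gray: np.ndarray,
    roi: PlateROI,
    policy: ThresholdPolicy = ThresholdPolicy(),
    connectivity: int = 8,
    image_identifier: str = "",
) -> ParticleTable:
    """Binarize inside the ROI, label, and measure every particle."""
    mask, threshold = binarize(gray, roi, policy)
    components = label_particles(mask, connectivity)
    particles = [measure_particle(pix, particle_id=i) for i, pix in enumerate(components, start=1)]
    return ParticleTable(
        image_identifier=image_identifier,
        particles=particles,
        roi_center_xy=roi.center_xy,
        roi_radius=roi.radius,
        threshold_used=threshold,
    )
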