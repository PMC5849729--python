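"""Synthetic plate-photograph generator with recorded ground truth.

Emulates the imaging setup used for high-throughput Drosophila fecundity
assays: a Petri dish filled with dark (charcoal) medium photographed from
above against a white background, with pale eggs lying on the medium as
bright, roughly uniform ellipses.  Every generated image comes with a
:class:`GroundTruth` record of the planted objects, so segmentation,
area filtering and count validation can all be tested without any real
photographs.

The scene model, in rendering order:

1. white background at ``background_intensity``;
2. a dark disk (the medium) at ``medium_intensity`` plus Gaussian texture;
3. eggs as filled bright ellipses — size and aspect ratio drawn from
   truncated normals (eggs of one species are close to uniform in size),
   orientation uniform; a configurable fraction is planted in touching
   clumps of 2–3 so that downstream segmentation sees them as one particle;
4. dust as small bright specks, all strictly smaller than the smallest egg;
5. a linear horizontal illumination gradient, then additive Gaussian pixel
   noise, both clipped to the 8-bit range.

Determinism contract: a fixed :class:`SyntheticPlateSpec` (which embeds the
seed) always produces a bit-identical image and ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np

from .errors import InvalidInputError, PlacementError

__all__ = [
    "SyntheticPlateSpec",
    "GroundTruth",
    "render_ellipse",
    "generate_plate",
    "generate_validation_series",
    "PLACEMENT_RETRY_BUDGET",
]

#: attempts allowed per object before placement gives up
PLACEMENT_RETRY_BUDGET = 5000


@dataclass(frozen=True)
class SyntheticPlateSpec:
    """Parameters of one synthetic plate photograph.

    Defaults describe a 1024×1024 rendering of the assay geometry: the dish
    nearly fills the frame, the medium is near-black, the background white,
    and an egg of ~0.5 mm spans ~24 px along its major axis.
    """

    image_width: int = 1024
    image_height: int = 1024
    plate_center_xy: tuple[float, float] = (512.0, 512.0)
    plate_radius: float = 420.0
    background_intensity: int = 245
    medium_intensity: int = 30
    medium_texture_sd: float = 2.0
    egg_count: int = 100
    egg_major_mean: float = 24.0
    egg_major_sd: float = 1.5
    egg_aspect_ratio_mean: float = 2.5
    egg_aspect_ratio_sd: float = 0.2
    egg_intensity: int = 200
    dust_count: int = 0
    dust_area_range: tuple[float, float] = (2.0, 12.0)
    clump_fraction: float = 0.0
    clump_size_range: tuple[int, int] = (2, 3)
    illumination_gradient: float = 0.05
    noise_sd: float = 3.0
    seed: int = 0

    def nominal_egg_area(self) -> float:
        """Expected single-egg area in px² at the spec's mean geometry."""
        return math.pi / 4.0 * self.egg_major_mean**2 / self.egg_aspect_ratio_mean

    def validate(self) -> None:
        cx, cy = self.plate_center_xy
        w, h = self.image_width, self.image_height
        if w < 1 or h < 1:
            raise InvalidInputError("image dimensions must be positive")
        r = self.plate_radius
        if r <= 0:
            raise InvalidInputError("plate_radius must be positive")
        if (cx - r < 0) or (cy - r < 0) or (cx + r > w - 1) or (cy + r > h - 1):
            raise InvalidInputError("plate must fit fully inside the frame")
        if not (self.egg_intensity > self.medium_intensity + 5 * self.medium_texture_sd):
            raise InvalidInputError(
                "egg_intensity must exceed medium_intensity by at least "
                "5×medium_texture_sd for eggs to be segmentable"
            )
        if not (self.background_intensity > self.egg_intensity):
            raise InvalidInputError(
                "background must be brighter than eggs (plate is the darkest large region)"
            )
        if self.egg_count < 0 or self.dust_count < 0:
            raise InvalidInputError("object counts must be non-negative")
        if not (0.0 <= self.clump_fraction <= 1.0):
            raise InvalidInputError("clump_fraction must lie in [0, 1]")
        lo, hi = self.clump_size_range
        if not (2 <= lo <= hi):
            raise InvalidInputError("clump_size_range must satisfy 2 <= lo <= hi")
        alo, ahi = self.dust_area_range
        if not (0 < alo <= ahi):
            raise InvalidInputError("dust_area_range must be positive and ordered")
        if self.egg_major_mean <= 0 or self.egg_aspect_ratio_mean < 1.0:
            raise InvalidInputError("egg geometry must have major > 0 and aspect >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["plate_center_xy"] = list(self.plate_center_xy)
        d["dust_area_range"] = list(self.dust_area_range)
        d["clump_size_range"] = list(self.clump_size_range)
        return d


@dataclass
class GroundTruth:
    """Planted objects of one synthetic plate, recorded before noise.

    ``eggs`` holds ``(center_xy, major, minor, angle_deg)`` per egg;
    ``dust`` holds ``(center_xy, area)`` per speck; ``clumps`` lists the
    egg-index sets planted as touching groups.
    """

    eggs: list[tuple[tuple[float, float], float, float, float]] = field(default_factory=list)
    dust: list[tuple[tuple[float, float], float]] = field(default_factory=list)
    clumps: list[set[int]] = field(default_factory=list)

    @property
    def planted_egg_count(self) -> int:
        return len(self.eggs)

    @property
    def planted_dust_count(self) -> int:
        return len(self.dust)

    @property
    def clumped_indices(self) -> set[int]:
        out: set[int] = set()
        for c in self.clumps:
            out |= c
        return out


def render_ellipse(image, center_xy, major, minor, angle_deg, intensity):
    """Paint a filled rotated ellipse onto ``image`` (in place) and return it.

    A pixel is painted when its integer-coordinate center falls inside the
    ellipse, so the painted pixel count approximates π·(major/2)·(minor/2).
    """
    h, w = image.shape[:2]
    cx, cy = float(center_xy[0]), float(center_xy[1])
    if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
        raise InvalidInputError(f"ellipse center {center_xy} outside image bounds {w}x{h}")
    if not (major >= minor > 0):
        raise InvalidInputError("require major >= minor > 0")
    a, b = major / 2.0, minor / 2.0
    x0 = max(int(math.floor(cx - a)), 0)
    x1 = min(int(math.ceil(cx + a)), w - 1)
    y0 = max(int(math.floor(cy - a)), 0)
    y1 = min(int(math.ceil(cy + a)), h - 1)
    ys, xs = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    dx = xs - cx
    dy = ys - cy
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    region = image[y0 : y1 + 1, x0 : x1 + 1]
    region[inside] = intensity
    return image


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    # ±2σ truncation keeps egg geometry "roughly uniform"; see module docstring
    if sd <= 0:
        return mean
    return float(np.clip(rng.normal(mean, sd), mean - 2 * sd, mean + 2 * sd))


def _ellipse_pixels(shape, center_xy, major, minor, angle_deg):
    """Global (rows, cols) of pixel centers inside the rotated ellipse."""
    h, w = shape
    cx, cy = center_xy
    a, b = major / 2.0, minor / 2.0
    x0 = max(int(math.floor(cx - a)), 0)
    x1 = min(int(math.ceil(cx + a)), w - 1)
    y0 = max(int(math.floor(cy - a)), 0)
    y1 = min(int(math.ceil(cy + a)), h - 1)
    ys, xs = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    dx = xs - cx
    dy = ys - cy
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return ys[inside], xs[inside]


def _stamp(occupancy, rows, cols):
    """Mark the 1-px-dilated (8-neighbourhood) footprint as occupied."""
    h, w = occupancy.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            r = np.clip(rows + dr, 0, h - 1)
            c = np.clip(cols + dc, 0, w - 1)
            occupancy[r, c] = True


def _place(rng, occupancy, cx, cy, r_max, footprint_fn, budget=PLACEMENT_RETRY_BUDGET):
    """Rejection-sample a center inside the plate with a collision-free footprint.

    ``footprint_fn(x, y)`` returns the candidate's global ``(rows, cols)``
    pixel footprint.  A candidate is accepted when no footprint pixel hits
    the dilated occupancy of previously placed objects, which guarantees
    that the rendered components never touch (8-connectivity).
    """
    if r_max <= 0:
        raise PlacementError("plate too small for an object of the requested size")
    for _ in range(budget):
        rho = r_max * math.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * math.pi)
        x = cx + rho * math.cos(phi)
        y = cy + rho * math.sin(phi)
        rows, cols = footprint_fn(x, y)
        if rows.size and not occupancy[rows, cols].any():
            _stamp(occupancy, rows, cols)
            return x, y
    raise PlacementError(
        f"could not place object after {budget} attempts "
        f"(placement retry budget exhausted; plate too crowded)"
    )


def _partition_clumps(rng, egg_count, clump_fraction, size_range):
    """Split egg indices into singles and clump groups of the requested sizes."""
    n_clumped = int(round(clump_fraction * egg_count))
    if n_clumped < 2:
        return list(range(egg_count)), []
    lo, hi = size_range
    sizes: list[int] = []
    remaining = n_clumped
    while remaining >= 2:
        k = int(rng.integers(lo, hi + 1))
        k = min(k, remaining)
        if k < 2:
            break
        sizes.append(k)
        remaining -= k
    if remaining == 1 and sizes:
        sizes[-1] += 1  # avoid a dangling singleton "clump"
    clumps = []
    idx = 0
    for k in sizes:
        clumps.append(set(range(idx, idx + k)))
        idx += k
    singles = list(range(idx, egg_count))
    return singles, clumps


def generate_plate(spec: SyntheticPlateSpec):
    """Render one plate image and its ground truth.

    Returns ``(image, ground_truth)`` where image is a uint8 array of shape
    ``(image_height, image_width)``.  Deterministic for a fixed spec.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width
    cx, cy = spec.plate_center_xy

    img = np.full((h, w), float(spec.background_intensity))
    ys, xs = np.mgrid[0:h, 0:w]
    plate = (xs - cx) ** 2 + (ys - cy) ** 2 <= spec.plate_radius**2
    medium = np.full(plate.sum(), float(spec.medium_intensity))
    if spec.medium_texture_sd > 0:
        medium += rng.normal(0.0, spec.medium_texture_sd, size=medium.shape)
    img[plate] = medium

    gt = GroundTruth()
    occupancy = np.zeros((h, w), dtype=bool)
    margin = 2.0

    # clump bookkeeping first so index sets are contiguous and reproducible
    singles, clumps = _partition_clumps(
        rng, spec.egg_count, spec.clump_fraction, spec.clump_size_range
    )
    egg_params: dict[int, tuple[float, float, float]] = {}
    for i in range(spec.egg_count):
        major = _trunc_normal(rng, spec.egg_major_mean, spec.egg_major_sd)
        aspect = max(1.0, _trunc_normal(rng, spec.egg_aspect_ratio_mean, spec.egg_aspect_ratio_sd))
        angle = float(rng.uniform(0.0, 180.0))
        egg_params[i] = (major, major / aspect, angle)
    centers: dict[int, tuple[float, float]] = {}

    for clump in clumps:
        members = sorted(clump)
        minors = [egg_params[i][1] for i in members]
        spread = 0.45 * min(minors)
        # member offsets within 0.45·minor of the anchor: any two members then
        # sit closer than one minor axis apart, so their pixel sets overlap
        offsets = []
        for _ in members:
            rho = spread * math.sqrt(rng.uniform())
            phi = rng.uniform(0.0, 2.0 * math.pi)
            offsets.append((rho * math.cos(phi), rho * math.sin(phi)))
        reach = max(egg_params[i][0] for i in members) / 2.0 + spread
        r_max = spec.plate_radius - reach - margin

        def clump_footprint(x, y, members=members, offsets=offsets):
            parts = [
                _ellipse_pixels(
                    (h, w),
                    (x + ox, y + oy),
                    egg_params[i][0],
                    egg_params[i][1],
                    egg_params[i][2],
                )
                for i, (ox, oy) in zip(members, offsets)
            ]
            return (
                np.concatenate([p[0] for p in parts]),
                np.concatenate([p[1] for p in parts]),
            )

        ax, ay = _place(rng, occupancy, cx, cy, r_max, clump_footprint)
        for i, (ox, oy) in zip(members, offsets):
            centers[i] = (ax + ox, ay + oy)
    for i in singles:
        major, minor, angle = egg_params[i]
        r_max = spec.plate_radius - major / 2.0 - margin

        def egg_footprint(x, y, major=major, minor=minor, angle=angle):
            return _ellipse_pixels((h, w), (x, y), major, minor, angle)

        centers[i] = _place(rng, occupancy, cx, cy, r_max, egg_footprint)

    for i in range(spec.egg_count):
        major, minor, angle = egg_params[i]
        x, y = centers[i]
        render_ellipse(img, (x, y), major, minor, angle, float(spec.egg_intensity))
        gt.eggs.append(((x, y), major, minor, angle))
    gt.clumps = clumps

    alo, ahi = spec.dust_area_range
    for _ in range(spec.dust_count):
        area = float(rng.uniform(alo, ahi))
        rad = math.sqrt(area / math.pi)
        r_max = spec.plate_radius - rad - margin

        def dust_footprint(x, y, rad=rad):
            return _ellipse_pixels((h, w), (x, y), 2 * rad, 2 * rad, 0.0)

        x, y = _place(rng, occupancy, cx, cy, r_max, dust_footprint)
        render_ellipse(img, (x, y), 2 * rad, 2 * rad, 0.0, float(spec.egg_intensity))
        gt.dust.append(((x, y), area))

    if spec.illumination_gradient != 0.0:
        ramp = 1.0 + spec.illumination_gradient * (xs[0] / max(w - 1, 1) - 0.5)
        img *= ramp[np.newaxis, :]
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)

    return np.clip(np.rint(img), 0, 255).astype(np.uint8), gt


def generate_validation_series(egg_counts, base_spec: SyntheticPlateSpec, seed: int):
    """One plate per requested egg count, varying only the count and sub-seed.

    Sub-seeds are ``seed + index`` so images are reproducible independently.
    Mirrors a manual-vs-automated validation series across laying densities.
    """
    if any(c < 0 for c in egg_counts):
        raise InvalidInputError("egg counts must be non-negative")
    out = []
    for i, count in enumerate(egg_counts):
        spec = replace(base_spec, egg_count=int(count), seed=int(seed) + i)
        out.append(generate_plate(spec))
    return out


def ground_truth_records(image_name: str, gt: GroundTruth) -> list[dict]:
    """Flatten a ground truth into CSV-ready rows (one per planted object)."""
    clump_of = {}
    for ci, members in enumerate(gt.clumps, start=1):
        for m in members:
            clump_of[m] = ci
    rows = []
    for i, ((x, y), major, minor, angle) in enumerate(gt.eggs):
        rows.append(
            {
                "image": image_name,
                "type": "egg",
                "x": x,
                "y": y,
                "major": major,
                "minor": minor,
                "angle": angle,
                "area": math.pi / 4.0 * major * minor,
                "clump_id": clump_of.get(i, 0),
            }
        )
    for (x, y), area in gt.dust:
        rows.append(
            {
                "image": image_name,
                "type": "dust",
                "x": x,
                "y": y,
                "major": float("nan"),
                "minor": float("nan"),
                "angle": float("nan"),
                "area": area,
                "clump_id": 0,
            }
        )
    return rows
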