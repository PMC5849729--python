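"""Dust / egg / cluster classification from the particle-area distribution.

Besides eggs, segmentation picks up dust specks (much smaller than an egg)
and clumps of touching eggs that merge into one oversized particle.  The
area distribution across a plate is therefore bimodal on a log scale: a
small-area dust mode and an egg mode.  The filter locates the valley
between the two modes (dust/egg cutoff), takes everything above
``cluster_factor`` × egg-mode area as a cluster, and reports the remaining
mid-range particles as the per-image egg count.  Clusters are excluded
rather than apportioned, so counts are biased downward at very high egg
densities — the expected behavior of this procedure.

Valley finding: Gaussian KDE of log-areas (Silverman bandwidth) evaluated
on a fine grid; the two highest local maxima are the modes, the density
minimum between them the cutoff.  The valley must drop below half the lower
mode's density, otherwise the distribution is declared unimodal and the
caller falls back to fixed cutoffs from configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .errors import InsufficientDataError, InvalidInputError, UnimodalAreaError
from .particles import ParticleTable

__all__ = [
    "AreaPartition",
    "EggCount",
    "FilterConfig",
    "fit_area_partition",
    "classify_particles",
    "count_eggs",
]

#: minimum peak-to-valley density drop for the distribution to count as bimodal
_VALLEY_PROMINENCE = 0.5


@dataclass(frozen=True)
class AreaPartition:
    """Fitted dust/egg/cluster area cutoffs (all in px²)."""

    dust_egg_cutoff: float
    egg_mode: float
    cluster_cutoff: float
    cluster_factor: float
    method_detail: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if not (0 < self.dust_egg_cutoff < self.egg_mode < self.cluster_cutoff):
            raise InvalidInputError(
                "require 0 < dust_egg_cutoff < egg_mode < cluster_cutoff, got "
                f"{self.dust_egg_cutoff}, {self.egg_mode}, {self.cluster_cutoff}"
            )


@dataclass
class EggCount:
    """Per-image classification summary; ``n_eggs`` is the headline phenotype."""

    image_identifier: str
    n_particles_total: int
    n_dust: int
    n_eggs: int
    n_clusters: int
    partition: AreaPartition


@dataclass(frozen=True)
class FilterConfig:
    """Filtering parameters and the fixed-cutoff fallback.

    When per-image fitting fails (too few particles, or no second mode —
    e.g. an egg-free plate carrying only dust) the fixed cutoffs are used
    instead; with no fixed cutoffs configured the failure propagates.
    """

    cluster_factor: float = 1.75
    min_particles: int = 10
    fixed_dust_egg_cutoff: float | None = None
    fixed_cluster_cutoff: float | None = None

    @classmethod
    def from_nominal_egg_area(cls, egg_area_px2: float, cluster_factor: float = 1.75):
        """Derive fixed fallback cutoffs from a nominal single-egg area.

        Dust cutoff at a quarter of an egg, cluster cutoff at
        ``cluster_factor`` eggs — the same rule the fitted partition applies
        to its estimated egg mode.
        """
        if egg_area_px2 <= 0:
            raise InvalidInputError("nominal egg area must be positive")
        return cls(
            cluster_factor=cluster_factor,
            fixed_dust_egg_cutoff=0.25 * egg_area_px2,
            fixed_cluster_cutoff=cluster_factor * egg_area_px2,
        )

    def fallback_partition(self) -> AreaPartition:
        if self.fixed_dust_egg_cutoff is None or self.fixed_cluster_cutoff is None:
            raise InsufficientDataError(
                "area-partition fit failed and no fixed cutoffs are configured; "
                "set fixed_dust_egg_cutoff and fixed_cluster_cutoff"
            )
        return AreaPartition(
            dust_egg_cutoff=float(self.fixed_dust_egg_cutoff),
            egg_mode=float(self.fixed_cluster_cutoff) / self.cluster_factor,
            cluster_cutoff=float(self.fixed_cluster_cutoff),
            cluster_factor=self.cluster_factor,
            method_detail={"method": "fixed-fallback"},
        )


def fit_area_partition(
    areas, cluster_factor: float = 1.75, min_particles: int = 10
) -> AreaPartition:
    """Fit the bimodal dust/egg partition to a list of particle areas.

    Raises :class:`InsufficientDataError` below ``min_particles`` areas and
    :class:`UnimodalAreaError` when no acceptable valley exists.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.size < min_particles:
        raise InsufficientDataError(
            f"need at least {min_particles} particle areas to fit the "
            f"bimodal partition, got {areas.size}"
        )
    if np.any(areas <= 0):
        raise InvalidInputError("particle areas must be positive")
    log_a = np.log(areas)
    if np.ptp(log_a) < 1e-12:
        raise UnimodalAreaError(
            f"all particle areas identical (single mode at {areas[0]:.1f} px²)",
            mode=float(areas[0]),
        )
    kde = gaussian_kde(log_a, bw_method="silverman")
    bw = float(kde.factor * log_a.std(ddof=1))
    lo, hi = log_a.min() - 3 * bw, log_a.max() + 3 * bw
    grid = np.linspace(lo, hi, 512)
    dens = kde(grid)
    interior = dens[1:-1]
    is_peak = (interior > dens[:-2]) & (interior >= dens[2:])
    peak_idx = np.nonzero(is_peak)[0] + 1
    if len(peak_idx) < 2:
        mode = float(np.exp(grid[int(np.argmax(dens))]))
        raise UnimodalAreaError(
            f"particle-area distribution is unimodal (mode ≈ {mode:.1f} px²)", mode=mode
        )
    top_two = peak_idx[np.argsort(dens[peak_idx])][-2:]
    i_lo, i_hi = int(top_two.min()), int(top_two.max())
    valley_rel = int(np.argmin(dens[i_lo : i_hi + 1]))
    i_valley = i_lo + valley_rel
    peak_floor = min(dens[i_lo], dens[i_hi])
    if dens[i_valley] > _VALLEY_PROMINENCE * peak_floor:
        mode = float(np.exp(grid[int(np.argmax(dens))]))
        raise UnimodalAreaError(
            "no sufficiently deep valley between area modes "
            f"(valley/peak density ratio {dens[i_valley] / peak_floor:.2f}); "
            f"treating distribution as unimodal (mode ≈ {mode:.1f} px²)",
            mode=mode,
        )
    egg_mode = float(np.exp(grid[i_hi]))
    cutoff = float(np.exp(grid[i_valley]))
    return AreaPartition(
        dust_egg_cutoff=cutoff,
        egg_mode=egg_mode,
        cluster_cutoff=cluster_factor * egg_mode,
        cluster_factor=cluster_factor,
        method_detail={
            "method": "kde-valley",
            "bandwidth": bw,
            "dust_mode": float(np.exp(grid[i_lo])),
            "n_areas": int(areas.size),
        },
    )


def classify_particles(table: ParticleTable, partition: AreaPartition) -> pd.DataFrame:
    """Label every particle dust / egg / cluster; no particle is dropped.

    Areas at or below the dust cutoff are dust (inclusive rule), areas
    strictly above the cluster cutoff are clusters, the rest are eggs.
    """
    df = table.to_dataframe()
    area = df["area_px2"].to_numpy(dtype=float)
    labels = np.where(
        area <= partition.dust_egg_cutoff,
        "dust",
        np.where(area > partition.cluster_cutoff, "cluster", "egg"),
    )
    df["label"] = labels
    return df


def count_eggs(
    table: ParticleTable,
    config: FilterConfig = FilterConfig(),
    partition: AreaPartition | None = None,
) -> EggCount:
    """Fit the area partition (or use the given/fallback one) and count eggs."""
    if partition is None:
        try:
            partition = fit_area_partition(
                table.areas(),
                cluster_factor=config.cluster_factor,
                min_particles=config.min_particles,
            )
        except (InsufficientDataError, UnimodalAreaError):
            partition = config.fallback_partition()
    labeled = classify_particles(table, partition)
    counts = labeled["label"].value_counts()
    n_dust = int(counts.get("dust", 0))
    n_eggs = int(counts.get("egg", 0))
    n_clusters = int(counts.get("cluster", 0))
    return EggCount(
        image_identifier=table.image_identifier,
        n_particles_total=len(table),
        n_dust=n_dust,
        n_eggs=n_eggs,
        n_clusters=n_clusters,
        partition=partition,
    )
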