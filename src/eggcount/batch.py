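"""Recursive batch processing of plate-image directory trees.

Directory layout carries experiment metadata (e.g. population / transfer /
treatment as nested directories); the scanner decodes it, each image runs
through the full chain (grayscale → plate ROI → particle detection → area
filter), per-image particle tables are written as CSV files named from the
relative path, and a combined summary collects metadata plus egg counts.
Per-image failures are recorded and never abort the batch.

Also hosts the manual-vs-automated validation: Spearman rank concordance
between paired counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .errors import (
    InsufficientDataError,
    InvalidInputError,
    UndefinedCorrelationError,
)
from .filtering import EggCount, FilterConfig, count_eggs, fit_area_partition
from .particles import ParticleTable, ThresholdPolicy, detect_particles
from .roi import EQUAL_WEIGHTS, detect_plate_roi, to_grayscale

__all__ = [
    "BatchConfig",
    "BatchReport",
    "ValidationPair",
    "ConcordanceResult",
    "IMAGE_SUFFIXES",
    "scan_inputs",
    "analyze_image",
    "process_image",
    "run_batch",
    "spearman_concordance",
]

logger = logging.getLogger("eggcount")

#: suffixes considered images when the extension filter is disabled
IMAGE_SUFFIXES = {".jpg", ".jpeg", ".png", ".tif", ".tiff"}


@dataclass(frozen=True)
class BatchConfig:
    """Everything a batch run needs; YAML-config and CLI flags map onto this."""

    input_root: Path
    output_root: Path
    extension_filter: str | None = ".JPG"
    metadata_schema: tuple[str, ...] = ()
    grayscale_weights: tuple[float, float, float] = EQUAL_WEIGHTS
    dark_threshold: int | None = None
    min_circularity: float = 0.8
    min_area_fraction: float = 0.1
    threshold_policy: ThresholdPolicy = field(default_factory=ThresholdPolicy)
    connectivity: int = 8
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    pool_areas: bool = False

    def __post_init__(self):
        if self.extension_filter is not None:
            if not self.extension_filter.startswith(".") or len(self.extension_filter) < 2:
                raise InvalidInputError(
                    'extension_filter must be a non-empty string beginning with "."'
                )


@dataclass
class BatchReport:
    summary: pd.DataFrame
    failures: list[tuple[str, str]]
    n_processed: int

    @property
    def ok(self) -> bool:
        return not self.failures


class ValidationPair(NamedTuple):
    image_identifier: str
    manual_count: int
    automated_count: int


class ConcordanceResult(NamedTuple):
    rho: float
    n: int


def _iter_files(directory: Path):
    """Depth-first lexicographic traversal yielding files."""
    for entry in sorted(directory.iterdir(), key=lambda p: p.name):
        if entry.is_dir():
            yield from _iter_files(entry)
        elif entry.is_file():
            yield entry


def scan_inputs(config: BatchConfig):
    """List images under ``input_root`` with path-derived metadata records.

    Only files matching ``extension_filter`` (case-insensitively) are kept
    when the filter is active; with the filter disabled, any common image
    suffix qualifies.  Metadata maps ``metadata_schema`` names onto the
    image's ancestor directory names, top-down; unmatched schema levels are
    recorded as empty strings with a warning.
    """
    root = Path(config.input_root)
    if not root.is_dir():
        raise InvalidInputError(f"input root {root} does not exist or is not a directory")
    out = []
    for path in _iter_files(root):
        suffix = path.suffix.lower()
        if config.extension_filter is not None:
            if suffix != config.extension_filter.lower():
                continue
        elif suffix not in IMAGE_SUFFIXES:
            continue
        levels = path.relative_to(root).parts[:-1]
        meta = {}
        for i, name in enumerate(config.metadata_schema):
            if i < len(levels):
                meta[name] = levels[i]
            else:
                meta[name] = ""
                warnings.warn(
                    f"{path}: no directory level for metadata field {name!r}",
                    stacklevel=2,
                )
        out.append((path, meta))
    return out


def _relative_identifier(path: Path, root: Path | None) -> str:
    if root is not None:
        try:
            rel = path.relative_to(root)
            return "_".join(rel.parts[:-1] + (rel.stem,))
        except ValueError:
            pass
    return path.stem


def analyze_image(image: np.ndarray, config: BatchConfig, image_identifier: str = ""):
    """Run the in-memory chain on a decoded image array.

    Returns ``(ParticleTable, EggCount)``; when ``config.pool_areas`` is set
    the caller is expected to fit the pooled partition itself and pass the
    table to :func:`eggcount.filtering.count_eggs` directly.
    """
    gray = to_grayscale(image, config.grayscale_weights)
    roi = detect_plate_roi(
        gray,
        dark_threshold=config.dark_threshold,
        min_circularity=config.min_circularity,
        min_area_fraction=config.min_area_fraction,
    )
    table = detect_particles(
        gray,
        roi,
        policy=config.threshold_policy,
        connectivity=config.connectivity,
        image_identifier=image_identifier,
    )
    return table, count_eggs(table, config.filter_config)


def process_image(path, config: BatchConfig):
    """Read one image file and run the full per-image chain."""
    path = Path(path)
    image = iio.imread(path)
    identifier = _relative_identifier(path, Path(config.input_root))
    return analyze_image(image, config, image_identifier=identifier)


def _summary_row(meta: dict, identifier: str, count: EggCount) -> dict:
    row = dict(meta)
    row.update(
        image=identifier,
        n_particles_total=count.n_particles_total,
        n_dust=count.n_dust,
        n_eggs=count.n_eggs,
        n_clusters=count.n_clusters,
        dust_egg_cutoff=count.partition.dust_egg_cutoff,
        egg_mode=count.partition.egg_mode,
        cluster_cutoff=count.partition.cluster_cutoff,
    )
    return row


def run_batch(config: BatchConfig) -> BatchReport:
    """Process every image under ``input_root``; write CSVs under ``output_root``.

    Outputs: one particle CSV per image (named by joining the relative path
    components with underscores), ``summary.csv`` (metadata + egg counts),
    ``failures.csv``, and ``run.log``.  Per-image failures are isolated.
    """
    entries = scan_inputs(config)
    root = Path(config.input_root)
    out_root = Path(config.output_root)
    try:
        out_root.mkdir(parents=True, exist_ok=True)
        (out_root / ".write_test").write_text("")
        (out_root / ".write_test").unlink()
    except OSError as exc:
        raise InvalidInputError(f"output root {out_root} is not writable: {exc}") from exc

    identifiers = [_relative_identifier(p, root) for p, _ in entries]
    seen: dict[str, Path] = {}
    for ident, (p, _) in zip(identifiers, entries):
        if ident in seen:
            raise InvalidInputError(
                f"path-derived output name collision: {seen[ident]} and {p} "
                f"both map to {ident!r}"
            )
        seen[ident] = p

    handler = logging.FileHandler(out_root / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("eggcount %s batch start: %d images under %s", __version__, len(entries), root)
        logger.info("config: %r", config)

        pooled_partition = None
        tables: list[tuple[str, dict, ParticleTable]] = []
        rows: list[dict] = []
        failures: list[tuple[str, str]] = []

        for (path, meta), ident in zip(entries, identifiers):
            try:
                table, count = process_image(path, config)
            except Exception as exc:  # per-image isolation is the contract
                logger.warning("failed on %s: %s", path, exc)
                failures.append((str(path), f"{type(exc).__name__}: {exc}"))
                continue
            table.to_csv(out_root / f"{ident}.csv")
            if config.pool_areas:
                tables.append((ident, meta, table))
            else:
                logger.info(
                    "%s: %d particles, %d eggs (cutoffs %.1f / %.1f)",
                    ident,
                    count.n_particles_total,
                    count.n_eggs,
                    count.partition.dust_egg_cutoff,
                    count.partition.cluster_cutoff,
                )
                rows.append(_summary_row(meta, ident, count))

        if config.pool_areas and tables:
            pooled = np.concatenate([t.areas() for _, _, t in tables if len(t)])
            fc = config.filter_config
            try:
                pooled_partition = fit_area_partition(
                    pooled, cluster_factor=fc.cluster_factor, min_particles=fc.min_particles
                )
            except Exception as exc:
                logger.warning("pooled fit failed (%s); falling back per image", exc)
            for ident, meta, table in tables:
                count = count_eggs(table, config.filter_config, partition=pooled_partition)
                logger.info("%s: %d eggs (pooled fit)", ident, count.n_eggs)
                rows.append(_summary_row(meta, ident, count))

        meta_cols = list(config.metadata_schema)
        count_cols = [
            "image",
            "n_particles_total",
            "n_dust",
            "n_eggs",
            "n_clusters",
            "dust_egg_cutoff",
            "egg_mode",
            "cluster_cutoff",
        ]
        summary = pd.DataFrame(rows, columns=meta_cols + count_cols)
        summary.to_csv(out_root / "summary.csv", index=False)
        pd.DataFrame(failures, columns=["image", "error"]).to_csv(
            out_root / "failures.csv", index=False
        )
        logger.info("batch done: %d processed, %d failed", len(rows), len(failures))
        return BatchReport(summary=summary, failures=failures, n_processed=len(rows))
    finally:
        logger.removeHandler(handler)
        handler.close()


def spearman_concordance(pairs) -> ConcordanceResult:
    """Spearman's ρ between manual and automated counts (average ranks for ties).

    ``pairs`` is a sequence of :class:`ValidationPair` or
    ``(manual, automated)`` / ``(id, manual, automated)`` tuples.
    """
    manual, automated = [], []
    for p in pairs:
        if len(p) == 3:
            _, m, a = p
        else:
            m, a = p
        manual.append(float(m))
        automated.append(float(a))
    n = len(manual)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 pairs for rank correlation, got {n}")
    if np.ptp(manual) == 0 or np.ptp(automated) == 0:
        raise UndefinedCorrelationError(
            "rank correlation undefined: one of the count vectors has zero variance"
        )
    rho = float(stats.spearmanr(manual, automated).statistic)
    return ConcordanceResult(rho=rho, n=n)
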