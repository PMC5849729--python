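"""Directory scanning, per-image isolation, summary bookkeeping, concordance."""

import zlib
from dataclasses import replace

import imageio.v3 as iio
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from eggcount import (
    BatchConfig,
    InsufficientDataError,
    InvalidInputError,
    SyntheticPlateSpec,
    UndefinedCorrelationError,
    generate_plate,
    generate_validation_series,
    process_image,
    run_batch,
    scan_inputs,
    spearman_concordance,
)
from eggcount.filtering import FilterConfig

from helpers import spearman_oracle


BATCH_SPEC = SyntheticPlateSpec(
    image_width=256,
    image_height=256,
    plate_center_xy=(128.0, 128.0),
    plate_radius=105.0,
    egg_count=15,
    dust_count=8,
)

FILTER = FilterConfig.from_nominal_egg_area(BATCH_SPEC.nominal_egg_area())


def _write_tree(root, layout):
    """layout: {relative path -> egg count (int) or raw bytes}."""
    for rel, content in layout.items():
        path = root / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        if isinstance(content, bytes):
            path.write_bytes(content)
        else:
            seed = zlib.crc32(rel.encode()) % 2**31
            img, _ = generate_plate(replace(BATCH_SPEC, egg_count=content, seed=seed))
            iio.imwrite(path, img)


class TestScanInputs:
    def test_default_extension_filter(self, tmp_path):
        for name in ("a.JPG", "a.CR2", "notes.txt", "b.jpg"):
            (tmp_path / name).write_bytes(b"x")
        config = BatchConfig(input_root=tmp_path, output_root=tmp_path / "out")
        found = [p.name for p, _ in scan_inputs(config)]
        assert found == ["a.JPG", "b.jpg"]  # case-insensitive .JPG match

    def test_metadata_from_directory_levels(self, tmp_path):
        (tmp_path / "popA" / "t1").mkdir(parents=True)
        (tmp_path / "popA" / "t1" / "img1.jpg").write_bytes(b"x")
        config = BatchConfig(
            input_root=tmp_path, output_root=tmp_path / "out",
            metadata_schema=("population", "transfer"),
        )
        [(path, meta)] = scan_inputs(config)
        assert meta == {"population": "popA", "transfer": "t1"}

    def test_shallow_image_warns_and_pads(self, tmp_path):
        (tmp_path / "img.jpg").write_bytes(b"x")
        config = BatchConfig(
            input_root=tmp_path, output_root=tmp_path / "out",
            metadata_schema=("population", "transfer"),
        )
        with pytest.warns(UserWarning):
            [(path, meta)] = scan_inputs(config)
        assert meta == {"population": "", "transfer": ""}

    def test_disabled_filter_returns_all_image_formats(self, tmp_path):
        for name in ("a.jpg", "b.png", "c.txt"):
            (tmp_path / name).write_bytes(b"x")
        config = BatchConfig(input_root=tmp_path, output_root=tmp_path / "out",
                             extension_filter=None)
        assert [p.name for p, _ in scan_inputs(config)] == ["a.jpg", "b.png"]

    def test_missing_root_rejected(self, tmp_path):
        config = BatchConfig(input_root=tmp_path / "nope", output_root=tmp_path)
        with pytest.raises(InvalidInputError):
            scan_inputs(config)

    def test_traversal_deterministic(self, tmp_path):
        _write_tree(tmp_path, {"b/x.png": 5, "a/y.png": 5, "a/b/z.png": 5})
        config = BatchConfig(input_root=tmp_path, output_root=tmp_path / "out",
                             extension_filter=".png")
        assert scan_inputs(config) == scan_inputs(config)


def _batch_config(tmp_path, **kwargs):
    defaults = dict(
        input_root=tmp_path / "in",
        output_root=tmp_path / "out",
        extension_filter=".png",
        filter_config=FILTER,
    )
    defaults.update(kwargs)
    return BatchConfig(**defaults)


class TestProcessImage:
    def test_clean_plate_counted_exactly(self, tmp_path):
        _write_tree(tmp_path / "in", {"plate.png": 20})
        config = _batch_config(tmp_path)
        table, count = process_image(tmp_path / "in" / "plate.png", config)
        assert count.n_eggs == 20
        assert count.n_dust == BATCH_SPEC.dust_count

    def test_zero_byte_file_raises_cleanly(self, tmp_path):
        bad = tmp_path / "in" / "corrupt.png"
        bad.parent.mkdir(parents=True)
        bad.write_bytes(b"")
        with pytest.raises(Exception):
            process_image(bad, _batch_config(tmp_path))


class TestRunBatch:
    def test_outputs_and_metadata_roundtrip(self, tmp_path):
        layout = {
            f"pop{p}/t{t}/plate.png": 10 + 5 * t
            for p in "AB" for t in (1, 2, 3)
        }
        _write_tree(tmp_path / "in", layout)
        config = _batch_config(tmp_path, metadata_schema=("population", "transfer"))
        report = run_batch(config)
        assert report.ok and report.n_processed == 6
        assert sorted(report.summary["population"].unique()) == ["popA", "popB"]
        for rel in layout:
            name = rel.replace("/", "_").replace(".png", ".csv")
            assert (tmp_path / "out" / name).exists()
        summary = pd.read_csv(tmp_path / "out" / "summary.csv")
        for _, row in summary.iterrows():
            assert row["image"] == f"{row['population']}_{row['transfer']}_plate"

    def test_per_image_failure_is_isolated(self, tmp_path):
        _write_tree(tmp_path / "in", {"a/good1.png": 12, "a/good2.png": 14,
                                      "b/bad.png": b"not an image"})
        report = run_batch(_batch_config(tmp_path))
        assert report.n_processed == 2
        assert len(report.failures) == 1 and "bad" in report.failures[0][0]

    def test_rerun_is_byte_identical(self, tmp_path):
        _write_tree(tmp_path / "in", {"x/p.png": 18})
        run_batch(_batch_config(tmp_path, output_root=tmp_path / "out1"))
        run_batch(_batch_config(tmp_path, output_root=tmp_path / "out2"))
        for name in ("summary.csv", "x_p.csv"):
            assert (tmp_path / "out1" / name).read_bytes() == (
                tmp_path / "out2" / name
            ).read_bytes()

    def test_output_name_collision_aborts(self, tmp_path):
        _write_tree(tmp_path / "in", {"a/b_p.png": 10, "a_b/p.png": 10})
        with pytest.raises(InvalidInputError, match="collision"):
            run_batch(_batch_config(tmp_path))

    def test_pooled_fit_matches_per_image_on_rich_plates(self, tmp_path):
        _write_tree(tmp_path / "in", {"a/p1.png": 20, "a/p2.png": 25})
        per_image = run_batch(_batch_config(tmp_path, output_root=tmp_path / "o1"))
        pooled = run_batch(
            _batch_config(tmp_path, output_root=tmp_path / "o2", pool_areas=True)
        )
        a = per_image.summary.sort_values("image")["n_eggs"].tolist()
        b = pooled.summary.sort_values("image")["n_eggs"].tolist()
        assert a == b == [20, 25]


class TestSpearmanConcordance:
    def test_perfect_concordance(self):
        assert spearman_concordance([(1, 1), (2, 2), (3, 3), (4, 4)]).rho == pytest.approx(1.0)

    def test_perfect_reversal(self):
        assert spearman_concordance([(1, 4), (2, 3), (3, 2), (4, 1)]).rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle_with_ties(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            manual = rng.integers(0, 10, 20)
            auto = manual + rng.integers(-2, 3, 20)
            got = spearman_concordance(list(zip(manual, auto))).rho
            assert got == pytest.approx(spearman_oracle(manual, auto), abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            spearman_concordance([(1, 1), (2, 2)])

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_concordance([(5, 1), (5, 2), (5, 3)])

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        manual = rng.integers(0, 50, 10)
        auto = rng.integers(0, 50, 10)
        if np.ptp(manual) == 0 or np.ptp(auto) == 0:
            return
        base = spearman_concordance(list(zip(manual, auto))).rho
        transformed = spearman_concordance(
            list(zip(manual * 3 + 7, (auto.astype(float) + 1) ** 2))
        ).rho
        assert transformed == pytest.approx(base, abs=1e-12)


class TestEndToEndConcordance:
    def test_small_series_recovers_ranking(self, pipeline):
        series = generate_validation_series([10, 20, 30, 40, 50], BATCH_SPEC, seed=100)
        pairs = []
        for img, gt in series:
            _, result = pipeline(img, BATCH_SPEC)
            pairs.append((gt.planted_egg_count, result.n_eggs))
        assert spearman_concordance(pairs).rho >= 0.99
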