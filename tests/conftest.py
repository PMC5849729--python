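from dataclasses import replace

import pytest

from eggcount import SyntheticPlateSpec, count_eggs, detect_particles, detect_plate_roi
from eggcount.filtering import FilterConfig


@pytest.fixture
def small_spec():
    """A 512×512 plate: fast enough for unit tests, same geometry otherwise."""
    return SyntheticPlateSpec(
        image_width=512,
        image_height=512,
        plate_center_xy=(256.0, 256.0),
        plate_radius=210.0,
        egg_count=40,
        dust_count=10,
        seed=7,
    )


@pytest.fixture
def clean_spec(small_spec):
    """Noise-free, dust-free, texture-free variant for exact pixel assertions."""
    return replace(
        small_spec,
        egg_count=0,
        dust_count=0,
        noise_sd=0.0,
        medium_texture_sd=0.0,
        illumination_gradient=0.0,
    )


def run_pipeline(image, spec, **filter_kwargs):
    """Full in-memory chain on a synthetic plate image."""
    roi = detect_plate_roi(image)
    table = detect_particles(image, roi)
    config = FilterConfig.from_nominal_egg_area(spec.nominal_egg_area(), **filter_kwargs)
    return table, count_eggs(table, config)


@pytest.fixture
def pipeline():
    return run_pipeline
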